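"""Domain containers and file formats for network enrichment analysis.

The three inputs of an NEA run are a global functional-coupling network
(NET), one or more *altered gene sets* (AGS, the experimental side), and a
collection of *functional gene sets* (FGS, the annotation side).  This
module holds the in-memory containers for all three, the per-pair result
record, and the TSV/GMT readers and writers.

Gene identifiers are opaque, case-sensitive strings; AGS, FGS and NET must
use the same identifier scheme.  An optional ``normalize="upper"`` flag on
the readers maps everything to upper case for sloppy inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("netenrich")

__all__ = [
    "DataError",
    "Network",
    "GeneSet",
    "GeneSetCollection",
    "NEAStats",
    "ResultMatrix",
    "read_network",
    "read_gene_sets",
    "write_gmt",
    "restrict_to_network",
    "degree_sum",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

#: column order of the long result layout; fixed, relied on by round-trips
RESULT_COLUMNS = ["ags_id", "fgs_id", "n_edges", "expected_edges", "chi2", "z", "p", "q"]


class DataError(Exception):
    """Malformed or inconsistent user data (bad file, empty input, ...)."""


def _canonical(u: str, v: str) -> Tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class Network:
    """Undirected simple graph over gene identifiers.

    Self-loops and duplicate edges are collapsed at construction.  Degrees
    count distinct neighbours; the total edge count ``n_total_edges`` is the
    ``N_total`` of the enrichment null model.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` node-id pairs; orientation is ignored.
    weights
        Optional mapping from canonical pair to a confidence value.  Stored
        for provenance only — no statistic in this package uses weights.
    name
        Free-text label carried into result metadata.
    """

    def __init__(
        self,
        edges: Iterable[Tuple[str, str]],
        weights: Optional[Mapping[Tuple[str, str], float]] = None,
        name: str = "",
    ) -> None:
        self.name = name
        self.adj: Dict[str, set] = {}
        self.edges: set = set()
        n_self = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                continue
            key = _canonical(u, v)
            if key in self.edges:
                continue
            self.edges.add(key)
            self.adj.setdefault(u, set()).add(v)
            self.adj.setdefault(v, set()).add(u)
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        self.weights: Dict[Tuple[str, str], float] = dict(weights) if weights else {}
        self._node_order: Optional[List[str]] = None
        self._edge_arrays: Optional[Tuple[np.ndarray, np.ndarray]] = None

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self.adj)

    @property
    def n_total_edges(self) -> int:
        return len(self.edges)

    @property
    def degree(self) -> Dict[str, int]:
        return {u: len(nb) for u, nb in self.adj.items()}

    def __contains__(self, node: str) -> bool:
        return node in self.adj

    def __len__(self) -> int:
        return len(self.adj)

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical(u, v) in self.edges

    def neighbors(self, node: str) -> set:
        return self.adj[node]

    # -- integer-indexed view used by the vectorised counting kernels ------
    def node_order(self) -> List[str]:
        """Deterministic (sorted) node ordering used for array indexing."""
        if self._node_order is None:
            self._node_order = sorted(self.adj)
        return self._node_order

    def edge_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """Edge list as two int arrays of node indices (one row per edge)."""
        if self._edge_arrays is None:
            index = {n: i for i, n in enumerate(self.node_order())}
            pairs = sorted(self.edges)
            eu = np.fromiter((index[u] for u, _ in pairs), dtype=np.int64, count=len(pairs))
            ev = np.fromiter((index[v] for _, v in pairs), dtype=np.int64, count=len(pairs))
            self._edge_arrays = (eu, ev)
        return self._edge_arrays

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(name={self.name!r}, nodes={len(self)}, edges={self.n_total_edges})"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (used for both AGS and FGS roles)."""

    set_id: str
    members: frozenset

    def __post_init__(self) -> None:
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


class GeneSetCollection:
    """Ordered, id-unique collection of :class:`GeneSet` with a role tag."""

    def __init__(self, sets: Iterable[GeneSet] = (), role: str = "FGS", name: str = "") -> None:
        self.role = role
        self.name = name
        self._sets: Dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self._sets:
            raise DataError(f"duplicate gene-set id {gs.set_id!r}")
        self._sets[gs.set_id] = gs

    @property
    def ids(self) -> List[str]:
        return list(self._sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def all_genes(self) -> set:
        out: set = set()
        for gs in self:
            out |= gs.members
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection(role={self.role!r}, n_sets={len(self)})"


@dataclass
class NEAStats:
    """Enrichment statistics for one AGS–FGS pair.

    ``n_edges`` is the observed between-set edge count, ``expected_edges``
    the count expected under the null, ``chi2`` the one-degree-of-freedom
    statistic, ``z`` its signed Gaussian equivalent (negative = depletion),
    ``p`` the chi-squared upper-tail p-value and ``q`` the
    Benjamini–Hochberg adjusted value over the whole result matrix
    (NaN until matrix-level adjustment).
    """

    ags_id: str
    fgs_id: str
    n_edges: int
    expected_edges: float
    chi2: float
    z: float
    p: float
    q: float = math.nan


class ResultMatrix:
    """AGS × FGS grid of :class:`NEAStats` plus run metadata."""

    def __init__(self, cells: Sequence[NEAStats], metadata: Optional[dict] = None) -> None:
        self.cells = list(cells)
        self.metadata = dict(metadata or {})
        self._index = {(c.ags_id, c.fgs_id): c for c in self.cells}
        if len(self._index) != len(self.cells):
            raise ValueError("duplicate (ags_id, fgs_id) cell")

    def get(self, ags_id: str, fgs_id: str) -> NEAStats:
        return self._index[(ags_id, fgs_id)]

    @property
    def ags_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.ags_id)
        return list(seen)

    @property
    def fgs_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.fgs_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.cells)

    def to_long(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.ags_id, c.fgs_id, c.n_edges, c.expected_edges, c.chi2, c.z, c.p, c.q)
                for c in self.cells
            ],
            columns=RESULT_COLUMNS,
        )

    def to_wide(self, statistic: str) -> pd.DataFrame:
        if statistic not in RESULT_COLUMNS[2:]:
            raise ValueError(f"unknown statistic {statistic!r}; choose from {RESULT_COLUMNS[2:]}")
        long = self.to_long()
        return long.pivot(index="ags_id", columns="fgs_id", values=statistic).loc[
            self.ags_ids, self.fgs_ids
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_network(path, keep_weights: bool = False, normalize: Optional[str] = None) -> Network:
    """Read a 2–3 column edge-list TSV into a :class:`Network`.

    Columns are node, node and an optional numeric confidence; fields may be
    separated by tabs or spaces and lines starting with ``#`` are comments.
    Duplicate pairs (either orientation) collapse to one edge; self-loops
    are dropped with a warning.  The third column is stored verbatim in
    ``Network.weights`` when ``keep_weights`` is set but is never used by
    any statistic.
    """
    path = Path(path)
    edges: List[Tuple[str, str]] = []
    weights: Dict[Tuple[str, str], float] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise DataError(
                    f"{path.name}:{lineno}: expected 2-3 fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if normalize == "upper":
                u, v = u.upper(), v.upper()
            edges.append((u, v))
            if keep_weights and len(fields) == 3:
                try:
                    weights[_canonical(u, v)] = float(fields[2])
                except ValueError as exc:
                    raise DataError(
                        f"{path.name}:{lineno}: non-numeric confidence {fields[2]!r}"
                    ) from exc
            n_lines += 1
    if n_lines == 0:
        raise DataError(f"{path.name}: no edges found")
    return Network(edges, weights=weights or None, name=path.name)


def read_gene_sets(
    path, format: str = "gmt", role: str = "FGS", normalize: Optional[str] = None
) -> GeneSetCollection:
    """Read a gene-set collection from a GMT file or a long 2-column TSV.

    GMT rows are ``set_id <TAB> description <TAB> member...``; the long
    format has one ``gene <TAB> set_id`` row per membership.  Members are
    deduplicated per set, set order is preserved, empty sets are dropped
    with a warning, and a duplicate set id is an error.
    """
    path = Path(path)
    if format not in ("gmt", "long"):
        raise ValueError(f"unknown gene-set format {format!r}")
    ordered: Dict[str, set] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "gmt":
                if len(fields) < 2:
                    raise DataError(f"{path.name}:{lineno}: GMT row needs id + description")
                set_id, members = fields[0], fields[2:]
                if normalize == "upper":
                    members = [m.upper() for m in members]
                if set_id in ordered:
                    raise DataError(f"{path.name}:{lineno}: duplicate set id {set_id!r}")
                ordered[set_id] = set(m for m in members if m)
            else:
                if len(fields) != 2:
                    raise DataError(f"{path.name}:{lineno}: expected 2 fields (gene, set-id)")
                gene, set_id = fields
                if normalize == "upper":
                    gene = gene.upper()
                ordered.setdefault(set_id, set()).add(gene)
    sets = []
    for set_id, members in ordered.items():
        if not members:
            logger.warning("gene set %r is empty and was dropped", set_id)
            continue
        sets.append(GeneSet(set_id, frozenset(members)))
    if not sets:
        raise DataError(f"{path.name}: no non-empty gene sets")
    return GeneSetCollection(sets, role=role, name=path.name)


def write_gmt(gsc: GeneSetCollection, path, description: str = "na") -> None:
    """Write a collection as GMT (members in sorted order for determinism)."""
    with open(path, "w") as fh:
        for gs in gsc:
            fh.write("\t".join([gs.set_id, description, *sorted(gs.members)]) + "\n")


def restrict_to_network(gsc: GeneSetCollection, net: Network) -> GeneSetCollection:
    """Intersect every set with the network's node set.

    Genes absent from the network carry no degree and cannot take part in
    edge counting, so they are removed before scoring.  Sets left empty are
    dropped with a warning; if nothing survives, that is an error.
    """
    nodes = net.nodes
    kept = []
    for gs in gsc:
        members = gs.members & nodes
        dropped = len(gs.members) - len(members)
        if dropped:
            logger.warning("set %r: %d gene(s) not in network dropped", gs.set_id, dropped)
        if not members:
            logger.warning("set %r is empty after network restriction; removed", gs.set_id)
            continue
        kept.append(GeneSet(gs.set_id, frozenset(members)))
    if not kept:
        raise DataError("all gene sets empty after network restriction")
    return GeneSetCollection(kept, role=gsc.role, name=gsc.name)


def degree_sum(net: Network, gs: GeneSet) -> int:
    """Sum of network degrees over the set members (``N_AGS`` / ``N_FGS``)."""
    total = 0
    for gene in gs.members:
        if gene not in net.adj:
            raise ValueError(f"gene {gene!r} not in network; restrict the set first")
        total += len(net.adj[gene])
    return total


def write_results(rm: ResultMatrix, path, layout: str = "long") -> None:
    """Write a result matrix as TSV.

    ``layout="long"`` emits one row per AGS–FGS pair with the fixed column
    order of :data:`RESULT_COLUMNS`; ``layout="wide:<statistic>"`` emits an
    AGS × FGS grid of the chosen statistic.  Floats use ``%.17g`` so a
    round-trip through :func:`read_results` is lossless.
    """
    if layout == "long":
        rm.to_long().to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif layout.startswith("wide:"):
        stat = layout.split(":", 1)[1]
        rm.to_wide(stat).to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_results(path) -> pd.DataFrame:
    """Read a long-layout result TSV back into a DataFrame ('#' lines skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"result file lacks columns {missing}")
    return df
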