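"""Synthetic inputs: scale-free networks, gene sets, expression matrices.

Everything the other modules consume can be generated here, seeded and
text-only: preferential-attachment networks (the parametric enrichment
null assumes a power-law degree distribution, which this mechanism
produces), uniformly random gene sets for null calibration, gene sets
planted as connectivity modules for positive controls, and two-group
expression-like matrices with a controlled fraction of differential genes
for exercising the AGS builders.

These generators emulate the statistical regime of real inputs - degree
heavy tails, set-size ranges, log2 fold-change effect sizes - not the
biology: real pathway collections overlap heavily and real networks carry
confidence structure, neither of which is modelled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .ags import ScoreMatrix
from .model import DataError, GeneSet, GeneSetCollection, Network

logger = logging.getLogger("netenrich")

__all__ = [
    "SynthSpec",
    "make_scalefree_network",
    "make_random_gene_sets",
    "make_planted_fgs",
    "make_expression_matrix",
]


@dataclass
class SynthSpec:
    """Parameters of one synthetic study condition.

    Network: ``n_nodes`` grown by preferential attachment with ``m`` edges
    per new node.  Gene sets: ``n_sets`` sets with sizes in ``set_sizes``;
    ``boost`` multiplies within-module edge density over background.
    Expression: ``n_genes`` x (2 groups x ``n_replicates``) matrix where a
    ``de_fraction`` of genes is shifted by ±``effect`` (log2 units) with
    Gaussian noise ``noise_sd``.  ``seed`` is mandatory - every generator
    is deterministic.
    """

    n_nodes: int = 2000
    m: int = 5
    n_sets: int = 30
    set_sizes: Tuple[int, int] = (10, 300)
    boost: float = 5.0
    n_genes: int = 2000
    n_replicates: int = 3
    de_fraction: float = 0.1
    effect: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.de_fraction < 0 or self.de_fraction > 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        for name in ("n_nodes", "m", "n_sets", "n_genes", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _gene_id(i: int) -> str:
    return f"g{i + 1:06d}"


def make_scalefree_network(n_nodes: int, m: int, seed: int = 0) -> Network:
    """Preferential-attachment (Barabasi-Albert) network with power-law tail.

    Node ids are ``g000001``-style.  The generator attaches each new node
    to ``m`` distinct existing nodes, so the edge count is exactly
    ``m * (n_nodes - m)``.
    """
    if not (n_nodes > m >= 1):
        raise ValueError("need n_nodes > m >= 1")
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(seed))
    return Network(
        ((_gene_id(u), _gene_id(v)) for u, v in g.edges()),
        name=f"ba_n{n_nodes}_m{m}_s{seed}",
    )


def make_random_gene_sets(
    net: Network,
    n_sets: int,
    sizes: Union[int, Tuple[int, int], Sequence[int]],
    seed: int = 0,
    prefix: str = "S",
    role: str = "FGS",
) -> GeneSetCollection:
    """Uniformly random node sets (the enrichment null / calibration input).

    ``sizes`` may be a single int, a ``(lo, hi)`` inclusive range sampled
    per set, or an explicit per-set size list.
    """
    rng = np.random.default_rng(seed)
    nodes = np.array(net.node_order())
    if isinstance(sizes, (int, np.integer)):
        size_list = [int(sizes)] * n_sets
    elif isinstance(sizes, tuple) and len(sizes) == 2:
        lo, hi = int(sizes[0]), int(sizes[1])
        size_list = [int(s) for s in rng.integers(lo, hi + 1, size=n_sets)]
    else:
        size_list = [int(s) for s in sizes]
        if len(size_list) != n_sets:
            raise ValueError("explicit size list length must equal n_sets")
    if max(size_list) > len(nodes):
        raise ValueError("requested set size exceeds node count")
    sets = []
    for i, s in enumerate(size_list):
        members = rng.choice(nodes, size=s, replace=False)
        sets.append(GeneSet(f"{prefix}{i + 1:03d}", frozenset(members.tolist())))
    return GeneSetCollection(sets, role=role, name=f"random_sets_s{seed}")


def make_planted_fgs(
    net: Network,
    n_sets: int,
    size_range: Tuple[int, int],
    boost: float = 5.0,
    seed: int = 0,
) -> Tuple[Network, GeneSetCollection]:
    """Plant connectivity modules: disjoint sets with boosted edge density.

    Each set receives extra internal edges and extra edges from members to
    a small shared neighbour pool until both densities reach about
    ``boost`` times the background edge probability - giving signal both
    for between-set enrichment and for member-versus-set benchmarking.
    Returns the augmented network and the sets; ``boost=1`` returns the
    network unchanged.
    """
    if boost < 1:
        raise ValueError("boost must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = np.array(net.node_order())
    n = len(nodes)
    lo, hi = int(size_range[0]), int(size_range[1])
    size_list = [int(s) for s in rng.integers(lo, hi + 1, size=n_sets)]
    if sum(size_list) + max(size_list) > n:
        raise DataError("cannot place disjoint sets: network too small")
    perm = rng.permutation(n)
    sets: List[GeneSet] = []
    pos = 0
    for i, s in enumerate(size_list):
        members = nodes[perm[pos : pos + s]]
        pos += s
        sets.append(GeneSet(f"M{i + 1:03d}", frozenset(members.tolist())))
    gsc = GeneSetCollection(sets, role="FGS", name=f"planted_s{seed}")
    if boost == 1:
        return net, gsc

    p_bg = 2.0 * net.n_total_edges / (n * (n - 1))
    new_edges = list(net.edges)
    edge_set = set(net.edges)
    used = set(perm[:pos])
    pool_candidates = nodes[[i for i in range(n) if i not in set(perm[:pos].tolist())]]
    for gs in sets:
        members = sorted(gs.members)
        s = len(members)
        # internal edges up to boost x background density
        target_in = int(round(boost * p_bg * s * (s - 1) / 2.0))
        have_in = sum(
            1 for a in range(s) for b in range(a + 1, s)
            if (min(members[a], members[b]), max(members[a], members[b])) in edge_set
        )
        guard = 0
        while have_in < target_in and guard < 50 * target_in + 100:
            guard += 1
            a, b = rng.choice(s, size=2, replace=False)
            u, v = members[int(a)], members[int(b)]
            key = (u, v) if u <= v else (v, u)
            if key not in edge_set:
                edge_set.add(key)
                new_edges.append(key)
                have_in += 1
        # edges to a shared neighbour pool of comparable size
        pool = rng.choice(pool_candidates, size=min(s, len(pool_candidates)), replace=False)
        target_out = int(round(boost * p_bg * s * len(pool)))
        have_out = 0
        guard = 0
        while have_out < target_out and guard < 50 * target_out + 100:
            guard += 1
            u = members[int(rng.integers(0, s))]
            v = str(pool[int(rng.integers(0, len(pool)))])
            key = (u, v) if u <= v else (v, u)
            if key not in edge_set:
                edge_set.add(key)
                new_edges.append(key)
                have_out += 1
    boosted = Network(new_edges, name=f"{net.name}#planted")
    return boosted, gsc


def make_expression_matrix(spec: SynthSpec) -> Tuple[ScoreMatrix, pd.DataFrame]:
    """Two-group expression-like matrix with planted differential genes.

    Genes have baseline log2 abundances ~ N(8, 2); a ``de_fraction`` of
    them is shifted by ±``effect`` in group B.  Columns are named
    ``A_r1..A_rK, B_r1..B_rK``.  Returns the matrix (no companion p-values)
    and a truth table with columns gene, is_de, true_lfc, so AGS builders
    can be scored for recall against the planted labels.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [_gene_id(i) for i in range(spec.n_genes)]
    n_de = int(round(spec.de_fraction * spec.n_genes))
    if spec.de_fraction > 0 and n_de < 1:
        logger.warning("de_fraction x n_genes < 1: no differential genes planted")
    base = rng.normal(8.0, 2.0, size=spec.n_genes)
    lfc = np.zeros(spec.n_genes)
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    lfc[de_idx] = spec.effect * rng.choice([-1.0, 1.0], size=n_de)
    cols = {}
    for r in range(spec.n_replicates):
        cols[f"A_r{r + 1}"] = base + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
    for r in range(spec.n_replicates):
        cols[f"B_r{r + 1}"] = base + lfc + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
    frame = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame({"gene": genes, "is_de": lfc != 0.0, "true_lfc": lfc})
    return ScoreMatrix(frame), truth
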