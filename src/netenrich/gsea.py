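"""Overlap-based gene-set enrichment (Fisher's exact test), the comparator.

Where network enrichment counts edges between two sets, classical
binomial GSEA counts shared genes: for AGS A and FGS F within a gene
universe U the 2x2 table is

    a = |A n F|,  b = |A \\ F|,  c = |F \\ A|,  d = |U| - a - b - c

and the one-sided enrichment p-value is the hypergeometric upper tail
P(X >= a).  The odds ratio is the sample (a*d)/(b*c), with a Haldane 0.5
added to every cell when any cell is zero.  q-values are
Benjamini-Hochberg over all AGS x FGS pairs jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import pandas as pd
from scipy import stats as sps

from .enrich import bh_adjust
from .model import DataError, GeneSet, GeneSetCollection, Network

logger = logging.getLogger("netenrich")

__all__ = ["GseaStats", "GseaResult", "gsea_render"]

GSEA_COLUMNS = ["ags_id", "fgs_id", "overlap", "odds_ratio", "p", "q"]


@dataclass
class GseaStats:
    ags_id: str
    fgs_id: str
    overlap: int
    odds_ratio: float
    p: float
    q: float = float("nan")


@dataclass
class GseaResult:
    cells: List[GseaStats]
    metadata: dict = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.ags_id, c.fgs_id, c.overlap, c.odds_ratio, c.p, c.q) for c in self.cells],
            columns=GSEA_COLUMNS,
        )

    def get(self, ags_id: str, fgs_id: str) -> GseaStats:
        for c in self.cells:
            if c.ags_id == ags_id and c.fgs_id == fgs_id:
                return c
        raise KeyError((ags_id, fgs_id))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def gsea_render(
    ags_coll: GeneSetCollection,
    fgs_coll: GeneSetCollection,
    universe: Optional[GeneSet] = None,
    net: Optional[Network] = None,
) -> GseaResult:
    """Fisher's-exact overlap enrichment for every AGS-FGS pair.

    The universe defaults to the network's node set when ``net`` is given,
    else to the union of all AGS and FGS genes; an explicit ``universe``
    overrides both.  Every set must be contained in the universe.
    """
    if universe is not None:
        uni = frozenset(universe.members)
        uni_label = universe.set_id
    elif net is not None:
        uni = frozenset(net.nodes)
        uni_label = f"network:{net.name}"
    else:
        uni = frozenset(ags_coll.all_genes() | fgs_coll.all_genes())
        uni_label = "union(AGS,FGS)"
    stray = (ags_coll.all_genes() | fgs_coll.all_genes()) - uni
    if stray:
        raise DataError(
            f"universe smaller than union of sets: {len(stray)} gene(s) outside it"
        )
    n_u = len(uni)
    cells: List[GseaStats] = []
    for ags in ags_coll:
        for fgs in fgs_coll:
            a = len(ags.members & fgs.members)
            b = len(ags.members) - a
            c = len(fgs.members) - a
            d = n_u - a - b - c
            # P(X >= a) with X ~ Hypergeom(|U|, |A|, draws=|F|)
            p = float(sps.hypergeom.sf(a - 1, n_u, len(ags.members), len(fgs.members)))
            p = min(p, 1.0)
            cells.append(GseaStats(ags.set_id, fgs.set_id, a, _odds_ratio(a, b, c, d), p))
    qvals = bh_adjust([c.p for c in cells])
    for cell, q in zip(cells, qvals):
        cell.q = q
    return GseaResult(
        cells,
        metadata={"universe": uni_label, "universe_size": n_u,
                  "n_ags": len(ags_coll), "n_fgs": len(fgs_coll)},
    )
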