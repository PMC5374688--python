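"""Parametric network-enrichment statistic (chi-squared binomial, CSB).

For an altered gene set A and a functional gene set F on a network with
``N_total`` edges, the observed statistic is the number of edges running
between the two sets — edges internal to A or internal to F are never
counted.  Under the null that edges attach proportionally to degree, the
expected count is

    n_hat = N_A * N_F / (2 * N_total)

with ``N_A``, ``N_F`` the degree sums over set members.  Observed and
expected counts are compared with a one-degree-of-freedom chi-squared on
the 2x1 split (between-set edges vs all other edges), and the signed
Gaussian z equivalent carries the direction: z < 0 means depletion.

The chi-squared comes in two variants.  ``expected_denominator`` is the
Pearson form, dividing each squared deviation by its expectation; it is the
default because it is defined at n = 0, which is common for small sets.
``as_printed`` divides by the observed counts instead and is provided for
compatibility; where it is undefined (n = 0) the Pearson form is used for
that cell with a warning.

This approximation is unbiased on scale-free (power-law degree) networks;
for networks with strongly non-scale-free topology prefer the
randomization test in :mod:`netenrich.randomize`.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from scipy import stats as sps

from .model import (
    DataError,
    GeneSet,
    GeneSetCollection,
    NEAStats,
    Network,
    ResultMatrix,
    degree_sum,
)

logger = logging.getLogger("netenrich")

__all__ = [
    "ChiVariant",
    "Z_CAP",
    "count_connecting_edges",
    "expected_edges",
    "chi2_statistic",
    "pair_stats",
    "bh_adjust",
    "nea_render",
    "single_gene_fgs",
]

#: z-score cap used where the chi-squared would be infinite (n_hat = 0, n > 0);
#: 38 is roughly where the Gaussian tail underflows double precision.
Z_CAP = 38.0


class ChiVariant(str, Enum):
    """Denominator convention of the one-df chi-squared."""

    expected_denominator = "expected_denominator"  # Pearson; default
    as_printed = "as_printed"  # divide by observed counts

    @classmethod
    def coerce(cls, value) -> "ChiVariant":
        if isinstance(value, cls):
            return value
        aliases = {"pearson": cls.expected_denominator, "printed": cls.as_printed}
        if value in aliases:
            return aliases[value]
        return cls(value)


def count_connecting_edges(net: Network, ags: GeneSet, fgs: GeneSet) -> int:
    """Edges between AGS and FGS, excluding within-AGS and within-FGS edges.

    Only edges joining A\\F to F\\A can satisfy the exclusion rule, so the
    count walks the adjacency of the smaller difference set.
    """
    a = ags.members if isinstance(ags, GeneSet) else frozenset(ags)
    f = fgs.members if isinstance(fgs, GeneSet) else frozenset(fgs)
    x = a - f
    y = f - a
    if len(y) < len(x):
        x, y = y, x
    total = 0
    for u in x:
        if u not in net.adj:
            raise ValueError(f"gene {u!r} not in network; restrict the set first")
        total += len(net.adj[u] & y)
    for v in y:
        if v not in net.adj:
            raise ValueError(f"gene {v!r} not in network; restrict the set first")
    return total


def expected_edges(
    net: Network, ags: GeneSet, fgs: GeneSet, strict_overlap: bool = False
) -> float:
    """Expected between-set edge count ``N_A * N_F / (2 * N_total)``.

    Degree sums are taken over the *full* sets even when A and F overlap
    (the exclusion rule applies to the observed count only); with
    ``strict_overlap`` the shared genes are removed from both degree sums.
    """
    if net.n_total_edges == 0:
        raise DataError("network has no edges")
    a, f = ags, fgs
    if strict_overlap:
        shared = ags.members & fgs.members
        if shared:
            a = GeneSet(ags.set_id, ags.members - shared)
            f = GeneSet(fgs.set_id, fgs.members - shared)
    n_hat = degree_sum(net, a) * degree_sum(net, f) / (2.0 * net.n_total_edges)
    if n_hat > net.n_total_edges:
        logger.warning(
            "expected edges %.1f exceed total edges %d for (%s, %s); "
            "the binomial approximation is unreliable here",
            n_hat,
            net.n_total_edges,
            ags.set_id,
            fgs.set_id,
        )
    return n_hat


def _safe_term(dev: float, denom: float) -> float:
    if denom == 0.0:
        return 0.0 if dev == 0.0 else math.inf
    return dev * dev / denom


def chi2_statistic(
    n: int, n_hat: float, n_total: int, variant: ChiVariant = ChiVariant.expected_denominator
) -> float:
    """One-df chi-squared on (between-set edges, all other edges).

    With ``!n = n_total - n`` and ``!n_hat = n_total - n_hat``:

    * ``expected_denominator``: ``(n-n_hat)^2/n_hat + (!n-!n_hat)^2/!n_hat``
    * ``as_printed``:           ``(n-n_hat)^2/n     + (!n-!n_hat)^2/!n``

    An infinite Pearson value (n_hat = 0 with n > 0) is capped at
    ``Z_CAP**2``; the printed form at n = 0 is undefined and falls back to
    the Pearson form for that cell.
    """
    variant = ChiVariant.coerce(variant)
    if n < 0 or n > n_total:
        raise ValueError(f"observed edges n={n} outside [0, n_total={n_total}]")
    if n_hat < 0:
        raise ValueError("expected edges must be non-negative")
    dev = n - n_hat
    not_dev = (n_total - n) - (n_total - n_hat)  # = -dev, kept for clarity
    if n == n_hat:
        return 0.0
    if variant is ChiVariant.as_printed and n == 0:
        logger.warning(
            "as_printed chi-squared undefined at n=0; using expected-denominator form"
        )
        variant = ChiVariant.expected_denominator
    if variant is ChiVariant.expected_denominator:
        chi2 = _safe_term(dev, n_hat) + _safe_term(not_dev, n_total - n_hat)
    else:
        chi2 = _safe_term(dev, float(n)) + _safe_term(not_dev, float(n_total - n))
    if math.isinf(chi2):
        return Z_CAP * Z_CAP
    return chi2


def pair_stats(
    net: Network,
    ags: GeneSet,
    fgs: GeneSet,
    variant: ChiVariant = ChiVariant.expected_denominator,
    strict_overlap: bool = False,
) -> NEAStats:
    """Full CSB statistics for one AGS-FGS pair (q left NaN).

    ``p`` is the upper tail of the chi-squared distribution with 1 df;
    ``z = sign(n - n_hat) * sqrt(chi2)``, i.e. the Gaussian quantile
    recovered from p with the sign coerced negative under depletion.
    """
    n = count_connecting_edges(net, ags, fgs)
    n_hat = expected_edges(net, ags, fgs, strict_overlap=strict_overlap)
    chi2 = chi2_statistic(n, n_hat, net.n_total_edges, variant)
    p = float(sps.chi2.sf(chi2, df=1))
    z = math.copysign(math.sqrt(chi2), n - n_hat) if chi2 > 0 else 0.0
    return NEAStats(
        ags_id=ags.set_id,
        fgs_id=fgs.set_id,
        n_edges=n,
        expected_edges=n_hat,
        chi2=chi2,
        z=z,
        p=p,
    )


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped at
    1, mapped back to the input order.  Each q >= its p.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    # divide by (rank/m) so the top rank multiplies by exactly 1.0 (keeps q >= p)
    ranked = p[order] / (np.arange(1, m + 1) / m)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# vectorised all-pairs counting
# ---------------------------------------------------------------------------


def _membership_matrix(gsc: GeneSetCollection, node_order: Sequence[str]) -> np.ndarray:
    index = {n: i for i, n in enumerate(node_order)}
    mat = np.zeros((len(gsc), len(node_order)), dtype=np.float64)
    for row, gs in enumerate(gsc):
        for gene in gs.members:
            try:
                mat[row, index[gene]] = 1.0
            except KeyError:
                raise ValueError(
                    f"gene {gene!r} of set {gs.set_id!r} not in network; restrict first"
                ) from None
    return mat


def _pair_edge_counts(
    eu: np.ndarray, ev: np.ndarray, amat: np.ndarray, fmat: np.ndarray
) -> np.ndarray:
    """Between-set edge counts for all AGS x FGS pairs on one edge list.

    For an edge (u, v) and sets A, F the contribution is 1 iff one endpoint
    lies in A\\F and the other in F\\A.  Expanding the indicator product
    gives four bilinear terms, each a matrix product over edges, so the
    whole grid costs a handful of (n_sets x n_edges) matmuls.  Counts are
    exact (integers well below 2**53).
    """
    au, av = amat[:, eu], amat[:, ev]
    fu, fv = fmat[:, eu], fmat[:, ev]
    a_in = au * av  # edge internal to the AGS
    f_in = fu * fv  # edge internal to the FGS
    counts = (
        au @ fv.T
        + av @ fu.T
        - (au + av) @ f_in.T
        - a_in @ (fu + fv).T
        + 2.0 * (a_in @ f_in.T)
    )
    return np.rint(counts).astype(np.int64)


def _count_matrix(
    net: Network, ags_coll: GeneSetCollection, fgs_coll: GeneSetCollection, jobs: int = 1
) -> np.ndarray:
    eu, ev = net.edge_arrays()
    order = net.node_order()
    amat = _membership_matrix(ags_coll, order)
    fmat = _membership_matrix(fgs_coll, order)
    if jobs <= 1 or len(ags_coll) < 2 * jobs:
        return _pair_edge_counts(eu, ev, amat, fmat)
    chunks = np.array_split(np.arange(len(ags_coll)), jobs)
    parts = Parallel(n_jobs=jobs)(
        delayed(_pair_edge_counts)(eu, ev, amat[idx], fmat) for idx in chunks if idx.size
    )
    return np.vstack(parts)


def nea_render(
    net: Network,
    ags_coll: GeneSetCollection,
    fgs_coll: GeneSetCollection,
    variant: ChiVariant = ChiVariant.expected_denominator,
    jobs: int = 1,
    strict_overlap: bool = False,
) -> ResultMatrix:
    """Score every AGS against every FGS and adjust q-values jointly.

    Collections must already be restricted to the network.  The edge
    counting step may be split over ``jobs`` parallel workers; the result
    is identical for any job count.  q-values come from a single BH pass
    over all cells of the matrix, so adding or removing sets changes q
    (but never p) of the remaining cells.
    """
    variant = ChiVariant.coerce(variant)
    if len(ags_coll) == 0 or len(fgs_coll) == 0:
        raise DataError("empty gene-set collection")
    if net.n_total_edges == 0:
        raise DataError("network has no edges")
    n_tests = len(ags_coll) * len(fgs_coll)
    if n_tests < 200:
        logger.warning(
            "only %d AGS-FGS tests; q-values are poorly estimated below a few hundred tests",
            n_tests,
        )
    counts = _count_matrix(net, ags_coll, fgs_coll, jobs=jobs)
    ags_sets = list(ags_coll)
    fgs_sets = list(fgs_coll)
    cells: List[NEAStats] = []
    for i, ags in enumerate(ags_sets):
        for j, fgs in enumerate(fgs_sets):
            n = int(counts[i, j])
            n_hat = expected_edges(net, ags, fgs, strict_overlap=strict_overlap)
            chi2 = chi2_statistic(n, n_hat, net.n_total_edges, variant)
            p = float(sps.chi2.sf(chi2, df=1))
            z = math.copysign(math.sqrt(chi2), n - n_hat) if chi2 > 0 else 0.0
            cells.append(
                NEAStats(ags.set_id, fgs.set_id, n, n_hat, chi2, z, p)
            )
    qvals = bh_adjust([c.p for c in cells])
    for cell, q in zip(cells, qvals):
        cell.q = q
    metadata = {
        "network": net.name,
        "n_total_edges": net.n_total_edges,
        "chi_variant": variant.value,
        "strict_overlap": strict_overlap,
        "n_ags": len(ags_coll),
        "n_fgs": len(fgs_coll),
    }
    return ResultMatrix(cells, metadata=metadata)


def single_gene_fgs(net: Network) -> GeneSetCollection:
    """One singleton FGS per network node (ids preserved verbatim).

    Network density gives even single genes enough incident edges to be
    scored, which has no analogue in overlap-based GSEA.
    """
    return GeneSetCollection(
        (GeneSet(node, frozenset((node,))) for node in net.node_order()), role="FGS"
    )
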