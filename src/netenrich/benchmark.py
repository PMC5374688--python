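"""Network-quality benchmark: leave-one-member ROC over FGS genes.

A good functional-coupling network should connect a pathway member to the
rest of its pathway more strongly than a random gene of the same degree.
The benchmark builds one positive test case per (gene, FGS) membership:
the gene g is held out and scored as a single-gene AGS against F \\ {g}.
For each positive, degree-matched genes outside F are scored against the
same reduced set as negatives.  Sweeping a threshold over the z scores
yields TP/FP/TN/FN counts, a ROC curve, and its area - the figure of merit
for comparing alternative networks on the same FGS collection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .enrich import ChiVariant, pair_stats
from .model import DataError, GeneSet, GeneSetCollection, Network

logger = logging.getLogger("netenrich")

__all__ = ["BenchmarkResult", "benchmark_network", "roc_auc"]


@dataclass
class BenchmarkResult:
    """Scored cases, threshold table, ROC points and AUC of one benchmark run."""

    cases: pd.DataFrame  # gene, fgs_id, truth, score
    thresholds: pd.DataFrame  # threshold, TP, FP, TN, FN, FPR, TPR
    roc: List[Tuple[float, float]]
    auc: float
    seed: int
    negatives_per_positive: int
    degree_tolerance: float
    n_skipped: int = 0


def roc_auc(cases: Iterable[Tuple[str, float]]) -> Tuple[pd.DataFrame, List[Tuple[float, float]], float]:
    """Threshold sweep over scored cases -> (threshold table, ROC points, AUC).

    ``cases`` yields (truth, score) with truth ``"positive"``/``"negative"``
    (booleans accepted).  Ties are grouped at one threshold; the trapezoidal
    area equals the Mann-Whitney pairwise-ordering statistic with ties
    counted half.
    """
    labels: List[bool] = []
    scores: List[float] = []
    for truth, score in cases:
        if isinstance(truth, str):
            labels.append(truth == "positive")
        else:
            labels.append(bool(truth))
        scores.append(float(score))
    y = np.array(labels, dtype=bool)
    s = np.array(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs at least one positive and one negative case")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # group tied scores: cumulative TP/FP at each distinct threshold
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y.size - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(~y_sorted)[idx]
    thr = s_sorted[idx]
    table = pd.DataFrame(
        {
            "threshold": thr,
            "TP": tp,
            "FP": fp,
            "TN": n_neg - fp,
            "FN": n_pos - tp,
            "FPR": fp / n_neg,
            "TPR": tp / n_pos,
        }
    )
    fpr = np.r_[0.0, table["FPR"].to_numpy()]
    tpr = np.r_[0.0, table["TPR"].to_numpy()]
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # defensive; last threshold takes all
        fpr = np.r_[fpr, 1.0]
        tpr = np.r_[tpr, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return table, roc_points, auc


def _degree_matched(
    degrees: dict, target: int, exclude: frozenset, tol: float
) -> List[str]:
    lo, hi = target * (1.0 - tol), target * (1.0 + tol)
    return sorted(g for g, d in degrees.items() if lo <= d <= hi and g not in exclude)


def benchmark_network(
    net: Network,
    fgs_coll: GeneSetCollection,
    negatives_per_positive: int = 1,
    degree_tolerance: float = 0.25,
    seed: int = 0,
    variant: ChiVariant = ChiVariant.expected_denominator,
) -> BenchmarkResult:
    """Leave-one-member ROC benchmark of a network against an FGS collection.

    One test case per FGS membership (a gene in several FGS yields several
    cases).  The held-out gene is removed from its set before scoring so
    the within-set exclusion rule cannot leak the answer.  Negatives are
    drawn (seeded) from non-members whose degree is within
    ``degree_tolerance`` (relative) of the positive's; an empty candidate
    pool doubles the tolerance up to four times before the case is skipped
    with a log entry.
    """
    fgs_coll = _check_restricted(net, fgs_coll)
    degrees = net.degree
    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = 0
    for fgs in fgs_coll:
        if len(fgs) < 2:
            logger.warning("FGS %r has < 2 members; skipped", fgs.set_id)
            continue
        members = sorted(fgs.members)
        for g in members:
            reduced = GeneSet(fgs.set_id, fgs.members - {g})
            pos = pair_stats(net, GeneSet(g, frozenset((g,))), reduced, variant=variant)
            rows.append((g, fgs.set_id, "positive", pos.z))
            tol = degree_tolerance
            cands: List[str] = []
            for _ in range(5):  # initial + up to 4 doublings
                cands = _degree_matched(degrees, degrees[g], fgs.members | {g}, tol)
                if cands:
                    break
                tol *= 2.0
                logger.warning(
                    "no degree-matched negative for %r (deg %d); tolerance doubled to %.2f",
                    g, degrees[g], tol,
                )
            if not cands:
                n_skipped += 1
                logger.warning("case (%r, %r) skipped: no negative candidate", g, fgs.set_id)
                continue
            k = min(negatives_per_positive, len(cands))
            chosen = rng.choice(np.array(cands, dtype=object), size=k, replace=False)
            for neg_gene in chosen:
                neg = pair_stats(
                    net, GeneSet(str(neg_gene), frozenset((str(neg_gene),))), reduced,
                    variant=variant,
                )
                rows.append((str(neg_gene), fgs.set_id, "negative", neg.z))
    if not rows:
        raise DataError("no benchmark cases could be built")
    cases = pd.DataFrame(rows, columns=["gene", "fgs_id", "truth", "score"])
    table, roc_points, auc = roc_auc(zip(cases["truth"], cases["score"]))
    return BenchmarkResult(
        cases=cases,
        thresholds=table,
        roc=roc_points,
        auc=auc,
        seed=seed,
        negatives_per_positive=negatives_per_positive,
        degree_tolerance=degree_tolerance,
        n_skipped=n_skipped,
    )


def _check_restricted(net: Network, fgs_coll: GeneSetCollection) -> GeneSetCollection:
    for gs in fgs_coll:
        for gene in gs.members:
            if gene not in net.adj:
                raise ValueError(
                    f"gene {gene!r} of FGS {gs.set_id!r} not in network; restrict first"
                )
    return fgs_coll
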