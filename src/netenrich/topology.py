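"""Network topology diagnostics: scale-freeness and second-order structure.

The parametric enrichment null is only unbiased on scale-free networks, so
before trusting CSB scores a network should be inspected for a power-law
degree distribution (``connectivity``) and for second-order degree biases
such as high-degree nodes avoiding each other (``topology2nd``).  Both are
visual-inspection aids: the log-log fit is a plain least-squares line on
the raw degree histogram, not a formal power-law test.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import stats as sps

from .model import DataError, Network

logger = logging.getLogger("netenrich")

__all__ = ["TopologySummary", "connectivity", "topology2nd"]


@dataclass
class TopologySummary:
    """Degree-distribution and neighbour-degree diagnostics.

    ``loglog_slope``/``loglog_r2`` describe the least-squares line through
    (log10 degree, log10 node count); both are None when fewer than three
    distinct degrees exist.  ``assortativity`` is the Pearson correlation
    of degrees across edge endpoints (both orientations); None when the
    degree variance over endpoints is zero (e.g. regular graphs).
    """

    degree_hist: Dict[int, int] = field(default_factory=dict)
    loglog_slope: Optional[float] = None
    loglog_r2: Optional[float] = None
    neighbor_degree: Dict[int, float] = field(default_factory=dict)
    assortativity: Optional[float] = None


def connectivity(net: Network, log_binned: bool = False) -> TopologySummary:
    """Degree histogram plus a log-log power-law fit.

    With ``log_binned`` the histogram is aggregated into factor-2 degree
    bins before fitting (less noisy in the sparse tail, at the cost of
    resolution); the default fits the raw degree-count pairs.  A power law
    p(k) ~ k**-gamma shows up as slope ~ -gamma.
    """
    hist = dict(sorted(Counter(len(nb) for nb in net.adj.values()).items()))
    summary = TopologySummary(degree_hist=hist)
    pairs = [(d, c) for d, c in hist.items() if d > 0]
    if log_binned and pairs:
        binned: Dict[int, list] = {}
        for d, c in pairs:
            binned.setdefault(int(math.floor(math.log2(d))), []).append((d, c))
        pairs = [
            (
                float(np.exp(np.mean([math.log(d) for d, _ in grp]))),
                sum(c for _, c in grp) / len(grp),
            )
            for grp in binned.values()
        ]
    if len(pairs) < 3:
        logger.warning("fewer than 3 distinct degrees; log-log fit not reported")
        return summary
    x = np.log10([d for d, _ in pairs])
    y = np.log10([c for _, c in pairs])
    fit = sps.linregress(x, y)
    summary.loglog_slope = float(fit.slope)
    summary.loglog_r2 = float(fit.rvalue**2)
    return summary


def topology2nd(net: Network) -> TopologySummary:
    """Mean neighbour degree per degree class, plus degree assortativity.

    For each degree d the reported value is the mean over nodes of degree
    d of the mean degree of their neighbours.  Falling neighbour degree
    with rising d signals the avoidance of high-degree/high-degree contacts
    that degree-preserving rewiring does not fully control for.
    """
    if net.n_total_edges == 0:
        raise DataError("edgeless network: no second-order structure to report")
    deg = net.degree
    per_degree: Dict[int, list] = {}
    for node, neighbors in net.adj.items():
        mean_nb = sum(deg[v] for v in neighbors) / len(neighbors)
        per_degree.setdefault(deg[node], []).append(mean_nb)
    neighbor_degree = {
        d: float(np.mean(vals)) for d, vals in sorted(per_degree.items())
    }
    xs, ys = [], []
    for u, v in net.edges:
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    xs_arr = np.array(xs, dtype=float)
    ys_arr = np.array(ys, dtype=float)
    assort: Optional[float]
    if np.std(xs_arr) == 0.0:
        logger.warning("zero degree variance over endpoints; assortativity undefined")
        assort = None
    else:
        assort = float(np.corrcoef(xs_arr, ys_arr)[0, 1])
    return TopologySummary(
        degree_hist=dict(sorted(Counter(deg.values()).items())),
        neighbor_degree=neighbor_degree,
        assortativity=assort,
    )
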