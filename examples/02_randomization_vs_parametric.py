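"""Convergence of the randomization z-test toward the parametric statistic.

The randomization (NRZ) null needs many degree-preserving rewirings to
estimate each pair's mean and spread of between-set edge counts; the
parametric (CSB) statistic needs none.  This script scores all pairs of a
module-structured gene-set collection - halves of planted connectivity
modules, so many pairs carry genuine signal, as real pathway collections
do - with both methods and prints the Spearman correlation of their
log10 p-values as the number of rewirings N grows.  The correlation rises
steeply with N: with enough randomizations the two methods agree almost
perfectly, but at small N (the only affordable regime for large studies)
the randomization estimate is still noisy.  Runs a few minutes.
"""

from netenrich import (
    GeneSet,
    GeneSetCollection,
    convergence_experiment,
    make_planted_fgs,
    make_scalefree_network,
)

net = make_scalefree_network(n_nodes=2000, m=5, seed=1)
net, modules = make_planted_fgs(net, n_sets=15, size_range=(20, 60), boost=8.0, seed=1)

halves = []
for gs in modules:
    members = sorted(gs.members)
    mid = len(members) // 2
    halves.append(GeneSet(gs.set_id + "a", frozenset(members[:mid])))
    halves.append(GeneSet(gs.set_id + "b", frozenset(members[mid:])))
collection = GeneSetCollection(halves)

summary, pairs = convergence_experiment(
    net, collection, n_list=[3, 10, 30, 100, 300], seed=1
)
print(summary.to_string(index=False))
print()
print(
    "spearman_r: rank agreement between randomization and parametric "
    "log10 p over usable set pairs; n_excluded counts pairs with no "
    "observed edge or no permutation spread.  The pairs table also carries "
    "the factors that bias the randomization at small N (set size sum, "
    "degree sum, edge count) with tertile strata for Q-Q inspection."
)
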