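# Methods

## Model

Network enrichment analysis treats a global undirected functional-coupling
network as fixed and asks, for an altered gene set *A* and a functional
gene set *F*, whether more edges run between them than a degree-respecting
null predicts.  The observed statistic `n` counts edges with one endpoint
in *A* and the other in *F*; edges internal to *A* or to *F* are excluded,
so only edges joining `A\F` to `F\A` contribute.  The null holds the
degree of every node fixed and assumes edge stubs pair proportionally to
degree, giving the expectation

    n_hat = N_A * N_F / (2 * N_total)

with `N_A`, `N_F` the degree sums over the (full) sets and `N_total` the
network's edge count.  Observed and expected are compared by a
one-degree-of-freedom chi-squared on the two-bin split (between-set edges
vs all other edges); the signed Gaussian equivalent `z = sign(n − n_hat)
· sqrt(chi2)` recovers direction, with negative `z` meaning depletion.
P-values are the chi-squared upper tail; q-values are Benjamini–Hochberg
over all cells of one AGS × FGS matrix jointly (a warning is emitted
below 200 tests, where FDR estimation is unreliable).

Two chi-squared conventions are implemented.  The default
`expected_denominator` (Pearson) form divides each squared deviation by
its expectation and is defined at `n = 0`, which is common for small
sets.  The `as_printed` form divides by the observed counts `n` and
`!n = N_total − n`; it is kept for compatibility, and falls back to the
Pearson form, with a warning, where it is undefined (`n = 0`).  The two
differ numerically but agree in ordering for moderate deviations.
Degenerate cells with `n_hat = 0` and `n > 0` are capped at `z = 38`
(the Gaussian tail's double-precision underflow point).

Degree sums intentionally use the full sets even when *A* and *F*
overlap, while overlapping genes' edges never enter the observed count —
this mirrors the formula as conventionally stated.  A `strict_overlap`
mode that also removes shared genes from the degree sums is available but
off by default.

## Operating regime and its limits

The stub-pairing expectation is accurate when each set's degree sum is a
small fraction of all edge stubs and no single pair of hubs approaches
edge saturation (`d_u · d_v / 2N_total` well below 1).  Both conditions
hold in the intended use case — gene sets of tens-to-hundreds of members
on dense genome-scale networks — and both degrade on small sparse
networks, where `n_hat` overshoots the true rewiring mean for large sets
(hub saturation and within-set stub pairing are ignored by the formula).
The null-calibration checks in the test suite therefore use sets of
20–200 genes on a 5000-node synthetic network (sets ≤ 4 % of nodes), the
smallest scale that stays inside the regime; the convergence experiment
in `scripts/acceptance.py` deliberately also probes outside it (sets up
to 15 % of a 2000-node network), where the parametric-vs-randomization
agreement is visibly capped by this bias rather than by randomization
noise.  On networks that are not scale-free the same caveat applies more
strongly, and the randomization test should be preferred outright.

The chi-squared null on discrete small counts is conservative rather than
exactly uniform; the calibration test asserts only that the fraction of
nominal p < 0.05 under the null stays at or below ~3× nominal.

## Randomization test (NRZ)

The nonparametric comparator scores a pair as
`z = (n_obs − mean) / sd` with mean and sample standard deviation
(n−1 denominator) of the between-set edge count over `N` rewired network
instances; `p` is the two-sided Gaussian tail, matching the
two-directional character of the chi-squared p.  Rewiring is
Maslov–Sneppen double-edge swapping: `round(swaps_per_edge × N_total)`
accepted-or-rejected proposals, each picking two distinct edges and one
of the two reconnection orientations at random and rejecting self-loops
and duplicates.  `swaps_per_edge` defaults to 10, a standard mixing
heuristic (at 10 the edge Jaccard to the original network drops below
0.2 on synthetic scale-free graphs).  Permutation `i` is seeded
`seed + i`, so runs are reproducible, parallelizable, and prefix-stable:
a run at larger `N` extends a smaller one, which the convergence
experiment exploits by computing the count stack once at max(N).

Per-node degrees are conserved exactly under rewiring; second-order
structure (degree assortativity) is only approximately conserved, which
is a known, documented property of this randomization scheme — the
topology tests measure the drift rather than hiding it.  Pairs whose
permutation counts never vary are flagged (`sd_zero`), get `z = NaN`,
and are excluded (and counted) in the convergence correlations.

The convergence experiment scores one collection against itself
all-vs-all with both methods and reports, per `N`, the Spearman rank
correlation of log10 p-values over usable pairs (defined z, at least one
observed edge).  Log p-values come from `logsf`, not `sf`, so deep tails
do not underflow into ties.  The per-pair table carries the three
factors that bias NRZ at small `N` — set-size sum, degree-sum sum, and
the observed edge count — each with tertile strata labels for Q-Q-style
inspection.  With module-structured collections (pairs carrying genuine
connectivity signal, as real pathway collections have) the correlation
climbs steeply with `N` and approaches 1; with uniformly random sets the
asymptote is instead set by the parametric bias described above
(`examples/02` and the acceptance script print both regimes' numbers).

## AGS construction

Builders operate per column of a genes × samples score matrix (typically
log2 fold changes, used exactly as given — no internal normalization):
`ags_top(n)` takes the `n` largest by |score| with ties broken toward
the lexicographically smaller gene id; `ags_significant(cutoff, alpha)`
takes |score| strictly greater than `cutoff`, optionally intersected
with companion adjusted p-values ≤ `alpha` (non-strict); `ags_toprandom`
is the seeded size-matched random control; `mutations2ags` converts a
(sample, gene) table to one set per sample.  NaN scores are dropped per
column with a logged count.

## GSEA comparator

Overlap-based enrichment uses the one-sided hypergeometric upper tail
P(X ≥ a) on the 2×2 table of set membership within a gene universe —
network nodes when a network is supplied, else the union of all sets.
The odds ratio is the sample (a·d)/(b·c) with a Haldane 0.5 correction
when any cell is zero; q-values are BH over all pairs.

## Network benchmark

One test case per FGS membership: the held-out gene is removed from its
set before being scored as a single-gene AGS against the remainder
(keeping it in would excise its edges via the within-set exclusion and
leak the answer).  Each positive is paired with `negatives_per_positive`
(default 1) genes sampled outside the set with degree within ±25 %
(relative) of the positive's; an empty candidate pool doubles the window
up to four times before the case is skipped with a log entry.  The ROC
is a threshold sweep over the z scores with ties grouped; the
trapezoidal AUC equals the Mann–Whitney pairwise-ordering statistic.

## Synthetic data

Networks are preferential-attachment (Barabási–Albert) graphs — the
power-law degree property the parametric null assumes, produced by the
simplest standard mechanism.  Planted modules add within-set edges and
member-to-shared-pool edges until both densities reach `boost` × the
background edge probability, giving signal both for between-set
enrichment and for the member-vs-set benchmark; `boost = 1` is an exact
no-op.  Expression matrices draw per-gene baselines from N(8, 2) on the
log2 scale, shift a `de_fraction` of genes by ±`effect` (default 4, a
16-fold change, with `noise_sd` 0.5 — a strong-signal regime chosen so
builder recall is a property of the builder, not of a marginal detection
problem), and return ground-truth labels.  All generators are
deterministic under a mandatory seed.  These fixtures emulate the
statistical regime of real inputs, not the biology: real pathway
collections overlap heavily, real networks carry confidence weights and
non-power-law components, and real expression has correlated genes —
passing tests demonstrate correctness of the machinery, not performance
on any real network.

## Problem sizes and numerical choices

Test and acceptance runs use 500–5000-node networks, 10–30 sets per
collection, and up to 300 rewirings — sizes at which every check runs in
seconds to a couple of minutes while keeping ≥ 900 pairs for calibration
and convergence statistics.  Edge counting over a whole AGS × FGS grid
is vectorized as four boolean-mask matrix products per edge list (exact:
all counts are small integers in float64); the scalar per-pair counter
and a brute-force edge loop serve as oracles in the tests.  Results are
independent of the `jobs` parallelization parameter by construction
(fixed chunking, order-preserving concatenation), and output TSVs print
floats at 17 significant digits so round-trips are lossless.
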