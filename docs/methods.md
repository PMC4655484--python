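# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `paleoshift`, in the order the pipeline runs them.

## Ages and time bins

All ages are in Ma before present; larger is older. A time scale is an
ordered, contiguous sequence of bins, oldest first; geological stages are
split into early/late substages at their temporal midpoints. *Presence* of
a lineage in a bin always means positive-duration overlap, so a range that
merely touches a bin boundary does not count. *Point events* (a
cladogenesis age, a last appearance) at a shared boundary belong to the
older bin: a bin contains ages `young_bound <= a < old_bound`, the oldest
bin is closed at its old bound, and the window's closing edge falls in the
youngest bin. One consequence used throughout: a taxon whose last
appearance sits exactly at the window's young edge is treated as extant at
window close and never counted as an extinction.

## Time calibration

`chrono.calibrate` implements the standard first-appearance calibration:
each internal node is placed at the maximum first-appearance datum (FAD)
among its descendant tips, and each tip branch ends at its taxon's last
appearance (LAD). Zero-length internal branches are then expanded to a
configurable minimum duration (default 1 Ma) by pushing ancestors older in
a single post-order pass; nodes are never moved younger than their base
age, and tip branches are exempt because a LAD is data, not a free
parameter. The portion of a tip branch older than its FAD is the taxon's
ghost lineage and is non-negative by construction.

This calibration can only compress true divergence times: a node whose
children are both internal has no descendant tip whose FAD reaches back to
its split, so its assigned age is strictly younger than the true age. The
synthetic-data tests assert exactly this one-sided behaviour.

Polytomies are resolved by uniform random refinement (random-edge
insertion, which is uniform over rooted labeled shapes), with a recorded
seed; downstream shift calls are taken as the consensus over replicate
resolutions, matching clades by their subtended tip-label sets.

## Shift statistics and their null

Under the equal-rates Markov (ERM) model the two daughter sizes of an
n-tip clade follow the uniform split law (each ordered split has
probability 1/(n−1)). The *surprise* of an observed split (l, r), l ≥ r,
is S = −ln min(1, 2(n−l)/(n−1)), the negative log tail probability. For
the larger child c of node i:

    delta1(c) = S(i)
    delta2(c) = max(0, S(i) − S(c))

delta2 discounts parent-level imbalance already explained by imbalance at
c itself and is assigned to the more speciose daughter — the branch along
which a rate increase would be inferred. Nodes with fewer than 3
descendant tips carry no information (the split of 2 is forced); ties in
daughter size are maximally balanced splits with S = 0.

Monte-Carlo p-values: for a scored node with parent clade size n, the null
is the distribution of the same statistic at the larger root child of ERM
trees of n tips. Because an ERM clade of known size is itself ERM, that
statistic depends only on the root split and the larger child's own split,
so null draws are generated by two draws from the split law (O(1) per
draw); distributional identity with statistics scored on fully simulated
topologies is property-tested. Ties count toward the tail and the
estimator is +1-corrected, p = (1 + #{null ≥ obs})/(n_sims + 1), so p > 0
always. Defaults: 10⁴ null draws (configurable), no multiple-testing
correction (Benjamini–Hochberg available behind a flag), significant
p < 0.05, substantial 0.05 ≤ p < 0.1 (the boundary value is classed
substantial).

**Calibration and its limits.** The null statistic is discrete. At clade
size 64 the achievable p-values are dense below 0.05 and the test is
calibrated: the measured root-node rejection rate on ERM trees is within
binomial error of the nominal 5%. At small clade sizes the test is
*strictly conservative*: at n = 4 the smallest achievable p is ≈ 2/3, and
below n ≈ 40 no split can reach p < 0.05, so the rejection rate pooled
over all nodes of a tree is far below nominal. This is inherent to a
discrete tail statistic with a conservative tie rule, and it means small
clades can never falsely light up — at the price of no power there.

## Time-sliced series

Each substage slice retains the tips whose lineage interval — branch
origin (ghost included) down to LAD — overlaps the bin with positive
duration; unifurcations are suppressed and node ages kept. The per-bin
mean delta2 is taken over *all* scored nodes of the slice (zero when none),
so the series reflects magnitude and number of shifts jointly; a
detected-only variant is available behind a flag. Slices with fewer than 3
tips contribute zeros.

## Diversity, rates, sampling

The phylogenetic diversity estimate (PDE) of a bin counts the branch
segments of the calibrated tree crossing it (plus zero-length branches
whose point event falls in it). Origination events are cladogenesis ages
in the bin; extinction events are tip LADs in the bin, excluding
window-close survivors; per-lineage rates divide events by the bin's PDE
(empty bins give 0).

Because the denominator counts branch segments and each within-bin split
closes one segment and opens two, the exact expectation of the pooled
ratio estimator under a birth–death process with speciation λ and
extinction μ over bins of width Δt is

    E[ext rate] = μ·g / (1 + 2λg),   g = (e^{(λ−μ)Δt} − 1)/(λ−μ),

and λ·g/(1+2λg) for origination — equal to μΔt and λΔt to first order in
Δt. The rate-recovery benchmark therefore simulates complete-sampling
birth–death trees (λ = 0.3, μ = 0.2 per Ma, 12-Ma window from two crown
lineages, 0.25-Ma bins, 100 replicates, unconditioned on survival so the
expectations hold exactly) and checks the pooled estimates against this
expectation to 5% and against the first-order reading to 20% (the
branch-segment factor alone is ≈ 13% at these settings).

The sampling proportion of a bin is
`s = n_observed / (n_observed + n_ghost)`, where a branch crossing the bin
counts as observed iff the tip's [FAD, LAD] span overlaps the bin along
that branch; ghost portions of tip branches and all internal branches
count as ghost (they carry no observed range), and bins crossed by nothing
default to s = 1. The default rate correction multiplies each raw rate by
s — a damping that discounts bins whose diversity is mostly inferred
rather than observed; the correction is pluggable (identity available), so
alternative formulas can be dropped in. Mass-extinction flags mark bins
whose corrected extinction rate is strictly above 0.30. Rate tables from
replicate trees are combined by element-wise means.

## Ancestral states and trait groups

Binary codings evolve as a two-state continuous-time Markov chain with
rates q01, q10 per Ma on the calibrated durations; P(t) is the closed-form
2×2 exponential. Tip likelihoods use Felsenstein pruning; marginal node
probabilities use the standard up–down pass at the ML rates, which equals
brute-force summation over internal-state assignments (tested to 1e-10 on
all labeled shapes of up to 5 tips plus sampled 6-tip shapes over a rate
grid). The root prior is uniform by default (stationary behind a flag);
the default rate model is equal-rates (one parameter, appropriate for
sparse binary paleo-codings), with all-rates-different available.
Optimization is bounded on log-rates (1e-9 to 50 per Ma — far beyond
saturation on Ma-scale branches); ARD uses three starts of L-BFGS-B.
Impossible configurations (conflicting states across zero-length branches
at zero rates) return −inf rather than raising.

Lineage groups are hereditary: a branch belongs to the trait group iff its
parent node (or any ancestor) has P(state 1) above the cutoff (default
0.5), or it is a trait-positive tip under a negative parent — "descended
from" a trait-positive ancestor, robust to later reversals; a strict-state
variant is flagged. Group origination series attribute each cladogenesis
event to the group of the branch carrying it; the root's event counts only
when both root branches fall in the same subset, so group + complement
event counts can undercount the full tree by at most that one event, and
lineage counts partition the PDE exactly.

## Model comparison

The delta2 series is regressed on the rate series by GLS with AR(1)
errors, fitted by full maximum likelihood (β and σ² profiled out, scalar
search over φ ∈ (−0.99, 0.99)); ML rather than REML so log-likelihoods are
comparable across fixed-effect structures. Six candidate models: null
(intercept only; a fixed-mean variant is available), extinction,
origination, mass-extinction indicator, origination + extinction,
origination + mass-extinction. The parameter count k covers identifiable
coefficients plus σ² and φ, AIC = 2k − 2ln L, and Akaike weights are
normalized relative likelihoods. A rank-deficient design (e.g. a
mass-extinction indicator that never fires, collinear with the intercept)
collapses onto its nested sub-model with k reduced to the design rank, so
the comparison never crashes on degenerate windows. Two facts worth
knowing when reading recovery simulations: a nested superset of the true
model out-ranks it whenever its spurious extra coefficient gains more than
one log-likelihood unit (a χ²₁-tail event of probability ≈ 0.16,
independent of noise level), and a sparse binary indicator can overfit a
handful of bins; near-certain recovery of the exact true model is
therefore not attainable by AIC, only large-majority recovery.

The random forest (scikit-learn, 500 trees, mtry = p/3, bootstrap)
reports `pct_mse` — the percent increase in out-of-bag MSE when one
predictor's values are permuted on each tree's out-of-bag samples —
alongside mean-decrease-in-impurity and the out-of-bag R². Out-of-bag
index sets are reconstructed from each tree's recorded random state and
verified against the forest's own OOB predictions in the tests.

## The synthetic generator

`synthdata` simulates a crown birth–death process forward in time by the
Gillespie algorithm: two lineages start at the window's old edge; events
are cladogenesis (λ), extinction (μ) and trait flips (q01/q10), all
per-lineage; scheduled events interleave exactly by memorylessness.
Rate shifts switch one extant lineage (chosen uniformly, or uniformly
among trait-positive lineages) and are inherited by its descendants.
Extinction pulses are instantaneous survival lotteries whose probabilities
depend on the trait state. Fossil sampling overlays a Poisson process
(rate r per lineage-Ma) on each tip branch; a taxon's FAD/LAD are its
extreme sample ages, unsampled tips are pruned, and lineages alive at
window close are always observed there (their survival is known). Ghost
lineages and range truncation thus arise mechanically, not by fiat.

Preset conditions (all rates per Ma; window 320–260 Ma, analysis stages
300–260 Ma split into 5-Ma substages — the pre-300 interval is a growth
phase excluded from analysis because near-empty bins yield extreme rate
ratios from denominators of 2–5 lineages):

- **erm-null** — λ = 0.1, μ = 0.04, q01 = q10 = 0.02, r = 0.5; the
  homogeneous control.
- **clade-shift** — as above, plus one uniformly chosen lineage switching
  to 5λ at 270 Ma. The 10-Ma post-shift interval lets the clade reach
  roughly 5–10× its sister, which is what the tail-probability test needs
  to resolve a shift; placement power (consensus shift at or adjacent to
  the true node) is ≈ 0.65 across seeds.
- **trait-buffered-pulse** — a protracted three-phase extinction episode
  (272, 268, 264 Ma) whose per-phase survival lotteries compound to 0.8
  for trait-positive vs 0.2 for trait-negative lineages, followed by a 2λ
  radiation seeded in a trait-positive survivor (sampling r = 1.0; true
  tip count conditioned to 60–500, the standard practice of conditioning
  birth–death simulations on size). The episodic, multi-phase design
  mirrors protracted biotic crises; the trait-linked radiation implements
  the buffered-survivor mechanism — the innovation does not accelerate
  cladogenesis when it appears, it saves its bearers at the crisis, and
  their diversification is deferred to it.

What the generator does *not* emulate: diversity-dependent or
environment-driven rates, time-varying fossil-sampling rates, anagenetic
taxonomy (taxa are tip branches), and geographic structure. Passing tests
therefore demonstrate correctness of the estimators under the stated
birth–death-with-pulses world, not robustness to those real-data features.

### A structural caveat on the pulse scenario

Two findings from the design of the end-to-end scenario are worth stating
because they are properties of the method, not bugs. First, an
instantaneous trait-dependent survival lottery alone leaves almost no
trace in the mean-delta2 series: independent per-lineage thinning of an
ERM-shaped tree is still ERM-shaped, and a fully extinguished monophyletic
block disappears from later slices without leaving imbalance (its
attachment node is suppressed as a unifurcation). Detectable topological
signal requires the survivors' subsequent radiation. Second, the delta2
response necessarily *lags* the extinction episode (imbalance becomes
visible only after differential loss), and tree imbalance *is*
differential origination, so in a contemporaneous six-model GLS comparison
on a single synthetic episode the origination and indicator models compete
strongly with the graded extinction model. In this generator the
mean-delta2 peak lands in the extinction episode in about 65% of datasets,
but the extinction model takes the top Akaike weight in only ~15–20% —
recovering that ranking appears to require a record with several
extinction events of varying magnitude, as in the empirical case the
pipeline was built for, rather than one engineered episode.

## Benchmark problem sizes

The reproducibility benchmarks (`paleoshift.evaluation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) run at: split-law
analytics to n = 200 exactly; simulator goodness-of-fit at 10⁵ draws for
n = 4…12; test calibration on 10³ ERM 64-tip trees with 10³ null draws
each; placement power over 50 clade-shift datasets at 10⁴ null draws;
Mk enumeration over all shapes to 5 tips plus 40 sampled 6-tip shapes on a
3×3 rate grid; rate recovery over 100 birth–death replicates; and 25
end-to-end pulse datasets at 2×10³ null draws.
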