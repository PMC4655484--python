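# paleoshift

Diversification-rate shifts, origination/extinction rates, and
trait-dependent survival in time-calibrated fossil phylogenies.

## The problem

In a clade's fossil record, bursts of diversification leave a topological
fingerprint: the tree becomes imbalanced where one lineage out-diversified
its sister. Tree-shape statistics locate such shifts without branch-length
or character data, by comparing each node's daughter-clade sizes against an
equal-rates Markov (ERM) null in which every lineage is equally likely to
split next. But a shift can be driven either by elevated origination in the
diversifying clade or by elevated extinction in its sister — and
distinguishing the two requires putting the shifts on a time axis and
comparing them with per-interval origination and extinction rates estimated
from the same calibrated tree.

`paleoshift` implements that whole workflow for researchers working with
stratigraphic-range-calibrated phylogenies of extinct clades:

- **`chrono`** — read Newick trees and taxon FAD/LAD range tables, resolve
  polytomies by uniform random refinement, and time-calibrate: each node is
  placed at the oldest first-appearance among its descendants, with a
  configurable minimum internal branch duration enforced by pushing
  ancestors older.
- **`shiftstat`** — the per-node shift statistics. For the larger daughter
  `c` of a node `i`, Δ₁(c) = S(i) and Δ₂(c) = max(0, S(i) − S(c)), where
  S = −ln P(a split at least as asymmetric | ERM); the ERM tail is
  min(1, 2(n−l)/(n−1)). Monte-Carlo p-values come from the ERM null at the
  parent clade's size; shifts with p < 0.05 are *significant* and
  0.05 ≤ p < 0.1 *substantial*; only shifts present in every
  polytomy-resolution replicate are reported.
- **`timeslice`** — split geological stages into early/late substages at
  their midpoints, prune the calibrated tree to each bin (a taxon belongs
  to a slice if its lineage, ghost portion included, overlaps the bin), and
  assemble the mean-Δ₂ series through time.
- **`paleorates`** — per-bin phylogenetic diversity estimates (PDE,
  counting ghost lineages and range extensions), per-lineage origination
  and extinction rates (events / lineages present), a ghost-lineage
  sampling proportion that damps rates in poorly sampled bins, and
  mass-extinction flags (corrected extinction rate > 30%).
- **`traits`** — two-state Mk ancestral-state inference (pruning
  likelihood, ML rates, marginal node probabilities) for binary ecological
  codings, hereditary "descended from a trait-positive ancestor" lineage
  groups, and per-group origination-rate series.
- **`modelsel`** — GLS regression of the Δ₂ series on rate predictors with
  AR(1) errors fitted by full maximum likelihood, six candidate models
  (null, extinction, origination, mass extinction, and two bivariate
  combinations) ranked by Akaike weights, plus random-forest regression
  with out-of-bag permutation importance.
- **`synthdata`** — a fossil birth–death generator with clade-specific rate
  shifts, trait evolution, trait-dependent extinction pulses, and Poisson
  fossil sampling, so every stage of the pipeline can be validated against
  known truth.

## Worked example

```python
import numpy as np
from paleoshift import chrono, shiftstat, synthdata

# a synthetic fossil record containing one clade with 5x speciation
bundle = synthdata.scenario_generator("clade-shift", seed=2)
ct = chrono.calibrate(bundle.topology, bundle.ranges, min_branch=1.0)
results = shiftstat.shift_pvalues(
    ct.tree, n_sims=10_000, rng=np.random.default_rng(0)
)
for r in sorted(results, key=lambda r: r.p_value)[:3]:
    print(f"clade of {len(r.clade):3d} tips  split {r.l}:{r.r}  "
          f"delta2={r.delta2:.2f}  p={r.p_value:.4f}  {r.klass}")
```

prints

```
clade of 160 tips  split 160:1  delta2=4.34  p=0.0010  significant
clade of  31 tips  split 31:1  delta2=2.23  p=0.0323  significant
clade of 198 tips  split 198:2  delta2=2.31  p=0.0425  significant
```

The dataset's manifest records the true shifted clade: 198 sampled tips,
exactly the third detection — the radiating clade sits against a 2-tip
sister, a split far more asymmetric than the ERM null expects. The two
stronger detections are nested inside it (the radiation's own early
splits), so all three mark the same diversification-rate increase: a shift
is inferred along the branch leading to the large clade.

The same bundle can be pushed through the whole pipeline from the shell:

```sh
paleoshift simulate --preset clade-shift --seed 2 --out data/
paleoshift run-all --config run.cfg     # calibrate -> shifts -> slices ->
                                        # rates -> traits -> model comparison
```

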