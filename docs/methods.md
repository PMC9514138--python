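# Methods

This note records the scientific and numerical choices behind the
package, in the spirit of a model-description appendix: what is assumed,
what is tunable, what the synthetic data does and does not emulate, and
where the design was genuinely open.

## Network model

Nodes are cortical regions (148 Destrieux parcels in the reference
design; any unique label set is accepted). Edges are nonzero partial
correlations of regional thickness across the subjects of a group,
selected by the graphical lasso

    max_Θ  log det Θ − tr(SΘ) − ρ‖Θ‖₁,off

on the **sample correlation matrix** S of standardized regions. Working
on the correlation scale makes ρ comparable across groups, datasets and
cohorts; a penalty quoted for covariance-scale data would not be. The
penalty applies to off-diagonal precision entries only (the common
convention, and the one scikit-learn uses, which the test suite exploits
as an independent numerical cross-check of the in-package solver).
"Nonzero" is operationalized as |partial correlation| > 1e−8 to absorb
solver noise. Networks are binarized and treated as undirected.

The solver is a numba-compiled block coordinate descent with duality-gap
stopping (absolute tolerance 1e−4, matching the cross-check) and warm
starts. Warm starting from the whole-sample solution is what makes
permutation inference affordable: the two group fits of each shuffle
typically converge in a few sweeps, ~0.3 ms at p = 40. A fit that cannot
reach the gap tolerance, or that loses positive definiteness (possible
for the off-diagonal-penalty convention when S is singular and ρ is very
small), raises an error carrying ρ and the iteration count; permutation
draws that fail this way are redrawn within a 2 × n_perm budget.

### Penalty selection

ρ is chosen by k-fold cross-validation of the held-out Gaussian
log-likelihood over a log-spaced grid (default 30 points in
[0.01, ρ_max], where ρ_max is the largest absolute off-diagonal sample
correlation — the smallest penalty giving an empty network). Two
methodological points, both deliberate:

* **Held-out scoring uses the training fold's scale.** Test-fold rows
  are centered and scaled by the *training* fold's means and SDs before
  forming the held-out second-moment matrix. Re-standardizing the test
  fold by its own statistics discards scale mismatch and measurably
  biases selection toward dense fits.
* **The one-standard-error rule is the default.** Plain
  maximum-likelihood CV is known to overselect edges for the graphical
  lasso — it optimizes prediction, not support recovery — and in the
  n ≲ p regime it drives ρ toward values (~0.05–0.07 at n = 114,
  p = 60) where networks are dense, noise-dominated and occasionally
  numerically unstable at group size. The 1SE rule (largest ρ within one
  SE of the CV optimum, as in glmnet) restores a sparsity level at which
  planted structure is actually expressed, and selects ρ ≈ 0.10–0.22 at
  these sizes — the same order as the ρ = 0.184 reported for real
  cortical-thickness data at p = 148, n = 114. `rule="max"` remains
  available.
* **k = 3 folds by default.** With roughly as many regions as subjects,
  the conditioning of the held-out second-moment matrix (test folds of
  ~38 subjects rather than ~23) matters more than the usual fold-count
  trade-off.

In the full pipeline one ρ serves every network (whole-group, per-group,
and every permutation re-fit). It is selected per timepoint at the true
sample size (n = 114) and averaged across the two timepoints; selecting
on the pooled 2n rows would tune the penalty to twice the sample size
actually used by the n/2-subject group fits and destabilize them.

## Graph parameters

* Global efficiency: mean over unordered pairs of 1/d(i, j);
  disconnected pairs contribute 0; computed with scipy's compiled BFS.
* Mean local efficiency: per node, the global efficiency of the subgraph
  induced by its neighbors (the node itself excluded); nodes of degree
  < 2 score 0 (standard convention).
* Modularity is *quantified as the mean participation coefficient*
  PC_i = 1 − Σ_s (k_is/k_i)² over a Louvain partition at resolution
  γ = 1; degree-0 nodes score 0 and all nodes enter the mean. The
  Newman–Girvan Q of the partition is carried as a diagnostic only.
  Interpretation contract, encoded in tests: **higher mean participation
  = less segregation between modules**.

Louvain runs through igraph's C implementation, seeded per call and
restarted 5 times (best modularity at the requested resolution kept) —
the usual remedy for the algorithm's node-order dependence. Partitions
are pure functions of (adjacency, resolution, seed, restarts); module
ids are relabeled contiguously by smallest member node.

## Group formation and inference

Behavioral component scores (four parenting components in the reference
design) are median-split into low/high groups; ties at the median are
assigned in stable subject-ID order to the currently smaller group, so
sizes differ by at most one and the split is deterministic and invariant
to monotone transforms of the score. A covariate screen (two-group ANOVA
for continuous covariates, Pearson chi-squared for binary ones, one
joint BH-FDR family across all component × covariate comparisons) gates
the analysis but never adjusts it — if the screen is null the pipeline
proceeds on raw partial correlations.

Permutation tests re-allocate subjects to groups of the original sizes
and re-estimate both networks at the fixed whole-sample ρ. The p-value
is the add-one two-tailed count, p = (1 + #{|null| ≥ |obs|})/(1 + n_perm)
(default n_perm = 5,000); at α = 0.05 this is decision-equivalent to
thresholding at the 95th percentile of the absolute null, while always
yielding a usable per-contrast p strictly greater than 0. The
longitudinal omnibus statistic is the difference-in-differences
(low_T2 − low_T1) − (high_T2 − high_T1), permuted by re-allocating
subjects with both their timepoints together; this is one defensible
construction of a single change-contrast p and is documented as a
package decision. FDR families are the four components within one
metric × contrast (the covariate screen uses its own 24-way family).
Time-1 cross-sections are reported descriptively without a test by
default (a flag enables testing them).

Every random step descends from one master seed through named
`SeedSequence` children (recorded in the output bundle), and each
permutation draw owns its own child, so results are byte-identical
across reruns and across `--jobs` settings, and any single
(component, metric, contrast) cell can be reproduced in isolation.

## Synthetic cohorts

The generator emulates the *statistical design* the analysis assumes:
n = 114 subjects; regional thickness ~ N(2.5 mm, 0.25 mm) marginally;
two timepoints with per-region test–retest correlation 0.7
(equicorrelated bivariate latent draw, not an autoregressive process —
the simplest structure supporting a change analysis); four component
scores from standardized log-normals matched to the reference skewness
profile (1.98, 0.23, 0.89, −1.80); demographic/symptom covariates with
plausible ranges.

The region × region correlation matrix is modular: within a module every
pair correlates at `within_module_corr` (default 0.50); across modules
only *slot-matched* pairs correlate (region i of module A with region i
of module B, default 0.25), mimicking homotopic/long-range association
pairs; other cross-module pairs are marginally uncorrelated. The
slot-matched design is essential, not cosmetic: a *uniform*
between-module correlation is a single global factor, and partial
correlation analysis removes global factors by construction — its
population between-module partial correlations are ~0.002 at p = 60,
invisible at any penalty, so nothing planted there could ever reach the
estimated network. Slot-matched bridges carry partial correlations
~0.15–0.25 and appear as genuine cross-module edges.

A planted group effect multiplies the bridge correlations of the
low-scoring half of the "warmth" component by `group_effect` (< 1 makes
the low group's covariance more modular, hence its network more
segregated and its mean participation lower; 1.0 gives a fully
exchangeable null cohort — the basis of the calibration tests). The
truth record (module assignment, group labels, config) suffices to
recompute the planted covariance exactly.

What the generator does **not** emulate: spatial smoothness and
distance-dependent covariance of real cortex, scanner/site effects,
heavy-tailed thickness distributions, non-stationary longitudinal
change, or realistic effect sizes. Passing tests therefore demonstrate
that the *procedure* is correct and calibrated under its own
assumptions, not that real cohorts carry effects of this magnitude.

## Problem sizes in the simulation studies

Simulation-based checks run at deliberately scaled-down sizes chosen as
the package's own working points: calibration uses 200 null cohorts of
40 regions × 500 shuffles (type-I error within a 99% binomial band
around 0.05); power/directionality uses 50 cohorts of 60 regions with
bridge correlations scaled by 0.4 and 299 shuffles; support recovery
uses p = 20, n = 1,000 with ~10 planted edges of partial correlation
0.35 (at that strength the CV-selected penalty recovers the support
essentially perfectly; much stronger planted partials paradoxically hurt
precision, because penalty shrinkage of strong edges leaves two-hop
pairs on the inclusion boundary). The 3-region chain-recovery check runs
at ρ = 0.10, where the population glasso solution excludes the absent
edge with a strict margin — at ρ ≈ 0.05 the population KKT margin for
that edge is exactly zero and sampling noise flips it in ~30% of draws.

## Known limitations

* Graphical-lasso support recovery is inconsistent under strong
  two-hop structure at any single CV-chosen penalty; edge sets should
  be read as penalized estimates, not tested hypotheses.
* Power at the reference sample size is moderate. With 57 subjects per
  group, bridge partial correlations reachable under the generator's
  `between ≤ within` constraint sit only ~1.3–2 sampling SDs
  (1/√57 ≈ 0.13) above the detection boundary at the CV-selected
  penalty, so a 0.4 scaling of bridge correlations is detected through
  the participation coefficient in only about half of simulated
  cohorts (the power check in the acceptance suite reports the
  measured rate). Directionality — the affected group's lower
  participation — is recovered far more reliably than significance.
* The participation coefficient inherits Louvain's resolution limit;
  γ = 1 with restarts is adequate at p ≤ 148 but partitions of dense,
  weakly modular graphs remain the dominant noise source of the metric.
* The omnibus change construction is one of several defensible
  definitions; alternatives (e.g. permuting within-subject change
  signs) would test subtly different hypotheses.
* Median splits discard within-group variation in the behavioral
  scores; groups are analytic conveniences required by the group-level
  nature of covariance networks, not theoretical cut-points.
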