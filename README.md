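# scovnet

Structural covariance network (SCN) analysis of regional cortical
thickness: group-level brain networks from **sparse partial
correlations**, segregation/integration **graph metrics**, and
**permutation-based group comparison** across two timepoints — plus a
synthetic-cohort generator so the entire pipeline is testable without
access to any MRI data.

## The problem

In a structural covariance network, nodes are cortical regions (e.g. the
148 parcels of the Destrieux atlas) and edges reflect how strongly the
thickness of two regions co-varies *across subjects*. Such networks are
group-level objects: one network describes one group of participants, not
an individual. Comparing, say, children of low- vs high-warmth mothers
therefore means (1) splitting the cohort at the median of a behavioral
score, (2) estimating one network per group, (3) summarizing each network
with graph parameters, and (4) judging the group difference against a
permutation null in which subjects are repeatedly re-allocated and both
networks entirely re-estimated.

The package implements that full procedure for longitudinal designs
(two timepoints ~18 months apart): cross-sectional comparisons at
follow-up and an omnibus contrast on the Time2 − Time1 change.

## The model

Let X be the n × p matrix of standardized regional thickness. Edges are
the nonzero **partial correlations** r_ij = −Θ_ij / √(Θ_ii Θ_jj), where
the precision matrix Θ solves the graphical-lasso problem on the sample
correlation matrix S:

    max_Θ  log det Θ − tr(S Θ) − ρ ‖Θ‖₁,off

The penalty ρ (correlation scale, off-diagonal entries only) is chosen
by k-fold cross-validated held-out log-likelihood with the
one-standard-error rule; all group and permutation networks reuse the
single whole-sample ρ. Networks are binary and undirected.

Three parameters summarize each network:

* **global efficiency** E_glob = mean over pairs of 1/d(i,j) — integration;
* **mean local efficiency** E_loc — mean over nodes of the global
  efficiency of each node's neighborhood subgraph — segregation;
* **modularity as mean participation coefficient**
  PC_i = 1 − Σ_s (k_is/k_i)² over a seeded Louvain partition at
  resolution γ = 1. Low mean PC means edges concentrate within modules:
  *more* segregation; high mean PC means *less*.

Group inference: the observed low − high difference in a parameter is
compared with its distribution over random reallocations of subjects to
groups of the original sizes (networks re-estimated at the same ρ each
time), with the add-one two-tailed p-value
p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm), and Benjamini–Hochberg FDR
across the four behavioral components per parameter and contrast.

## Worked example

Simulate a 114-subject cohort (60 regions, 4 planted modules) in which
the low-warmth half has its between-module correlations scaled by 0.4 —
i.e. genuinely more segregated covariance — and test the participation
coefficient at Time 2:

```python
from scovnet import (SyntheticConfig, generate_cohort, median_split,
                     permutation_test, select_regularization,
                     standardize_regions)

cfg = SyntheticConfig(n_subjects=114, n_regions=60, n_modules=4,
                      group_effect=0.4, seed=1)
cohort = generate_cohort(cfg)
z2 = standardize_regions(cohort.thickness_t2)
rho, curve = select_regularization(z2)          # 1SE cross-validation
groups = median_split(cohort.component_scores, "warmth")
res = permutation_test(z2, groups, "participation", rho,
                       n_perm=500, seed=2)
print(rho, res.observed_low, res.observed_high, res.p_raw)
```

A full pipeline run on the same cohort (`scovnet run-all`, or
`run_pipeline`) prints, among others:

```
rho (whole-sample, CV 1SE)        0.136
mean participation, low-warmth    0.535
mean participation, high-warmth   0.617
difference (low - high)           -0.081   p = 0.004
```

The low-warmth group's mean participation coefficient is lower — its
network's edges stay within modules — reproducing the interpretive chain
*lower warmth → lower participation coefficient → more segregated
network*, and the permutation test flags the difference well below
α = 0.05. With `group_effect=1.0` (no planted difference) the same test
is calibrated: it rejects at ~5%.

## Command line

```bash
scovnet simulate --n-subjects 114 --n-regions 148 --seed 7 --outdir cohort/
scovnet qc cohort/thickness_t1.csv --z-threshold 3.0
scovnet build-network cohort/thickness_t2.csv --rho cv --prefix net_t2
scovnet run-all config.json
```

`run-all` writes one comparison table per network parameter (rows:
component × {Time 1, Time 2, Time 2 − Time 1, omnibus p}; columns: low,
high, difference, p, FDR-adjusted p), GraphML networks, CV curves, and a
JSON bundle embedding every seed so any single cell can be recomputed in
isolation.

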