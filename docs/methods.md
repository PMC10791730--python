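# Methods

## Network model and metrics

A subject's structural network is a symmetric, hollow, nonnegative
N × N matrix of connectivity probabilities (N = 90, AAL parcellation).
Analysis proceeds per sparsity level s: the ⌊s·N(N−1)/2⌋ strongest
undirected edges are retained with their original weights (ties at the
cutoff broken by ascending (row, column) index, so results do not depend
on platform sort stability). The sparsity denominator is the undirected
pair count N(N−1)/2. Asymmetric input is rejected rather than silently
symmetrized — an asymmetric matrix signals an upstream bug — with an
explicit `symmetrize="mean"` escape hatch.

Before any metric is computed the surviving weights are divided by their
mean, so each subject's network carries the same total cost; the scaling
is recomputed per thresholded network because the surviving edge set
defines "all weights" at that level. Edge length is the reciprocal of the
scaled weight. Then:

- **Clustering** uses the geometric-mean triangle intensity
  C_i = 2/(k_i(k_i−1)) Σ_{j<k} (w̄_ij w̄_jk w̄_ki)^{1/3}, summed over
  unordered neighbor pairs — with this reading a complete unit-weight
  graph gives C_i = 1 exactly (an ordered-pair sum would give 2).
  Nodes with degree < 2 contribute C_i = 0 and stay in the average over
  all N nodes.
- **Paths** are Dijkstra shortest paths (scipy.sparse.csgraph) over the
  reciprocal lengths. Unreachable pairs get infinite length; they
  contribute zero efficiency, and the characteristic path length Lp is
  averaged over finite pairs only with a `disconnected` flag raised —
  propagating infinity would make Lp useless at low sparsity.
- **Local efficiency** averages, over all N nodes, the global efficiency
  of the subgraph induced on each node's neighbors (keeping their mutual
  scaled weights; a subgraph with < 2 nodes contributes 0). The inner
  loop is a numba Floyd–Warshall kernel; an independent pure-NumPy
  subgraph oracle verifies it in the tests.
- **Nodal efficiency** is the per-node mean inverse path length; its
  node average equals global efficiency identically, which the tests
  assert to 1e−10 as an internal consistency check.

## Null model and small-world indices

"Matched" random networks preserve the degree sequence exactly via
Maslov–Sneppen double-edge swaps (target: 10 successful swaps per edge, a
conventional mixing heuristic, configurable) and the weight multiset
exactly (original weights randomly permuted onto the rewired edge set).
The swap loop is implemented in the package because the achieved-swap
count must be reported when the target is unreachable (a star graph
admits no swap at all); degree-sequence and weight-multiset conservation
are asserted in tests for every surrogate. Surrogates are regenerated per
thresholded network, not rewired once per subject. Surrogate
connectedness is not enforced; the finite-pair Lp convention applies.

γ = Cp/Cp_rand and λ = Lp/Lp_rand use ensemble means (default 100
surrogates; studies at reduced scale use 20). The small-world index is
σ = γ/λ: this is the only definition consistent with the standard
criterion that γ > 1 with λ ≈ 1 implies σ > 1.

## AUC and hubs

Metric-versus-sparsity curves are integrated with the trapezoid rule over
the sparsity axis (on a uniform grid rectangle and trapezoid rules differ
only at the endpoints; trapezoid is the standard choice). Hub analysis
operates on the group-mean nodal-efficiency AUC vector: a region is a hub
when its value strictly exceeds mean + SD, with the sample SD (N−1
denominator) by default and population SD as an option.

## Statistics

Demographics and cognitive scores: one-way ANOVA (a summary-statistic
variant reconstructs F from printed n/mean/SD triples for checking
published tables); sex proportions: Pearson chi-square without continuity
correction. Network metrics: one-way ANCOVA — an OLS fit of
`y ~ group + age + sex + education` with the omnibus statistic the
partial F for the group factor; sex enters as a binary indicator,
education in years as numeric. Adjusted group means are evaluated at the
covariate means. Fisher's LSD post hoc tests are unadjusted model-based
t-tests on adjusted mean differences using the full model's residual mean
square and df; for two groups the LSD p equals the omnibus p (t² = F).
With no covariates the ANCOVA reduces exactly to one-way ANOVA.

Brain-behavior correlations are Pearson by default, with a partial mode
(covariates residualized, via pingouin) provided. FDR control is
Benjamini–Hochberg, applied within each group's (regions × tests) family
by default, with a pooled global family as an option. Zero-variance
features are flagged undefined and excluded from the FDR family.

## Synthetic cohort generator

The generator emulates tractography output at the statistical level:

- **Backbone**: connected Watts–Strogatz graph, N = 90, lattice degree
  k₀ = 10, rewiring probability β = 0.1 — the simplest generator that
  reproduces γ > 1 with λ ≈ 1 without fitting real data. Rewiring
  preserves the edge count (450), so the raw density is 11.2%; sweep
  levels above that request more edges than exist, and per the
  thresholding contract all edges are kept with a warning. Pipeline
  stages cache per retained-edge count so identical saturated networks
  are computed once.
- **Weights**: independent log-normal draws (default log-mean −4,
  log-SD 0.7) clipped to (0, 1], because a connectivity probability is a
  fraction in [0, 1]; the empirical distribution of tractography
  probabilities is not published, so these defaults are declared
  assumptions, not estimates.
- **Group effect**: a per-subject fraction of edges (default mean 0.5)
  is attenuated multiplicatively by δ_g — defaults δ = 0.5 (severe),
  0.9 (mild), 1.0 (controls). Selection is preferential among
  triangle-closing edges with probability proportional to the *square*
  of the per-edge triangle count, concentrating the insult in densely
  clustered neighborhoods so that the injected deficit is specifically
  local (Eloc) rather than global. This concentration matters: in a
  Watts–Strogatz lattice nearly every edge closes a triangle, so uniform
  "triangle-preferring" sampling is effectively unconditional, and
  mean-weight rescaling cancels diffuse multiplicative attenuation to
  first order — the resulting deficit is then too weak for the
  detection rates the design targets. A per-subject severity multiplier
  (uniform in 1 ± 0.5) models inter-patient heterogeneity of lesion
  burden and gives the latent damage score within-group variance, which
  in turn carries the damage–cognition correlations.
- **Damage score**: the mean per-edge attenuation applied,
  n_attenuated·(1−δ)/n_edges; 0 for controls.
- **Cognition**: each score is the calibrated group mean (published
  cohort summaries for MoCA, AVLT, SDMT, SCWT, TMT B−A) plus a
  damage-linked shift plus Gaussian noise. The slope is set so the
  damage signal carries a 1−noise_share share of the calibrated variance
  (default noise_share 0.5), with negative sign for MoCA/AVLT/SDMT and
  positive for the timed SCWT/TMT. Cross-test correlation is induced
  only through the single latent damage score (parsimony). Groups
  without damage variance receive pure noise at the full calibrated SD.
- **Covariates**: age and education normal per group, sex Bernoulli,
  all calibrated to the published cohort (67 severe / 133 mild / 89
  controls).
- **Reproducibility**: one cohort seed; per-subject generators are
  spawned from a single seed sequence, so output is bit-identical across
  runs and stable under iteration order.

What the generator does *not* emulate: spatial lesion geometry,
distance-dependent connection probability, hemispheric symmetry of real
connectomes, measurement noise of tractography, or site/scanner effects.
Passing tests therefore demonstrate that the pipeline recovers the
effects the generator injects under realistic topology and calibrated
score distributions — not that it would detect effects in any particular
clinical sample.

## Problem sizes and numerical choices

Validation studies run at reduced scale chosen for a desk-class machine:
10-subject cohorts with 20-surrogate ensembles for small-world
characterization, 20-subject groups for detection studies (50 replicates
with the deficit, 100 without). Detection is the ANCOVA omnibus (group
partial-F) p < 0.05 on the local-efficiency AUC. At those sizes the
deficit configuration is detected in ≈ 95% of replicates and the null
configuration rejects at ≈ 3–5%, consistent with the nominal test level.

Symmetry and zero-diagonal validation use a 1e−9 absolute tolerance
(text round-trips are exact; the tolerance guards hand-edited input).
Ensemble normalization fails loudly if the surrogate mean clustering or
path length is non-finite or non-positive. Sparsity grids are built from
integer step counts and rounded to 12 decimals so that 0.06 + 18 × 0.01
lands exactly on 0.24.
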