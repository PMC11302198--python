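# Methods

This note documents the statistical model behind `stroopsense`, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## Synthetic cohort model

The generator emulates a case-control wearable study at the level of the
extracted feature table, not the raw signals.  Each analysed participant
contributes one row per Stroop test; the value for participant *i*,
feature *f*, test *t* of type *T* is

    x_{i,f,t} = μ_f + a_i + b_{f,T} + Δ·σ_ε·z_{f,T}·1[i ∈ EG] + ε_{i,f,t}

| term | meaning | default |
|---|---|---|
| μ_f | per-feature baseline, N(0, 1) | — |
| a_i | participant random effect, N(0, σ_a) | σ_a = 0.5 |
| b_{f,T} | per-(feature, test-type) offset, shared by same-type tests | σ_b = 1.0 |
| ε | residual noise distinguishing same-type tests | σ_ε = 1.0 |
| z_{f,T} | planted group-effect indicator | fractions N 0.52, C 0.104, E 0.036 |
| Δ | standardized group shift (units of σ_ε) | 1.5 |

All scales are dimensionless: every downstream statistic is rank-based
(Wilcoxon), distribution-free (KS) or applied after z-scoring, so Gaussian
marginals with arbitrary units suffice.  The structure delivers exactly the
three properties the screening stage assumes: same-type tests are
exchangeable at the individual level (their paired differences are pure
ε-noise with mean zero), different types are shifted against each other
through b, and group effects concentrate in the number-test features.

Planted-effect counts use round-half-up of fraction × 191 (99 / 20 / 7
features for N / C / E); the affected set is drawn from a seed-derived
stream separate from the noise stream, so `planted_truth` can reproduce it
without generating data.  σ_a = 0.5 keeps the between-subject component
clearly smaller than the residual (subjects differ, but not enough to
swamp a 1.5σ group shift at n = 44 + 32); σ_b = 1.0 makes cross-type
pairwise ratios high (≈ 0.8) without saturating them at 1.0.  Dropout
participants (4 incomplete + 15 unretrievable, 14 of the 19 controls) are
generated and flagged rather than omitted, so the enrolment flow
95 → 76 is auditable; the split of dropouts across groups reproduces the
enrolled group sizes of 58 controls and 37 cases.  Ages are normal,
truncated at 18 (rejection sampling), with per-group means/SDs matching
the reported enrolled-cohort demographics; gender is Bernoulli with
per-group male fractions 32/58 and 24/37.

What the generator does *not* emulate: real marginal distributions of the
proprietary features (unknown and likely non-Gaussian), correlations
between features beyond the shared subject effect, label noise in the
control group, and any medication or comorbidity structure.  Passing tests
therefore show that the pipeline recovers the planted structure under its
own assumptions — not that it would achieve comparable metrics on clinical
data.  The default synthetic task is in fact considerably easier than the
real one (accuracies near 1.0 on the number bundle); effect size and
noise scales are exposed for harder settings.

## Screening

- Wilcoxon signed-rank, two-sided, per feature and test pair; zero
  differences dropped before ranking (classic convention) and a feature
  with all-zero differences counted as non-significant.  The significance
  cutoff P ≤ 0.1 is inclusive.
- Bundling is available as the data-driven rule (merge where the ratio
  ≤ τ in both groups; connected components; default τ = 0.2) and as the
  fixed C/N/E map, which the orchestrated pipeline uses by default because
  the merging criterion in the emulated design is verbal, not numeric.
- The KS stage pools a bundle's member-test rows per group and treats them
  as independent samples.  With two number tests per participant this is
  deliberate pseudo-replication, justified operationally by the low
  within-type Wilcoxon ratios; it inflates effective sample size and is
  retained for fidelity to the emulated design, not endorsed.  KS p-values
  use the asymptotic distribution (pooled group sizes ≈ 88 vs 64).
- Demographics: pooled-variance t (df = n₁+n₂−2) and Pearson χ² with
  Yates continuity correction on the 2×2 gender table — the corrected
  statistic is the one that reproduces the published value (0.5221 on
  32/26 vs 24/13; the uncorrected statistic would be 0.8769).

A note on invariances: the signed-rank matrix is invariant under positive
affine rescaling of a feature but **not** under arbitrary monotone
transforms (they reorder difference magnitudes); the KS ratios are
invariant under any strictly monotone per-feature transform.  The tests
assert exactly these.

## Informative KNN

- Distances are computed after per-feature z-scoring (the kernel is
  scale-sensitive; raw units would let one feature dominate).
- The literal kernel exp(−‖Δ‖²) underflows for standardized vectors in
  77–191 dimensions (‖Δ‖² ≈ 2 × dim), collapsing all similarities to zero.
  The default bandwidth is therefore the median pairwise squared distance
  (median heuristic), which reduces to the literal kernel when that median
  is 1; `bandwidth_rule="literal"` is kept for low-dimensional work and
  oracle tests.  If every unnormalized mass still underflows, the
  informativeness falls back to uniform 1/k with a warning.
- η is the fraction of x_i's k neighbors whose label equals that of the
  candidate neighbor x_j; Λ multiplies (1 − similarity) over the
  opposite-class members of the same neighborhood.  A point is never its
  own neighbor.
- Majority-vote ties (even M, split labels) resolve to the label of the
  single most informative neighbor; informativeness ties resolve toward
  the nearer neighbor, then input order.  Discard counts use round-half-up
  of fraction × n, with ties in s̄ broken by stable input order.
- Scope: `all-points` (default) ranks every point; `cg-only` restricts
  discarding to control-group points — the reading in which only the
  unvetted controls can harbour mislabelled cases.  Both are exposed;
  neither is asserted as the canonical procedure.
- Filtering is applied once to the full dataset before cross-validation,
  so all folds share the same point set.  This leaks label information
  from future test points into the filter; the per-fold alternative
  (filter on training rows only) is available by composing
  `filter_points` inside a custom loop, but the shared-points scheme is
  the default for fidelity.

The brute-force oracle in `tests/_oracles.py` re-implements the scoring
with direct loops and no shared code; agreement is required to 1e−12 on
30-point, 5-dimensional instances for both bandwidth rules.

## Variance filters

rMAD and rIQR use absolute values in the denominators (|med|, |p25|) so
negative-valued features still yield nonnegative, scale-relative
statistics.  A zero median makes rMAD fall back to the unnormalized MAD
with a degenerate flag; rIQR switches its denominator to p75 when p25 = 0
and returns a flagged 0 when both quartiles vanish.  Percentiles use
linear interpolation between order statistics.  No rescaling beyond the
built-in denominators is applied.  During cross-validation the statistics
are computed on training rows only.

## Classification

- "Cross-validation with a 70/30 split" is implemented as Monte-Carlo CV:
  repeated random stratified splits with per-class test counts of
  round-half-up(0.3 × n_class) — 13 CG + 10 EG test points at the default
  cohort size.  A plain k-fold partition is incompatible with fixed 70/30
  proportions at n ≈ 76–152.
- Per repetition, fitted on the training partition only: variance
  thresholds (on raw values — z-scored columns have near-zero medians and
  would degenerate the relative statistics), then z-scoring, then PCA,
  then the classifier.  Integer PCA dimensions exceeding the training rank
  are clamped with a warning; single-class training partitions are skipped
  with a warning.
- Default tuning grids: LR C ∈ {0.01, 0.1, 1, 10}; KNN neighbors
  ∈ {3, 5, 7, 9}; RF trees ∈ {100, 300} × depth ∈ {∞, 5}; SVM (RBF)
  C ∈ {0.1, 1, 10} × γ ∈ {scale, 0.01, 0.1}; thresholds
  (θ_rMAD, θ_rIQR) ∈ {0, 0.05, 0.1}²-diagonal; PCA ∈ {90% var, 95% var,
  10 components}.  Selection maximizes mean test accuracy over folds that
  are identical across grid points (same seeds).  This is in-sample model
  selection and optimistic by construction; the package keeps it because
  the comparison of interest (full vs reduced) applies the same optimism
  to both arms.
- Points are (participant, test) rows, so the default split can place the
  same participant's two number-test rows on opposite sides of a fold.
  This replicates the emulated design; a participant-grouped split is the
  obvious correction and can be built from `split_stratified` applied to
  participant labels, but is not the default.
- The full-vs-reduced dataset choice is never a tuned hyperparameter; both
  variants are evaluated with the same fold seeds.

## Problem sizes used by the shipped checks

The test suite and the acceptance script scale the Monte-Carlo work to
desk scale as the package's own defaults for quick verification: 10–50 CV
repetitions instead of 100, 20-seed Monte-Carlo loops for recovery and
calibration claims, and reduced feature counts in pure-plumbing tests.
All are ordinary parameters; nothing in the methods depends on these
sizes.

## Known limitations

- The balanced-accuracy figures of the emulated study are reproducible
  only as derived arithmetic on its published tables; absolute metric
  values require the clinical dataset, which is not public.
- The pooled-rows KS test and the shared-points filtering both violate
  independence assumptions in documented, deliberate ways (fidelity over
  purity).
- The i-KNN kernel's high-dimensional behaviour in the original analysis
  is unknown; the median-heuristic bandwidth is this package's remedy and
  is flagged as such.
- The generator's Gaussian, feature-independent structure understates the
  difficulty of real wearable data.
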