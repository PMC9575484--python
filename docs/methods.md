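# Methods

Statistical models, parameter conventions and numerical choices. Units:
expression is either `raw_counts` (non-negative read counts) or
`log2_normalized`; survival time is in arbitrary consistent units (the
generator uses the scale set by its baseline hazard); all fold changes
are log2.

## Normalization

**log2 + quantile** (`normalize_method: log2_quantile`). Counts are
transformed to `log2(x + 1)`, then each sample's values are replaced by
the mean order statistics across samples: the reference distribution is
the per-rank mean of the column-sorted matrix, and each value maps to the
reference value at its within-column rank. Ties receive the mean of the
reference values their rank block spans (average ranks). Consequences
worth knowing: with ties present the transform is not exactly idempotent
and tied columns need not match untied ones exactly; with very few genes
the rank mapping coarsens between-sample variation (see Limitations).
Requires ≥ 2 samples.

**TMM + log2-CPM** (`normalize_method: tmm_log2cpm`). Trimmed mean of
M-values: the reference sample is the one whose 75th-percentile count
fraction is closest to the cohort mean; for each sample, M (log-ratio)
and A (log-abundance) values are computed over genes nonzero in both
sample and reference; a two-tailed trim removes 30% of each M tail and 5%
of each A tail (cutoffs `floor(n·frac)+1 … n−floor(n·frac)` on average
ranks); the factor is the inverse-delta-variance weighted mean of the
kept M values, and factors are rescaled to geometric mean 1. Output is
`log2(count / effective_library_size · 1e6 + 0.5)` with
`effective_library_size = column_sum · factor`. Cross-checked against an
independent R implementation in the test suite.

## Differential expression

High-risk versus pooled intermediate + low risk, per gene: two-sided
two-sample *t*-test (pooled-variance Student by default; Welch available
via `de_welch`) on log2-normalized values, plus a fold-change gate. A
gene is flagged upregulated when `p < de_p_threshold` (default 0.05) and
`mean(high) − mean(other) ≥ de_log2fc_threshold` (default 1.0, i.e. a
two-fold change). Zero-variance genes get `t = 0, p = 1`. Each group
must have ≥ 2 samples; samples with missing risk are excluded from this
contrast only.

## Unbiased distance correlation

For `x ∈ R^n` (n ≥ 4), `a_ij = |x_i − x_j|`, U-centering

```
Ã_ij = a_ij − col_j/(n−2) − row_i/(n−2) + grand/((n−1)(n−2)),  Ã_ii = 0,
```

`Cov_D = Σ Ã∘B̃ /(n(n−3))`, `R_D = Cov_D/√(Var_x Var_y)`. `Cov_D` is an
unbiased estimator of the squared population distance covariance, so
`R_D` can be legitimately negative under independence. The p-value is
the χ²₁ survival function at `n·R_D + 1` (equivalently, `n·R_D` referred
to χ²₁ − 1), a conservative large-sample bound: its finite-sample
rejection rate under independence is at most the nominal level. Genes
whose unbiased distance variance is below `1e−14 · mean(a)²` are treated
as degenerate and skipped with a log message rather than given `p = 1`,
so downstream edge counts remain auditable. The pairwise screen caches
each gene's U-centered matrix, making the screen O(pairs · n²).

**Edge rule.** RBP → target edges require `p_raw < edge_p_threshold`
(default 1e−6, a fixed stringent threshold standing in for multiplicity
control) **and** `R_D > edge_rd_threshold` (default 0.2, signed).
`bonferroni_mode: alpha_over_m` switches the p cutoff to
`bonferroni_alpha / #tests`.

## Survival

**Log-rank.** Expression dichotomized at the cohort median (ties fall in
the low group), standard hypergeometric-variance log-rank χ²₁ statistic
between the two Kaplan–Meier curves. Requires ≥ 2 observed events and
two nonempty groups.

**Univariate Cox.** Partial likelihood on continuous expression,
Newton–Raphson from β = 0, Efron tie handling by default (Breslow
available). Convergence at |score| < 1e−9 within 50 iterations; steps
are clipped to ±5 and a monotone partial likelihood (perfect separation)
is detected post hoc — |β| > 20 or observed information collapsing below
1e−6 of its β = 0 value — and flagged as non-converged instead of being
reported as a finite estimate. Wald standard errors, 95% CI and p-values.

## Synthetic-cohort generator

The generator emulates a bulk RNA-seq cohort with risk-group structure:

- **Cohort layout.** Default risk groups 37 high / 101 intermediate / 32
  low (n = 170); a pediatric-style preset (12/93/72) is provided.
- **Expression.** Each gene has a latent log2 mean drawn uniformly from
  `baseline_log2_mean_range` (default (3, 9)) plus per-sample
  `N(0, latent_sd²)` variation (default sd 1.0). Counts are
  negative-binomial via a gamma–Poisson mixture with dispersion
  `nb_dispersion` (default 0.1) and per-sample depth factors uniform on
  `depth_range` (default (0.7, 1.3)).
- **Planted upregulation.** `n_planted_up` genes get `planted_log2fc`
  (default 1.5) added to their latent mean in the high-risk group.
- **Planted edges.** Each planted edge overwrites the target's latent
  variation with `latent_sd · f(u) + N(0, noise_sd²)` where `u` is the
  RBP's standardized latent profile and `f` cycles through linear
  (`f(u) = u`), centered quadratic (`(u² − mean)/√2`, population Pearson
  correlation ≈ 0 — a deliberately Pearson-blind dependence) and
  sinusoidal (`sin(u)/0.658`, scaled to unit variance for standard
  normal input).
- **Survival.** Event times are exponential with hazard
  `h₀ · exp(Σ β_g z_g)` on standardized latent profiles; censoring is
  uniform on `(0, c_max)` with `c_max` calibrated by bisection so the
  expected censoring fraction matches `censoring_rate` (default 0.3).

The generator does **not** emulate: gene–gene co-expression modules
beyond the planted edges, batch effects, GC/length biases, isoform
structure, dropout, competing risks, or informative censoring. Generator
defaults are the study conditions of the test suite; the strong-effect
condition used for network-recovery studies (noise sd 0.05, latent sd
2.0, dispersion 0.01, baseline means (6, 10)) exists because the
centered-quadratic dependence has `R_D ≈ 0.22–0.28` at n = 150 under
low noise — only modestly above the 0.2 edge gate — so recovery studies
must keep measurement noise from eroding that margin; this is a property
of the quadratic form, not a tuning against any particular run.

## Numerical choices

- All floating-point table output uses the `%.12g` format; edges are
  written sorted by `(rbp_id, target_id)`; combined with seed-derived
  randomness (all sub-seeds below 2³¹ from `numpy.random.default_rng`),
  every pipeline artifact is byte-identical across same-seed runs.
- `R_D` is clipped into `[−1, 1]` only when within 1e−12 of the
  boundary; larger excursions raise, as they indicate a bug.
- The χ²₁ argument `n·R_D + 1` is floored at 0 (p = 1).
- Cox CI exponentials silence overflow only for the non-converged flagged
  path.

## Limitations

- The distance-correlation p-value is a conservative bound, not an exact
  test; calibrated p-values would need permutation.
- The fixed `p < 1e−6` edge rule is a stand-in for formal multiplicity
  control; `alpha_over_m` provides a classical Bonferroni alternative.
- Quantile normalization with very few genes (tens) destroys
  between-sample variation; survival analyses on such matrices attenuate
  effect sizes. Use adequately sized matrices (≥ ~100 genes) or TMM.
- The *t*-test DE screen assumes approximate normality of log-normalized
  values; no empirical-Bayes variance moderation is applied.
- Univariate Cox and log-rank test one gene at a time; no multivariate
  adjustment (age, cytogenetics, etc.) is modeled.
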