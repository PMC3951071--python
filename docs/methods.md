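# Methods and design notes

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerically delicate choices. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Normalization

Counts are normalized per experiment: the baseline for a cell type is the
mean pre-irradiation count over *all* animals of the experiment (sham
included), and every record becomes count / baseline. Consequences worth
noting:

* the cohort-wide pre-irradiation mean fraction is exactly 1, but
  individual animals' pre-irradiation fractions are not;
* normalization is idempotent — records already carrying fractions pass
  through unchanged;
* two reference experiments with interleaved dose ladders (5/7.7/15 Gy and
  7.5/10/20 Gy) are pooled *after* per-experiment normalization, which is
  how the shipped six-dose reference tables arise.

Percent change is `(fraction − 1)·100`; decreases are negative.

## Dose-response fitting

`fit_lq` minimizes `Σ_g n_g (ȳ_g − exp(−a·D_g − b·D_g²))²` subject to
`a, b ≥ 0` on the untransformed fraction scale.

* **Scale.** Fitting on the fraction scale (not log scale) is what
  reproduces the published reference-arm slopes and effective doses from
  the shipped tables; the log-scale through-origin regression is retained
  only as the optimizer's starting point. The lymphocyte 4-h stratum is
  the clearest discriminator: the fraction-scale fit gives a ≈ 0.086 Gy⁻¹
  (matching the published value) where the log-scale fit gives ≈ 0.075.
* **Weights.** Group size n only. Inverse-variance (1/SE²) weighting was
  rejected because it fails to reproduce the published slopes and because
  n=3 SEs are far too noisy to be useful precision estimates. With
  weights = n, fitting group means is algebraically identical to fitting
  the individual animals (the within-group sum of squares does not depend
  on the parameters); this equivalence is property-tested to ~1e-12.
* **Bounds.** Non-negative a and b, matching the radiobiological meaning
  (counts cannot increase with dose under this model) and the published
  convention of quadratic components reported as essentially zero and a
  linear component of exactly 0.000 — signatures of an active bound.
* **Data points.** Fits use positive doses only. Sham (0 Gy)
  post-irradiation values are not fitted: the model forces y(0) = 1
  regardless, so they carry no information about (a, b) under this
  parameterization.
* **Optimizer.** `scipy.optimize.least_squares` (trust-region reflective,
  tolerances 1e-12) multi-started from the log-scale estimate and from
  (0, 0); the lowest weighted SSR wins, ties break toward smaller b. A
  final active-set Newton polish with analytic gradient and Hessian drives
  the optimum to the floating-point noise floor, so equivalent problem
  formulations agree to ~1e-12 in (a, b). A dense two-stage grid search
  over a ∈ [0, 0.3] × b ∈ [0, 0.01] (refined to steps 1e-4/1e-5) serves as
  an independent oracle in the tests, never as the implementation.
* **Covariance.** Gauss-Newton, `s²(JᵀWJ)⁻¹` with `s² = SSR/df` and
  `df = n_points − 2` by convention regardless of active bounds. With a
  parameter on the boundary this is an approximation; it feeds only the
  delta-method ED intervals, which are cross-checked against a bootstrap
  that does not use it.

### Significance of the dose response

"Is there any dose response?" is tested with an F statistic comparing the
flat null y ≡ 1 against the **unconstrained** least-squares alternative
(2 numerator df, n − 2 denominator df). The bounded fit's SSR is *not*
used here: classical F theory assumes an interior optimum, and under a
flat truth roughly half of all noise realizations push the bounded optimum
onto the a = b = 0 boundary where the statistic degenerates to zero,
making a bounded-SSR test severely conservative (empirical type-I error
well below 1% at nominal 5%; the unconstrained version tracks α — both
measured by simulation in the test suite). Reported coefficients remain
the bounded estimates. Non-significant strata propagate as "NM" cells and
gate the RBE stage.

### Tukey annotations

The count-table significance tiers (# / * / ** / ***) come from a Tukey
HSD computed from summary statistics: within one (cell type, time-point)
the family is all dose groups plus the pre-irradiation summary, the pooled
error variance comes from the group SDs (SE·√n), and p-values use the
studentized-range distribution. The family definition is a choice (the
source tables do not state theirs); it is deliberately the narrowest
family consistent with the annotations. Families containing any n < 2
group return "not testable" rather than raising.

## Effective doses

`ED_p` solves `a·D + b·D² = −ln(1 − p/100)`; p is on the percent-reduction
scale (ED10 ⇔ fraction 0.9). The quadratic root is evaluated as
`2L / (a + √(a² + 4bL))`, which is exact for b = 0 and avoids the
catastrophic cancellation the textbook form `(−a + √(a²+4bL))/(2b)`
suffers when b sits at the zero bound (~1e-30).

Censoring conventions: a non-significant slope renders every ED cell "NM";
a point estimate above the arm's maximum delivered dose renders ">Dmax"
(one decimal, e.g. ">20.0"); ED90 is suppressed outright when it exceeds
the maximum dose, to avoid extrapolating the curve beyond the design
range.

Confidence intervals: delta method by default (gradient
`∂D/∂a = −D/(a+2bD)`, `∂D/∂b = −D²/(a+2bD)`, normal quantiles), with a
parametric bootstrap — group means resampled from (fitted value, residual
variance / weight), bounded refit, percentile interval — as an independent
cross-check; the two agree closely in the moderate-noise regime the tests
probe. ED intervals computed from group-mean tables reflect between-group
scatter only (df = 4 here); intervals published from per-animal fits
(df = 16) are systematically narrower, so CI values are validated by
method-vs-method agreement and coverage simulation, not against published
CI numbers.

## RBE estimation

For each test-arm animal: isoeffective reference dose
`D_iso = invert(a_ref, b_ref, fraction_observed)`, RBE = D_iso / D_test.
Fractions ≥ 1 (no effect) map to D_iso = 0, hence RBE 0 — an observed
convention in the source material, kept as-is. Test time-points map to
reference time-points via an explicit pairing (identity except test
Day 4 → reference Day 7, reflecting the two arms' sampling schedules).

The per-animal RBE values of one stratum are fitted with an OLS quadratic
in test dose. With the 3-dose × n=3 design the quadratic saturates the
design points, so fitted values at the design doses equal per-dose
replicate means, and the residual variance (df = 6) is the pooled
within-dose scatter. The 95% limits are mean-response t-intervals,
`fitted ± t(0.975, df)·√(xᵀΣx)`. Negative fitted values or limits are
reported unclamped.

Two known limitations of this interval, verified by simulation (200
replicates, true RBE 2.5, σ = 0.2, study-sized design — the conditions of
the end-to-end recovery test):

1. per-animal RBE noise scales like 1/(a_ref·D), so the homoscedastic OLS
   interval is slightly anti-conservative at the lowest dose and
   conservative at the highest;
2. the reference-curve estimation error is shared by all RBE points of a
   replicate and is invisible to the residual-based interval.

Observed coverage in that simulation sits near the low end of the nominal
band (~0.90–0.93 pooled across doses) rather than at 0.95. The average
RBE is the mean ± SEM of fitted values over endpoints where both arms'
dose responses were significant; the inclusion rule is exposed as a
callable because endpoint sets are study-specific.

## Synthetic data generator

`hemrbe.synthetic` runs the fitted model forward: per animal a lognormal
baseline count (per cell type mean and CV), per stratum a fraction
`exp(−aD−bD²)·exp(N(0, σ²))`, absolute counts = fraction × the animal's
own baseline. Defaults mirror the two-arm study design: test groups n = 3
at 5/7.7/10 Gy, reference n = 3 at 5/7.5/7.7/10/15/20 Gy, sham animals
generated (they enter the baseline, never the fits), σ = 0.2 — sized so
group SEs land in the ~5–20%-of-mean range the published n=3 tables show.
Baseline CVs (0.07–0.45 by cell type) are back-computed from the published
pre-irradiation SEs (SE·√n with the pooled cohort n). A configured true
RBE links the arms via a_test = RBE·a_ref and b_test = RBE²·b_ref, which
makes the isoeffect ratio dose-independent; `true_rbe` refuses
non-proportional configurations and reports dose-resolved ratios instead.

What the generator does **not** emulate — and what passing tests therefore
do not certify about real data: within-animal correlation across
time-points (time-points are generated independently, as the analysis
treats them), hematopoietic recovery kinetics, analyzer measurement error
distinct from biological variation, and non-lognormal outliers (e.g. the
occasional >2× group-mean spikes visible in the published monocyte and
eosinophil tables).

## Problem sizes in the test suite

Simulation-based tests use 200 replicates for RBE recovery/coverage, 1000
replicates for the type-I-error check, and 1000–2000 bootstrap replicates
for interval cross-checks; these sizes put binomial/Monte-Carlo error
comfortably inside the asserted tolerances while keeping the full suite in
the minutes range on one CPU.
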