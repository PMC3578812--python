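# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## The stochastic transition model

Hourly model-based insulin sensitivity SI is strictly positive and
right-skewed, and its hour-to-hour evolution is strongly level-dependent.
The transition model is a conditional kernel density estimate built from
every observed transition (SI_n, SI_n+1) of the cohort, pooled across
patients, days of stay and diagnosis groups — the "whole-cohort" reference
against which individual patients are scored.

Kernels are Gaussian on the log scale (this respects the positive support
and symmetrises the skew). Two coordinate systems are available for the
second kernel dimension:

* **change (default).** Centres are (uᵢ, rᵢ) = (log SIₙ, log SIₙ₊₁ − log SIₙ).
  The conditional CDF given current value x is
  F(y|x) = Σ wᵢ(x) Φ((log y − log x − rᵢ)/h_vᵢ) with
  wᵢ(x) ∝ φ((log x − uᵢ)/h_uᵢ)/h_uᵢ.
* **level.** Centres are (uᵢ, vᵢ) = (log SIₙ, log SIₙ₊₁) and the component
  means are the vᵢ themselves.

The change parameterisation is the default for a structural reason. Hourly
transition pairs lie close to the identity diagonal: the spread of SI
*levels* across patients (log-SD ≈ 0.7–1.4 in our cohorts) is an order of
magnitude larger than the hour-to-hour *change* (log-SD ≈ 0.05–0.3). In
level coordinates the conditional spread inherited from a Silverman-width
conditioning window is dominated by the window width, so the predicted
distribution is several times wider than the true conditional; percentiles
of the training data then pile up near 0.5 and the tail-exceedance metric
records almost no events. In change coordinates the second-dimension
bandwidth is set by the change distribution itself, and the model is
approximately self-calibrated: on its own training cohort the percentiles
are near-uniform (exceedance fraction ≈ 0.095, mean squared deviation
≈ 0.078 against the uniform references 0.10 and 1/12). Only a calibrated
reference model makes the downstream penalties interpretable, so this is
the package default; `coordinates="level"` retains the plain bivariate
form for comparison.

**Bandwidths.** Default is the normal-reference (Silverman/Scott) rule per
dimension for a bivariate KDE, h = σ̂ n^(−1/6) (the d = 2 constant
(4/(d+2))^(1/(d+4)) is 1). An optional adaptive rule (`bandwidth_rule="knn"`)
scales both bandwidths per centre by the distance to the k-th nearest
neighbour in standardised coordinates (k = √n by default), normalised to
geometric mean one — wider kernels in sparse tails. If a dimension has zero
spread (e.g. two identical transitions) the bandwidth falls back to
max(10⁻³, 10⁻² |centre|) so the CDF stays proper.

**Quantiles** invert the CDF by an expanding bracket plus bisection on the
log scale, to 10⁻¹⁰ in probability (well inside the 10⁻⁸ contract).
The CDF is strictly increasing under Gaussian kernels, so the root is
unique; ties can arise only from floating-point flatness in the extreme
tails, where bisection converges to the bracket midpoint.

**Sampling** draws a mixture component by its weight, then one lognormal
variate from that component. Percentiles of data sampled from the model and
scored by the same model are *exactly* U(0, 1) by the probability integral
transform; this is the package's main self-consistency check (it holds for
any proper conditional model, in both coordinate systems).

## Variability percentiles and penalties

For each within-patient consecutive pair, p = F(SI_n+1 | SI_n) is recorded
at the observed hour (the first hour of a stay has no predecessor and yields
no record). Percentiles are kept as fractions in [0, 1].

* Quadratic penalty: mean (p − ½)² over a block; range [0, 0.25];
  1/12 under uniformity. Invariant under p → 1 − p.
* One-sided penalty: fraction of p > 0.9 (strict; under a continuous model
  ties have probability zero, so the choice is immaterial but fixed);
  0.10 under uniformity. Deliberately direction-sensitive: it counts only
  upward SI surprises, the hypoglycaemia-relevant direction. The exceedance
  is defined on the percentile rather than on raw SI against a precomputed
  quantile — equivalent under a proper CDF and numerically cleaner.

**Day blocks.** Records are assigned by their observed-hour timestamp to
day1 = (0, 1440], day2 = (1440, 2880], day3 = (2880, 4320] minutes and
day4plus = (4320, ∞), so the k-th day holds the 24 records observed during
its hours. To avoid weighting patients unequally near discharge, day 1–3
blocks are kept only when the stay covers the whole block; day 4+ keeps
whatever remains; stays under 24 h are excluded from daily statistics
entirely. A 48-h stay therefore contributes exactly two blocks of 24
records each.

## Descriptive surfaces

Decile histograms of the percentiles per (day, group) cell quantify
coverage (flat = calibrated, U-shaped = underdispersed model, peaked =
overdispersed model); a Pearson χ² against equal bin counts (9 df)
summarises flatness, flagged below n = 50 where the approximation is poor.
The time trend of the per-hour squared deviation is smoothed with LOWESS
(span 2/3, 3 robustness iterations — conventional defaults; the span is
exposed). Per-patient score distributions are summarised violin-style:
mean, linear-interpolation quartiles, and a Gaussian KDE on a grid padded
three bandwidths past the support; all-identical cells fall back to a
narrow Gaussian spike so the reported density still integrates to one.

## Mixed-effects inference

The observation unit is the per-hour percentile record after segmentation
(not a per-day average): time enters at minute precision and varies within
patients, which is what identifies the within-patient slope. Records past
8,000 minutes (~5.5 days) are dropped — beyond that the variability–time
relation is visibly non-linear and sample sizes thin out, so the model is
fitted on the roughly linear early region.

With cell-means coding (one coefficient per diagnosis group, no global
intercept) and time t in minutes:

y_ij = Σ_k β_k d_k(i) + β_T t_ij + b_0i + b_1i t_ij + ε_ij,
(b_0i, b_1i) ~ N(0, Ψ) per patient.

* **Quadratic route.** The block response is rescaled by 4 to map
  [0, 0.25] onto (0, 1), clamped to [ε, 1−ε] with ε = 10⁻⁶, and
  logit-transformed; the LME is fitted by REML (statsmodels MixedLM). The
  clamp matters only at p = ½ exactly, where the logit would be −∞; ε sets
  the most negative attainable response.
* **One-sided route.** The per-hour indicator 1{p > 0.9} is fitted as a
  logistic-binomial GLMM with the same fixed and random structure. No
  installed Python package offers a frequentist Laplace GLMM with
  correlated random intercept and slope, so `sivar.glmm` implements the
  Laplace marginal likelihood directly: the per-patient 2-d penalised-
  likelihood modes are found by a damped Newton iteration vectorised across
  patients, and log L ≈ pll(b̂) − (G/2)log det Σ − ½Σ log det H_g is
  maximised by L-BFGS-B over (β, log σ₀, log σ₁, atanh ρ). Standard errors
  come from a central-difference Hessian at the optimum. This is the same
  approximation lme4's `glmer` uses at nAGQ = 1, and the test suite
  cross-checks fixed effects and log-likelihood against `glmer` through
  Rscript on a simulated dataset (agreement to ~10⁻² observed). Possible
  complete separation (|β| > 30) is flagged, never silently repaired.

Time is rescaled to days inside the optimisers for conditioning;
coefficients are reported per minute and per day (×1440).

**Model-selection tests.**

* Random structure: LR tests of none → random intercept → intercept+slope,
  on ML (not REML) refits for the LME and on the Laplace likelihood for the
  GLMM. Variance parameters sit on the null boundary, so the naive χ²
  reference (df 1 and 2) is conservative; this caveat is recorded in the
  returned metadata rather than corrected by a mixture reference.
* AR(1) residual check: the LME backend cannot estimate an AR(1)
  within-patient error process jointly, so the check is a pooled lag-1
  autocorrelation of the conditional residuals (fixed effects and BLUPs
  removed) over consecutive hourly records. Removing per-patient BLUPs
  induces a small negative autocorrelation even under independent errors,
  so the null distribution is calibrated by a parametric bootstrap under
  the fitted model: variance components held at their estimates, responses
  resimulated with independent errors, fixed effects re-estimated by GLS
  and random effects re-BLUPed (all linear algebra, 300 replicates by
  default, seeded). Patients with fewer than 3 records are excluded.
* Interaction: a joint 5-df LR test of separate-per-group versus common
  time slopes; non-rejection justifies the common-slope model above.

**Tukey HSD.** All 15 pairwise contrasts of the six group coefficients,
with single-step familywise adjustment
p_adj(k) = P(max_m |Z_m| ≥ |z_k|) under the joint normal of the
standardised contrasts. The contrast covariance has rank 5, so the
15-dimensional rectangle probability is evaluated by quasi-Monte-Carlo on
the underlying 6-dimensional coefficient normal (scrambled Sobol, 2¹⁵
points, fixed scramble seed — deterministic), with p_adj clipped below by
the raw p to preserve single-step dominance. Contrast z-statistics use the
normal reference, as is standard for mixed-model post-hoc contrasts.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any physiological mechanism:

log SI(t+1h) = log SI(t) + s_i + η_t,  η_t ~ N(0, σ_g(t)),
σ_g(t) = σ_day1 · decay^(t/1440) · m_g,

with per-patient lognormal baseline, normal random slope s_i, lognormal
length of stay truncated at 24 h, and group multipliers m_g.

Defaults (chosen once, as the study conditions): baseline
log-mean log 3.0 in nominal 10⁻⁴ L·mU⁻¹·min⁻¹ units with log-SD 0.6
(median SI 3×10⁻⁴ L/mU/min, a typical critically ill value); length of
stay lognormal(log 60 h, 0.5) truncated at 24 h, spanning ~1 to >5.5 days;
day-1 innovation SD 0.25 on the log scale decaying ×0.7 per day (variability
largest at admission, mostly settled by day 4); multipliers
NOpG 0.60 < OpG 0.80 < NOpO 0.90 < OpO 0.95 < NOpC 1.25 < OpC 1.35
(gastric calmest, cardiac most variable); random slope SD 0.002 per hour.
One master seed spawns an independent substream per (group, patient), so
cohorts are reproducible under reordering. An `allow_short_stays` switch
(default off) emits sub-24-h stays to exercise the exclusion path.

What the generator does **not** emulate: glucose/insulin/nutrition
dynamics or any physiological SI identification; measurement gaps and
irregular sampling; informative discharge (length of stay is independent
of a patient's variability); admission transients beyond the smooth
day-scale decay; heavy-tailed or regime-switching innovations. Passing
tests therefore demonstrate that the *pipeline* recovers the structure it
assumes (signs, orderings, calibration), not that clinical SI behaves this
way, and no clinical effect magnitudes are reproduced anywhere.

## Problem sizes and numerical choices

Simulation-based tests run at deliberately modest sizes chosen so the whole
suite completes in a few minutes: e.g. the parameter-recovery experiment
uses 50 replicate cohorts of 36 patients (~2,000 transitions each) and
checks sign and ordering only; LR-test calibration uses 15–25 replicates of
40 × 20 observations with thresholds widened to the binomial error of those
replicate counts; the self-calibration checks use 10,000-transition null
cohorts. The acceptance script fits on ~6,000 transitions and scores a
10,000-transition null cohort (~10 s end to end).

Other numerics: conditional-CDF evaluation is chunked at 4×10⁶
(query × centre) elements with log-sum-exp stabilised weights; quantile
tolerance 10⁻¹⁰ in probability; KDE densities for score summaries on
256-point grids; MixedLM fits retry across optimizers (lbfgs, bfgs, powell,
cg) keeping the first converged fit, because boundary variance estimates
can leave the default optimizer's Hessian singular; GLMM variance bounds
log σ ∈ [−6, 3], atanh ρ ∈ [−4, 4].

## Known limitations

* The GLMM's covariance of fixed effects is a MAP-curvature estimate from
  the Laplace surface; like glmer's, it ignores uncertainty in the variance
  parameters.
* The boundary-conservative LR p-values are reported naive (no 50:50 χ²
  mixture correction), matching common practice; the metadata notes it.
* The AR(1) fallback tests lag-1 dependence only; higher-order or
  continuous-time correlation structures are out of scope.
* With very low event rates the one-sided GLMM can sit near separation for
  calm groups; results carry a flag rather than a repair.
* The level-coordinates KDE variant is retained for comparison but is
  knowingly overdispersed on diagonal transition data (see above); its
  percentiles should not feed the penalties without checking calibration
  first.
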