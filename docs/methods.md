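# Methods

This note documents the models, the synthetic-data generator, the
estimation and numerical choices, and the limitations of the `brainvar`
pipeline.

## The variability statistic and its adjustment

Per-region variability is the root mean squared successive difference
over the preprocessed BOLD series,

    δ_i = sqrt( Σ_{t=2..n} (x_i(t−1) − x_i(t))² / (n − 1) ),

with `n` the number of timepoints. The denominator is `n − 1` — the
timepoint count minus one, even though the sum has `n − 1` terms — kept
as the field convention; `denominator="n-2"` divides by the number of
differences instead (the two differ by a factor `sqrt((n−2)/(n−1))`,
immaterial at n ≈ 400). rMSSD is exactly shift-invariant and absolutely
homogeneous, and for a stationary AR(1) process with marginal variance σ²
and coefficient φ it converges to `sqrt(2σ²(1−φ))`.

The whole-brain adjustment works on successive differences, by analogy
with global signal regression: `g(t)` is the unweighted mean of all ROI
difference series and each ROI's difference series is residualized on
`g` by OLS with intercept. By the normal equations the residuals have
exactly zero sample covariance with `g`; moreover the ROI-mean of the
residual series is identically zero (the ROI-mean OLS slope on `g` is
exactly 1), so whatever variance the adjusted whole-brain summary retains
is, by construction, not the shared component. Adjusted rMSSD applies the
same sum-of-squares/(n−1)/sqrt form to the residual differences, without
re-adding the intercept, so it stays nonnegative. Degenerate inputs
(constant `g`) fall back to mean-centering each difference series.

The adjustment operates at ROI level because the pipeline's analysis unit
is the 246-ROI parcellation; voxel-level inputs are out of scope.
Aggregation takes unweighted means over each network's member ROIs;
regions outside the five named networks count toward the whole-brain mean
only. Motion is residualized from the network/whole-brain *summaries*
across subjects (per column, OLS on mean framewise displacement) — the
summaries are what enter the regressions; per-ROI residualization would
be equally defensible and is not implemented.

## Synthetic cohort

The generator emulates the structure of a large community life-span
study: n = 724 (default), ages uniform on 6–85 (the real cohort's age
histogram is unavailable; uniform gives even support for interaction
probing), 57% female, 10% left-handed, education rising with age to
adulthood, and 423 volumes at TR = 1.4 s (a 10-minute scan minus five
discarded volumes).

**Signal model.** Every ROI is a weighted sum of a shared AR(1) process
and an ROI-specific AR(1) process (lag-1 coefficient 0.3, a plausible
value for band-passed multiband BOLD),

    x_i(t) = w_s · G(t) + s_i · ε_i(t).

Targets are set on the rMSSD scale. The squared global amplitude carries
(i) the global variance share (`global_weight`, default 0.5) of the
cohort-mean squared target, (ii) a per-subject lognormal multiplier
(sd 0.12) representing stable individual differences in global
variability (vascular/arousal-like), and (iii) the motion confound,
`motion_delta_gain · (FD − 0.25)`. The network-specific amplitude of ROI
i follows its network's *adjusted-delta* target

    A_net(age, s) = a0_net + slope_net' · (age − 45.5) + dev_net,s ,

with `a0_net = sqrt(baseline² − ρ·m0)` and the slope rescaled so the raw
rMSSD age slope at the mid age equals the configured
`network_delta_age_slope`. Two composition rules are deliberate:

- the per-subject network deviations `dev` (sd 0.06, delta units) are
  centered to zero ROI-size-weighted mean within subject, and
- the default slopes are chosen so the size-weighted mean slope of the
  adjusted targets is ~0: cortical association networks (CEN, DMN, DA)
  decline with age while the salience network, the subcortical/limbic
  nuclei, and unassigned regions increase, with the common decline
  carried by the global component.

Together these make the adjusted whole-brain summary constant in
expectation across subjects — so, after adjustment, whole-brain
variability is uncorrelated with every network's variability, which is
precisely the decorrelation the adjustment is meant to produce and the
property the acceptance suite checks on the default cohort. Working on
the delta scale (not the variance scale) matters: the whole-brain summary
averages δ values, and centering on the variance scale leaks network
deviations into the whole-brain mean through the concavity of the square
root.

Motion follows a U-shaped age curve, `FD = 0.20 + 1e-4·(age − 40)² +
N(0, 0.06²)` floored at 0.02 mm (cohort mean ≈ 0.25 mm), generated high
in childhood and old age to exercise the residualization step; it loads
on the *global* variance component, so the adjustment (not the
residualization) removes most of it — consistent with treating motion as
a global artifact.

**Task scores.** Factor k for subject s is

    f_k = q_k(age) + Σ_net [ γ_main · A_net + γ_int · (A_net − Ā_net) · (age − mean age) ] + u_k ,

with concave quadratic age curves (peaks 32–40 years, curvature
3–4 × 10⁻⁴ per year²) and disturbances `u` correlated 0.45 across factors
(sd 0.9). The interaction uses the centered delta so it moderates the
slope without injecting a marginal linear age trend that would mask the
quadratic profile. Defaults plant the study's qualitative pattern: a
negative limbic main effect on all four factors (γ = −2.5 per δ unit
≈ −0.15 per SD of A_LN) and DMN-positive / CEN-negative delta-by-age
interactions (±0.12 per δ·year). Indicators are `x_j = λ_j f_k(j) + e_j`
with loadings 0.50–0.82, plus residual covariances between same-task
indicator pairs (LF–CF and two n-back pairs) representing shared method
variance; the pair formed by the two inhibitory-control indicators is
*not* planted because a residual covariance between the only two
indicators of a factor is unidentified (the fit absorbs it into the
loadings; its modification index is exactly zero). Timed scores are
emitted sign-flipped (lower = better) and re-oriented by `reverse_code`
before modeling. Because the factors are not variance-standardized, the
estimable loading under unit-variance-factor identification is
`λ_j · sd(f_k)`; the stored ground truth includes the factor draws so
recovery tests compare against exactly that.

The score pathway uses the generative delta targets (exact ground truth);
`emulated_measured_variability` adds the analytically derived finite-scan
estimation noise (per-ROI relative sd ≈ sqrt((1 + 2((1−φ)/2)²)/(2(T−1))),
independent across ROIs) for fast simulation studies, and the end-to-end
pipeline re-estimates deltas from the generated time series.

**What the generator does not emulate:** volumetric/physiological noise,
scanner artifacts, non-uniform age sampling, missing task data,
non-normal score distributions, and any vascular confounding beyond the
global amplitude. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness
to every property of real data.

## Factor model estimation

The CFA is identified by unit-variance factors with all 14 loadings free
— the only convention under which the hypothesized model has
105 − (14 + 14 + 6) = 71 degrees of freedom, and the modified model with
four freed residual covariances has 67. `F_ML` is minimized by L-BFGS-B
with analytic gradients (`dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) dΣ]`), deterministic
multistart (three start points varying the communality split and factor
correlation), a polishing pass at tight tolerances, and residual
variances bounded at 10⁻⁶ (solutions at the bound are flagged as Heywood
cases). Convergence requires max |gradient| < 10⁻⁴ over free coordinates
off their bounds. χ² uses the (n − 1) multiplier (configurable to n);
CFI uses the diagonal-covariance independence baseline; RMSEA is
`sqrt(max(χ²−df,0)/(df(n−1)))`; SRMR averages squared standardized
residuals over all p(p+1)/2 unique elements including the diagonal.
On one-factor problems the engine reproduces statsmodels' exploratory ML
factor analysis (the same optimum) to ~10⁻⁸, and on the four-factor model
it agrees with an independently parameterized numerical-gradient
minimizer to < 10⁻⁴ in F_ML.

Modification indices are proper score tests: for an eligible pair
(sharing both the task and the factor) the statistic is
`(n−1)/2 · g² / (H_cc − H_cf H_ff⁻¹ H_fc)` with `g` the F-gradient of the
candidate covariance and `H` the expected information
`tr(Σ⁻¹ dΣ_a Σ⁻¹ dΣ_b)` over free parameters plus candidate. The default
modification count is four (matching the 71 → 67 df drop); re-fitting is
the caller's responsibility, and the pipeline applies the modification
only when the hypothesized model is suboptimal by the configured
thresholds (CFI < 0.95, RMSEA > 0.08, or SRMR > 0.06). On the default
synthetic cohort the hypothesized model fits better than those thresholds
— real test batteries carry more method variance than the three planted
residual covariances — so the modification path is exercised by dedicated
tests with planted misfit rather than by the default pipeline run.

Factor scores use the regression method, `W = ΦΛ'Σ̂⁻¹`, applied to
mean-centered indicators from the final model; this equals the
GLS/posterior form `(Φ⁻¹ + Λ'Θ⁻¹Λ)⁻¹Λ'Θ⁻¹` when Θ is invertible (a
tested identity). Missing scores are handled by listwise deletion.

## Regressions, multiplicity, and probing

One model per (outcome, predictor) pair — six collinearity-prone
predictors are never entered jointly. Sex and handedness enter as
indicator variables (female = 1, left = 1), education in years. Age is
mean-centered at the sample mean; the interaction column is the product
of the predictor with centered age. Standardized coefficients come from a
fully z-scored refit in which the interaction column is the product of
the z-scored constituents (for main-effects models this equals
`b·sd(x)/sd(y)` exactly). BH-FDR is applied to the focal term within each
(outcome × effect-type) family of six predictors. Simple slopes at the
four cohort mean ages (13.17, 27.01, 50.09, 69.42 years) use
`b_δ + a·b_int` with delta-method variance
`V_dd + a²V_ii + 2aV_di`; this is algebraically identical to re-centering
age at the probe value and re-fitting, a tested 10⁻¹⁰-level identity.
Age curves are fit on QR-orthogonalized powers of centered age
(default degree 2) with coefficients reported in the raw centered-power
basis; the peak age is the vertex of a concave quadratic. With the
default generator the *marginal* fitted peaks sit a few years below the
generative curve peaks because the planted variability effects carry
their own mild age structure.

A known emulation caveat: because network deltas trend with age and the
fitted models are linear in age, a quadratic factor-age profile leaks
into the delta-by-age product (which contains an age² component). This
mildly inflates interaction estimates for declining networks — a bias the
real analysis shares by design, since its models are likewise linear in
age. The type-I-error calibration therefore uses a null configuration
with both the γ coefficients and the age curvature set to zero, so the
fitted null model is correctly specified.

## Determinism and I/O

All randomness descends from a single integer seed through named
`SeedSequence` streams (per-subject streams keyed by subject index), so
identical configs give byte-identical outputs. Interchange is headered
CSV/TSV; time-series matrices are written timepoint-rows × ROI-columns
with `%.17g` floats and parsed with round-trip float precision, so
write-then-read preserves values bit-exactly. Subjects with mean FD ≥
0.5 mm are excluded at phenotype load (strict "below 0.5 mm" inclusion);
time-series files with non-finite values or fewer than 10 timepoints are
skipped with a logged reason.

## Problem sizes used by the test suite

The suite exercises the pipeline at reduced scale chosen to keep every
property statistically decisive: the decorrelation check uses the default
cohort at 500 subjects; CFA oracle equivalence uses a fixed 724-subject
covariance; loading recovery uses 5,000 subjects on the score pathway
(no time series); calibration uses 1,000 null replicates and 120 power
replicates at n = 724 via the emulated-measurement pathway; end-to-end
determinism uses an 80-subject, 60-ROI, 80-timepoint cohort.

## Limitations

- No full-information ML for missing data; listwise deletion only.
- No RMSEA confidence intervals, measurement-invariance testing, or
  categorical-indicator estimators.
- The ML χ² inherits the usual sensitivity to excess kurtosis; no robust
  (Satorra–Bentler-style) corrections are implemented.
- Voxel-level adjustment, NIfTI ingestion, and preprocessing (motion
  correction, ICA denoising, band-passing) are out of scope; inputs are
  assumed preprocessed ROI series.
- The whole-brain summary weights networks by ROI count; an
  equal-network-weight variant is not implemented.
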