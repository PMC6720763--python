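# Methods

## Scope and assumptions

`odormix` models the odor intensity (OI) of single odorants and binary
mixtures on the VDI 3940 seven-point scale, and its estimation from an
8-channel gas-sensor array.  Three standing assumptions run through the
package:

* Panel-rated intensities are integers in 0–6; model-predicted
  intensities are continuous, clamped below at 0 (the scale has no
  negative intensities) and flagged — not clamped — above 6.
* Single-odorant psychophysics is log-linear (Weber–Fechner) or power-law
  (Stevens) over the studied concentration ranges; "log" is base 10
  throughout.  Base 10 is not a convention choice here but an empirical
  one: only base-10 inversion of the fitted coefficients reproduces the
  published per-level target concentrations (e.g. the toluene row 1.1 /
  3.6 / 11.5 ppm exactly at printed precision).
* Mixture interactions are pairwise and captured by a single scalar
  cosα per pair (per design level for the sensory-fitted models).

## Psychophysical fitting

Both laws are fitted by unweighted OLS in the coordinates in which they
are linear — OI vs log₁₀C and log₁₀OI vs log₁₀C — matching the
conventional graphical determination; no nonlinear refit is attempted,
since the reference coefficients were produced the same way.  The
Weber–Fechner threshold C_OT = 10^(−a/b) and Stevens prefactor
k_S = 10^a are back-transformed from the regression intercept; their
standard errors use the delta method with the OLS slope–intercept
covariance (cov(a,b) = −x̄·SE_b²).  Points with OI ≤ 0 are excluded
(with a warning) from the log–log Stevens fit.  Degenerate designs (all
concentrations equal) and non-monotone fits (slope ≤ 0) raise typed
errors rather than returning invalid laws.

The panelist screen accepts iff 10^s ≤ 2.3 with s the sample (n−1)
standard deviation of repeated ratings.  The criterion's published
typography is ambiguous between 10·s and 10^s; it is implemented as the
exponential form, under which the bound corresponds to s ≤ log₁₀2.3 ≈
0.36 — a plausible repeatability requirement, where 10·s ≤ 2.3 (s ≤ 0.23)
would reject a panelist who alternates between two adjacent integer
ratings, which integer scales make common.

## Perceptual mixture models

The vectorial and U predictors and their algebraic inverse estimators are
exact inverse pairs (property-tested).  Estimates from noisy panel means
can leave [−1, 1]; they are clamped with a structured
`CoefficientRangeWarning` and a `clamped` flag rather than rejected — the
triangle bound is a property of exact intensities, not of noisy means,
and discarding such pairs would bias coefficient tables toward weak
interactions.  Replicate mixture ratings are averaged on the sensory
OI_AB before the coefficient is computed (coefficients are convex in
OI_AB for neither model, so averaging first vs per-replicate estimation
differ; averaging first matches the use of panel-mean intensities).

UPL coefficients are level-free: cosα_X = 2^(n_X−1) − 1 per component,
combined pairwise as the intensity-weighted mean, which reduces to the
plain mean at equal intensities — the only case in which the
single-component formula is exact, and the form in which UPL tables are
reported.  The weighted form is exposed for unequal-intensity use.

Interaction matrices are keyed by unordered pair, so symmetry holds by
construction and the diagonal is never stored.

## Fuzzy e-nose engine

The engine is a classic Mamdani stack; the published description fixes
only Gaussian membership functions and centroid defuzzification, so the
remaining operators are the standard choices: AND = minimum, implication
= clipping (min), aggregation = pointwise maximum.

* **Calibration** fits each (sensor, level) Gaussian from the sample mean
  and (n−1) standard deviation of the training signals at that level;
  cells with fewer than two samples are an error naming the cell.
  Zero-variance cells (replicate-identical signals) fall back to a
  configurable sd floor, default 1% of the sensor's observed signal
  range, so degenerate membership functions cannot arise.
* **Rule learning** is Wang–Mendel from labeled samples: antecedent =
  per-sensor argmax-membership level (ties to the lower level),
  consequent = label, degree = product of winning memberships; identical
  antecedents are conflict-resolved by degree.  One homogeneous rule per
  trained level ("all sensors at L ⇒ L") is always included and takes
  precedence on conflict, guaranteeing the canonical diagonal of the rule
  table.  Degrees are used only at learning time, not to weight firing.
* **Inference** integrates the aggregated output set over the VDI axis
  [0, 6] at grid step 0.01 and returns the centroid, computed with
  trapezoidal moments (the aggregate is nonzero at the support ends,
  where a plain Riemann sum loses first-order accuracy; trapezoidal
  integration agrees with a 10×-finer grid to ~2·10⁻⁵).  If no rule
  fires above a configurable floor (10⁻⁶) a diagnostic error carries the
  per-rule strengths.

**Output sets** are Gaussians centered on the integer levels 0–6 with a
common sd, default **0.4**.  The default is set by the truncation
geometry of the support: a single fired rule at level 1 or 5 has its
output Gaussian cut at 2.5σ on one side only, biasing the centroid
outward by σ·φ(2.5)/Φ(2.5) ≈ 0.007 for σ = 0.4, versus ≈ 0.028 for
σ = 0.5 — large enough to misreport a trained level by several
hundredths.  The width is configurable where smoother interpolation
between levels matters more than edge fidelity.

Trained levels default to 1–5 (single-odorant calibration samples);
levels 0 and 6 keep output sets for centroid support but carry no
antecedent membership functions unless trained.  Signals enter as raw
stop-flow maxima; no baseline normalization is applied.

## Gas generation

Bubbler mass flow W = P₀MV̇/(10³RT) assumes the carrier leaves the vial
saturated; the ppm conversion c = 24.04·W/(10⁻⁶V̇M) hard-codes the 20 °C
molar volume, as the published formulas do.  Composing the two,
c = 24.04·10³·P₀/(RT): flow and molar mass cancel, and the result agrees
with the exact saturation mole fraction 10⁶·P₀/p_atm to < 0.3% at 293 K
(asserted over all eight odorants); a `strict` flag recomputes with
RT/p_atm instead.  Stream mixing is exact per-odorant mass balance.
`plan_mixture` inverts the Weber–Fechner laws for target concentrations
and splits a default 5 mL/s (300 mL/min) delivered flow between saturated
source streams and dilution air, erroring on targets above saturation.
Units follow the generator conventions (V̇ in mL/s, W in mg/s, E in ng/s,
ρ in ng/nL); conversions happen only at I/O boundaries.

## Synthetic data generator

The generator emulates the two data sources the estimators need:

* **Panel**: ratings = clamp(round(OI_true + ε), 0, 6), ε ~ N(0, sd),
  default sd 0.3 OI units with triplicate mixture ratings (single-odorant
  designs use 10 panelists × 5 two-fold concentrations).  The default
  noise is what makes a trained panel: raters agree within a fraction of
  a scale step on average, yet integer rounding and clamping leave
  visible scatter.
* **Sensors**: signal = baseline + [Σ_o a·log₁₀(1 + c_o/κ)]·(1 − γ·𝟙mix)
  + N(0, sd).  The log-saturating form is MOS-like; the single
  multiplicative suppression γ per sensor is the simplest structure that
  makes mixture responses non-additive, mirroring the premise that
  inter-sensor signal relations carry the interaction information.  The
  default parameterization draws sensitivities (0.4–1.6 per decade) and
  scales (2–16× each odorant's threshold) once from a fixed seed, so the
  five VDI levels fall on the informative part of each response curve.

What the generator deliberately does **not** model: sensor kinetics and
transients (only the stop-flow maximum exists), drift,
temperature/humidity effects, inter-panelist bias structure, and any
odor-quality dimension.  Passing recovery tests therefore demonstrate
estimator correctness under the assumed noise structure, not robustness
to real-hardware pathologies.

## Problem sizes and test design

The parameter-recovery experiments run at the sizes of the emulated
study: 8 odorants, 28 unordered pairs, triplicate mixture ratings,
5 levels × 3–5 replicates of e-nose training samples — small enough that
the full suite runs in seconds.  The cosα-recovery check runs on the
level-2 design: at level 1 several true mixture intensities sit near 0.5,
where VDI integer rounding alone moves the vectorial estimate by ~0.1
(the estimator's sensitivity dcosα/dOI_AB = OI_AB/(2·OI_A·OI_B) is
maximal there), whereas at level 2 the same sensitivity is four times
smaller and recovery is well-conditioned.  The end-to-end noise-trend
check holds the calibration fixed (moderate 0.05 training noise) and
shrinks only the measurement noise, because the prediction error has a
structural floor — mixture suppression is absent from single-odorant
calibration — that does not shrink with noise.

## Known limitations

* The published vectorial (level 2) and U (level 2) coefficient tables
  are mutually inconsistent at exactly one cell (o-xylene/n-hexane):
  converting the vectorial −0.62 through the shared mixture intensity
  implies a U coefficient of −0.564 where −0.54 is printed, just outside
  the ±0.02 rounding band that every other cell of both levels satisfies.
  The package reproduces the conversion faithfully and the corresponding
  consistency test documents the discrepant cell rather than widening the
  band.
* Interaction coefficients are pairwise and level-specific; nothing here
  extends to ternary or higher mixtures.
* The fuzzy model trained on single-odorant samples inherits their
  selectivity: mixtures whose suppressed signatures resemble a lower
  single-odorant level are under-predicted, which is the structural error
  floor discussed above.
* Published model-vs-panel error statistics for the real instrument
  cannot be recomputed without the raw sensor recordings, which are not
  public; the synthetic closure and property tests stand in for them.
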