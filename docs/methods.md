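# Methods

This note documents the statistical machinery, the calibration of the
synthetic cohort, the numerical choices, and what the tests do and do not
establish.

## Adherence metrics

Dates are 0-based integer day indices against the observation-period start
(2018-04-01 when converting ISO dates); a fill on day *d* with *s* days of
supply covers days *d … d+s−1*, closed on both ends.

**MPR** = Σ days-of-supply / (last fill − first fill + last supply), over
fills of the eligible controller classes. Patients with fewer than two
eligible fills are coded 0 — the variable-interval denominator is
undefined for one fill, and the zero code keeps all N patients usable for
covariance estimation. MPR is uncapped by default: the printed median 0.66
is consistent with an uncapped ratio, and no cap is stated in the source
material; `AdherenceConfig(cap_at_one=True)` caps it.

**PDC** = distinct covered days / denominator. Each calendar day counts at
most once (no stockpile carry-forward — the defining text says "covered
days", not supply days, and gives no stockpiling rule), and the numerator
is truncated at the denominator's end so PDC ≤ 1 by construction. The two
textual readings of the denominator disagree; the default is
FIRST_FILL_TO_PERIOD_END (the standard PDC and the more complete textual
statement), with FIRST_TO_LAST_FILL available via configuration.

A consequence worth stating explicitly, because it shapes the generator:
for any multi-fill patient, **MPR ≥ PDC is an identity** under the default
denominator — total supply ≥ distinct covered days, and the first-to-last
span is contained in the first-fill-to-period-end window. Only single-fill
patients (MPR coded 0) sit below their PDC.

**QCI** is a weighted sum over 17 comorbidity categories (weights 1/2/3/6,
each counted once, range 0–33), taken as boolean category flags; mapping
raw ICD codes to categories is out of scope.

## Path models from summary statistics

A `SummaryDataset` (names, n, means, SDs, covariance) is sufficient for
every model here. The printed covariance table is slightly asymmetric in
its PCP row (transcription artifacts up to 0.025); `symmetrize` averages
the triangles and reports every disagreement — there is no basis to prefer
either triangle. Positive semidefiniteness is validated (relative
tolerance 1e-8) and, when requested, repaired by eigenvalue clipping with
the perturbation norm reported. The baseline and all lateralized/perturbed
matrices used here are comfortably positive definite; no repair fires in
the shipped pipeline.

Models are recursive (acyclic) systems over observed variables, layered
exogenous → mediators → outcome. Estimation is equation-by-equation least
squares on the covariance matrix (β = Σ_XX⁻¹ Σ_Xy, residual variance
σ²_y − βᵀΣ_Xy), which coincides with maximum likelihood for recursive
systems with uncorrelated errors. Exogenous covariances are fixed at their
sample values; mediator residual covariances are constrained to zero.
Standard errors are normal-theory OLS forms reconstructed from the
moments with df = n − k − 1 (the source does not state its SE machinery).

Standardized total effects are (I − B_std)⁻¹ − I. Two independent oracles
verify the implementation: reduced-form equivalence (saturated totals of
exogenous variables equal single-regression standardized coefficients) and
brute-force path enumeration on small graphs. Significance of totals uses
the multivariate delta method with block-diagonal (per-equation)
coefficient covariances and a finite-difference Jacobian (step 1e-7) —
standard for path analysis; the source is silent on its method.

The estimated model is the fully saturated layered model. Published path
diagrams show only significant paths of a larger fitted model, so
`prune_and_refit` (drop p > 0.10, refit once) is provided as a sensitivity
mode, not the default. One published column (the claims-only PDC model)
prints age/QCI totals (0.1451 / −0.0283) that are inconsistent with the
saturated reduced form reproduced by every other PDC column — they equal
that model's *direct* effects (we compute 0.1456 / −0.0285), suggesting a
labeling slip in the source table. They are documented, not targeted.

**Fit statistics.** SRMR is the RMS of sample-minus-implied correlations
over unique elements, including standardized-variance diagonal residuals
(the common software convention; no formula is given in the source). CD is
the determinant ratio 1 − det(Ψ̂)/det(S_endog); it reduces to R² for a
single equation. Note that with mediator residual covariances fixed at
zero, the layered models do not reproduce the (large) mediator–mediator
covariances, so SRMR ≈ 0.21 and CD is negative for the battery models;
SRMR = 0 holds exactly for genuinely saturated structures (≤ 1 mediator).

## Lateralization and scenarios

A `LateralVariable` carries an assumed mean, SD, and named
cross-covariances taken literally on the covariance scale; unspecified
cells default to 0. The rewards–engagement entry 0.82 is read as a
covariance (implying a near-zero correlation given SDs 15 and 180); only
this reading reproduces the identical rewards totals with and without
engagement in the model. The alternative correlation reading is exposed
via `treat_cross_as_correlation`. Scenario multipliers (1.1 / 1.2 / 0.9 /
0.8) apply to the four lateral–adherence cells only, never to
lateral–mediator cells.

## Synthetic cohort

The generator's contract: the *recomputed* statistics of the generated
cohort — including MPR/PDC recalculated from the realized fills — match
the printed tables.

**Marginals.** Age: truncated normal on [18, 95], truncated moments
matched to 49.64/14.87, rounded to years. Utilization counts: negative
binomial matched to the printed mean/variance — this alone reproduces the
printed zero masses (3.0% with ≥ 1 hospitalization; ~1.4% vs printed 1.8%
for ER), so no explicit zero-inflation is added. All-medication fills and
QCI: shifted (1 +) negative binomials — every cohort member has ≥ 1 fill,
and asthma itself contributes a chronic-pulmonary point; QCI capped at 33.
PDC: Beta matched to mean/SD (0.59/0.2866). MPR: point mass at zero (the
single-fill rule) plus a Beta body.

**Dependence.** A Gaussian copula with the latent correlation matrix
obtained by inverting the NORTA map pairwise. The inversion is exact, not
approximate: discrete marginals are step functions of the latent normal,
so each pair expectation is computed by integrating the outer variable's
constant pieces exactly (Gauss–Legendre within each piece) against the
inner variable's analytic conditional expectation over its jump
thresholds. (A naive Gauss–Hermite tensor rule was off by a factor of ~2.5
for the heavy-tailed count pairs and was discarded.) The assembled latent
matrix is repaired to the nearest PSD correlation matrix if needed.

**The feasibility floor.** An unconstrained copula draws MPR < PDC for
roughly a third of multi-fill patients — geometrically impossible (see the
identity above) and, when clamped at realization time, it destroyed the
printed moments. The generator therefore floors MPR at PDC for multi-fill
rows *at the sampling stage*, and calibrates the MPR mixture (zero mass
p0, Beta body) and the MPR–PDC latent correlation *through* the floor:
common-random-number simulation (60 000 draws, fixed internal seed) inside
a least-squares solve over [mean, SD, median, corr]. The MPR–covariate
latent correlations likewise cannot use the plain NORTA map (observed MPR
is a function of two latents), so each is inverted by a three-latent CRN
simulation holding the covariate's known PDC-latent correlation fixed.
Calibration is deterministic and memoized (~20 s once per target).

**Latent draws.** Scrambled-Sobol QMC (`scipy.stats.qmc`
`MultivariateNormalQMC`) rather than iid normals: same distribution, far
smaller integration error, so sampled means sit within ~1e-3 of the
targets at every seed. With iid draws, a "means within ±2 SE at one fixed
seed" check is a per-variable 95% event — about 40% fragile across ten
variables — which is a property of the check, not of the generator.

**Claims realization.** Single-fill patients (MPR = 0) get one fill placed
late enough that supply/window matches their PDC (a late first starter
legitimately carries a high PDC under the first-fill denominator); PDC
targets below 30/365 (~1.3% of patients) are clamped to the floor and
tallied. Multi-fill patients get a contiguous run of ≈30-day fills whose
supplies sum exactly to the covered-day count C = round(PDC·W), plus a
final fill ending the span at round(C/MPR); overlapping-supply layouts
handle MPR > 1. Realized PDC is exact to one day in the window and MPR to
span rounding. The all-medication fill budget is respected by growing
per-fill supplies to 90 (rarely up to ~182) days; the claim count exceeds
the budget only for multi-fill patients whose profile says one total fill,
inflating the mean fill count by ≈ +0.026 (well inside 2 SE = 0.076).
Length of stay is a per-patient lognormal aggregate anchored at the
printed median (4) with the printed mean (5.61) matched, floored at the
hospitalization count; it is descriptive only, as in the source.

**What a green generator test establishes — and what it does not.** The
default cohort reproduces the ten means (within 2 SE), the full
correlation matrix (max error ≈ 0.008 against a 0.03 band), mean PDC
(0.591), and the median-MPR/median-PDC ordering (0.672 > 0.625). It does
not emulate: real supply-length distributions (supplies are ~30 days by
construction), seasonal fill timing, enrollment churn, ICD/GPI code
detail, or any causal structure beyond the printed second moments — the
copula is a dependence model, not a behavioral one. Effects estimated
from regenerated cohorts therefore validate the *pipeline*, not any new
clinical claim.

## Numerical choices and degenerate inputs

- Sample covariances use the n−1 denominator throughout.
- PSD tolerance: smallest eigenvalue ≥ −1e-8 × largest; repair = eigenvalue
  clipping at zero, perturbation norm reported.
- Collinear predictor sets raise an estimation error naming the equation;
  spectral radius ≥ 1 aborts effect decomposition.
- Copula uniforms are clipped to [1e-12, 1 − 1e-12]; discrete quantile
  tails are truncated at the 1 − 1e-11 quantile (mass reassigned to the
  last support point).
- Zero-mediator specs degrade to single regressions; empty cohorts,
  mismatched SSD files, and observation windows ending before the first
  fill raise typed errors.
- CLI exit codes: 0 success, 2 input error, 3 estimation error.

## Known limitations

- The delta-method significance of totals assumes cross-equation
  independence of coefficient estimates (exact for recursive systems under
  normality) and large-n normality; no bootstrap is provided.
- The two published claims-only PDC totals discussed above are not
  reproduced by any saturated fit and are treated as a source
  inconsistency.
- The generator matches first and second moments and three quantile
  anchors (the medians of age proxy through the truncated normal only
  approximately; count medians match by construction of the NB families).
- Multiple-testing correction across the 16 models is deliberately absent,
  matching the source analysis.
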