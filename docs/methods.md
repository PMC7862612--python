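# Methods

This note records the statistical model, the generative assumptions of the
synthetic data, the numerical choices, and the limits of what the test
suite demonstrates.

## The factorial model and its contrasts

Immune endpoints are analysed on technical-replicate means, one
observation per fish × time × LPS × concentration cell. The model is a
fixed-effects linear model with per-fish base levels and additive effects
of exposure duration (3 h vs 19 h), LPS stimulation, and concentration
treated as an unordered factor, plus the three interaction families
time×LPS, time×concentration and LPS×concentration. Residuals are iid
Gaussian. For |F| fish and |C| non-control concentrations the design has
1 + (|F|−1) + 1 + 1 + |C| + 1 + |C| + |C| columns under reference-level
coding (first fish by order of appearance, 3 h, no LPS, concentration 0);
a complete balanced design is full rank. The equation as written with a
full set of fish indicators would be over-parameterised; reference coding
is the conventional resolution and matches what standard linear-model
software does by default.

Estimation is ordinary least squares (`numpy.linalg.lstsq`), with rank
detected by column-pivoted QR; aliased columns of a rank-deficient design
are reported and the covariance uses the Moore–Penrose generalised inverse
σ̂²(XᵀX)⁻, σ̂² = RSS/(n − rank). Treatment questions are Wald tests of
linear combinations c'β̂, two-sided against Student-t with the residual
df. The standard comparison set is, per time point: stimulated vs
non-stimulated control; and each concentration vs its control, without
and with LPS — at 19 h the corresponding interaction coefficients enter
the combination. The LOEC is the smallest tested concentration with
p ≤ 0.05 versus control (ties to the printed significance rule; the rule
is ≤, so p exactly 0.05 counts). No multiple-testing correction is
applied, deliberately, because the screen's decision rule is a raw
p < 0.05 per comparison; this is a property of the procedure being
modelled, not an oversight, and it is exposed rather than silently
changed. Concentrations never enter as a numeric trend.

qPCR endpoints are analysed on the ΔCt scale; other endpoints on the
normalised response scale.

## Synthetic data: what it emulates and what it does not

The assay generator draws, per treatment cell, a shared biological
residual (SD `residual_sd`) and independent per-well technical noise
(SD `technical_sd`); replicate averaging therefore matters — the averaged
observation has variance `residual_sd² + technical_sd²/n_technical`. The
paper-level analysis assumes only the first component; the second is
artifact plumbing that makes the averaging step consequential and is set
to 0.5 (half the biological residual) by default in the calibration
studies. Fish effects are fixed offsets, not draws from a random-effects
distribution, matching the fixed-effects formulation. Viability follows a
decreasing Hill curve (the standard in vitro concentration–response
shape; the generator is not claimed to match any real range-finding
curve). Ct tables use a per-sample reference-gene draw plus gene-wise
ΔCt offsets and duplicate-level cycle noise, constrained to the 45-cycle
window.

Because no effect magnitudes or residual variances are published for the
original fits, the default truth parameters are illustrative: chosen once
as values a plate screen plausibly produces (intercepts ~10 signal units,
LPS effect ~3, suppressions up to −4, residual SD 0.5–1). Passing tests
therefore demonstrate that the *procedure* is correct and calibrated
under its own assumptions — not that any specific biological effect size
is recoverable from real fish data, which show larger inter-individual
variability, non-Gaussian tails and plate effects that the generator does
not emulate (no edge effects, no flow-cytometry event noise).

`residual_sd = 0` is permitted (the validation bound is ≥ 0) so that
noise-free interpolation checks — residuals exactly zero, coefficients
equal to the generating values — are expressible.

## Plate QC

Blank normalisation subtracts the mean blank per endpoint grouping.
"Technical error" in the LPS validity rule is the pooled (df-weighted)
SD of the fish's control technical replicates, with an exposed multiplier
k (default 1.0): valid ⇔ stim − unstim > k × pooled SD. The exact formula
behind the original rule is not published in full; the pooled SD with
k = 1 is the declared interpretation. Exclusion is per fish × endpoint,
since valid n can differ between parameters.

## EC20 and the non-cytotoxic range

Viability is (calcein/DAPI) normalised to the same scenario's control, so
control ≡ 1 and any common rescaling of both signals cancels. The EC20 is
found by log-linear interpolation of viability between the two tested
levels bracketing 0.8 — not by fitting a four-parameter curve, because
the screen reports threshold exceedance per tested level and
interpolation is the minimal added assumption. The control is excluded
from the log interpolation (log 0 undefined); if the lowest non-zero
level is already below 0.8, that level is reported as an upper bound;
with no level below 0.8 the result is censored "> max tested".
Non-monotone curves use the first crossing from low concentration and are
flagged. Per-scenario EC20s (3 h/19 h × ±LPS) are averaged for summary
reporting.

## Partitioning model

Compartment capacities are V_water, D_protw·V_protein, D_lipw·V_lipid and
K_aw·V_air; fractions are capacities over their sum. The nominal
IC10_baseline is the dose at which the lipid phase reaches the critical
membrane concentration (69 mmol/L lipid): C_w = C_crit/D_lipw, mass =
C_w·Σcapacities, nominal = mass/V_medium, with V_medium = water + protein
+ lipid volumes — the headspace contributes capacity but is not part of
the dose volume, so air loss appears as a deviation flag (volatile when
the air fraction exceeds 10%) rather than as a dose correction. mmol/L
converts to µM by a factor 1000; no other unit factors enter.
The default `CompartmentSystem` volumes are a documented stub for a
microplate well; the original study's adapted protein/lipid contents are
not published in its main text, so reproducing its absolute IC10 values
(e.g. for dexamethasone) is out of reach without those inputs — the
model's correctness is instead established by conservation,
forward–backward inversion and monotonicity properties.

## Ratios and censoring

TR = IC10/EC20 with "specific" strictly above 10 (the ≤ boundary is
non-specific); SR = EC20/LOEC with "specific" strictly above 10. TR within
±1 of the threshold carries a borderline flag, because a screen-level
call at e.g. TR = 10.9 deserves surfacing rather than silent
mechanisation. Censored EC20s and non-determinable LOECs never yield a
finite ratio; where one side is finite a bound at the censoring limit is
attached, marked as a bound. Scenario averages are arithmetic means over
the determinable values; an all-censored set stays censored. Per-endpoint
SR is computed per scenario and then averaged (primary mode); the ratio
of the averaged EC20 and LOEC columns is also emitted because the two do
not coincide and the difference is informative. Table output rounds to
one decimal, half away from zero; machine-readable outputs keep full
precision.

## Monte-Carlo calibration studies

`leukotox.montecarlo` draws replicate datasets at the averaged-cell level
(biological residual plus the mean of n technical noise draws — identical
in law to simulating wells and averaging) and pushes each through the
ordinary `fit_ols`/`wald_contrast` path. The type-I study uses 10,000
replicates of a 6-fish, 3-replicate, 3-concentration design with all
effects zero; the coverage study uses 2,000 replicates with non-zero
effects. These sizes give Monte-Carlo SEs of ~0.002 (rejection rate) and
~0.005 (coverage), small enough to resolve miscalibration of a few
percent. Coverage is asserted within ±3.3 Monte-Carlo SEs per
coefficient because ~19 coefficients are checked jointly.

## Known limitations

* Fixed-effects only; no random-fish hierarchy, so inference is
  conditional on the sampled fish.
* No plate/edge-effect correction and no dose–response curve fitting for
  immune endpoints (discrete levels only).
* qPCR efficiency is fixed at 2 per cycle; no efficiency correction,
  multi-reference averaging, or melting-curve analytics.
* Partitioning assumes equilibrium and ignores plastic sorption and
  ionisation corrections; distribution ratios are inputs, not predicted
  from structure.
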