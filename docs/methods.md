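# Methods

This note documents the models, conventions and design choices behind
`pkmarker`, and what the synthetic-data generators do and do not emulate.

## Non-compartmental analysis

**Model-free parameters.** For one IV-bolus concentration–time course the
package reports Cmax/Tmax over the quantifiable observations, trapezoidal
AUC₀₋ₜ and AUMC₀₋ₜ to the last quantifiable point, the terminal rate
constant λz, t½ = ln2/λz, AUC₀₋∞ = AUC₀₋ₜ + C_last/λz (observed, not
λz-predicted, C_last — the classic WinNonlin/DAS convention),
AUMC₀₋∞ = AUMC₀₋ₜ + C_last·t_last/λz + C_last/λz², MRT = AUMC/AUC at both
horizons, CL = Dose/AUC₀₋∞ and Vz = CL/λz. With dose in µg/kg, time in h
and concentration in ng/ml (≡ µg/L), CL comes out in L/(h·kg) and Vz in
L/kg with no hidden conversion factor. The published "Vd" column is
interpreted as Vz; the terminal-phase volume is the only one an IV-bolus
NCA can deliver without a steady-state design.

**λz window selection.** Candidate windows are the suffixes (length ≥ 3) of
the quantifiable tail. For profiles whose maximum is not at the first
sample the points up to and including Cmax are excluded (no distribution
phase should leak into the terminal fit); IV-bolus-shaped profiles (Tmax at
the first sample) may use every point. Each window is fit by ordinary least
squares on ln C vs t; the window with the highest adjusted R² wins, with
ties closer than 10⁻⁴ resolved toward the larger window (more points, more
stable slope). A window is only acceptable with a strictly negative slope;
otherwise the terminal phase is *inestimable* and the terminal-dependent
parameters propagate as missing values — mirroring the dashes a bioanalyst
prints when plasma levels fall below quantification too early.

**Trapezoid rules.** The default is the plain linear trapezoid; a
linear-up/log-down variant applies the logarithmic mean on strictly
decreasing positive segments (exact for mono-exponential decline; the AUMC
log segment uses the matching closed form (t₁C₁ − t₂C₂)/k + (C₁ − C₂)/k²).
The original software's rule is not public, so the rule is a caller option
rather than a fixed behaviour.

**No back-extrapolation to t = 0.** Areas start at the first observed time.
The study's first sample is 2.4 min post dose, so the untracked head area is
a few percent of total exposure for the fastest-eliminated analytes (k ≈ 3/h)
and negligible for slow ones; this is a documented convention, not a claim
that the head area is zero. Callers who need exact closed-form agreement in
simulation studies should include t = 0 in the sampling grid.

**BLQ handling.** Below-quantification observations are stored as 0 with a
flag. Leading BLQ points enter the trapezoid as zeros (pre-dose or not-yet-
detectable), embedded BLQ points are excluded (a missing value between two
quantifiable ones), trailing BLQ points are excluded entirely. BLQ points
never enter the λz fit.

## Integrated multicomponent PK

Three constructions collapse the co-dosed analytes of one subject into a
virtual single-analyte profile on the shared sampling grid (no resampling or
interpolation across grids is attempted):

* concentration sum: C_Z(t) = Σᵢ Cᵢ(t);
* AUC-weighted: ωᵢ = AUCᵢ / Σⱼ AUCⱼ, C_Z = Σ ωᵢCᵢ;
* effect-weighted: ωᵢ = AUCᵢ^effect / Σⱼ AUCⱼ^effect, C_Z = Σ ωᵢCᵢ.

Weights are dimensionless, non-negative and sum to 1 (±10⁻¹²). Integration
is performed **per subject**, NCA per subject, then group mean ± SD — a
group-mean-curve route would hide between-animal variability from the
summary SDs. AUC weights are computed from dose-group mean AUC₀₋ₜ (one ω
set per dose group): the weights describe the preparation's exposure
composition at that dose, and per-animal weights would fold subject noise
into the definition of the virtual analyte. Summation happens on the mass
scale (ng/ml), matching how multi-analyte bioanalysis reports
concentrations; a molar-basis integration is available through the explicit
mass-to-molar conversion. BLQ observations contribute 0 to sums — the
censored mass is negligible against the dominant analyte. The virtual
analyte's dose is the same ω-combination of the per-analyte doses, which
keeps CL and Vz of the integrated profile on the usual scales.

## Concentration–effect weighting

Protection rate is the exact assay ratio
(OD_treated − OD_model)/(OD_normal − OD_model) × 100, computed on group
means when replicate vectors are supplied; it is invariant to affine
rescaling of all ODs and may legitimately be negative (treatment worse than
the injury model) or above 100. Effect curves interpolate linearly between
the measured (µM, %) points — with 2–4 points per ingredient any parametric
dose–response fit (4PL, Emax) would be over-modelling. A zero anchor
(0 µM, 0%) is prepended by default: no drug means model-group OD, hence 0%
by the formula, and it makes the evaluation range [0.02 µM, Cmax] lie
inside the curve span. AUC_effect is the trapezoidal area of that curve
over the ingredient's observed plasma concentration range; requests outside
the span raise rather than silently extrapolating. Negative rates are
retained (clipping would bias the ω ratio), with an explicit clip option.
A range-width-normalized "average" variant is provided; the two conventions
give identical weights only when all ingredients share one range width, so
drivers state which they used.

## Composition and differential proteins

Content tables (µg/ml per sample × ingredient) are normalized row-wise to
percent; the analyte universe is whatever the table quantifies. Means are
pooled across samples, ties broken lexicographically, and the major set is
the smallest ranked prefix reaching the cumulative threshold (default 95%).

Protein filtering follows the raw-threshold rule: fold change on raw group
means (≥ 1.5 up, ≤ 1/1.5 down) and a two-sample Student t-test on log2
abundances, p < 0.05, no multiplicity correction — with n = 3 per group and
a fixed fold cut this is the common TMT screening default. Welch and
Benjamini–Hochberg variants exist behind flags and are labelled as
departures from the original rule. Proteins with zero within-group variance
and equal means receive p = 1.

## Marker screening

*Favorable PK* is reconstructed as: terminal phase estimable at a dose no
higher than a reference dose (default: the medium, 2 ml/kg — one step above
the clinical-equivalent low dose). The original study states the idea
("easily detected, high exposure") without a numeric rule; the dose-threshold
reconstruction reproduces its published favorable set (all six quantified
ingredients except rutin, estimable only at 4 ml/kg). When derived from
simulated cohorts, a dose cell counts as estimable with ≥ 2 estimable
animals (the minimum for a mean ± SD cell).

*Representativeness* runs, per NCA parameter and dose group, an unpaired
two-sample t-test of the candidate's per-subject values against the
integrated profile's. The original analysis used a single-tailed test; this
is implemented as directing the tail by the observed mean difference
(p = p_two/2), with a two-tailed option and the explicit caution that a
data-directed single tail doubles the effective type-I rate. The analyte is
representative when no evaluable cell is significant at α = 0.05;
inestimable cells are excluded from the conjunction rather than treated as
evidence either way.

*Disease relevance* is an external annotation (the study derived it from
target-fishing and disease-ontology services, out of scope here); the
published annotation ships with the package. *Effect validation* is derived
from OD plates when available (any tested concentration protecting
significantly at one-sided α = 0.05 vs the model group), else annotated.

The marker set is the intersection of the four criterion sets; an empty set
is a valid outcome, and the report exposes every exact criterion-combination
region for Venn-style presentation.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed). The default cohort
mirrors the study design: 6 analytes, IV bolus at 1/2/4 ml/kg with
n = 4/3/3, 15 samples from 0.04 to 12 h. Disposition is one-compartment by
default (a two-compartment option exists for the slow, biphasic-looking
ingredient), with per-analyte CL and Vz set to the published high-dose means
and preparation contents back-solved from Dose = CL·AUC₀₋∞ at 4 ml/kg, so
simulated exposures land on the published magnitudes. Residual error is
proportional log-normal, mean 1, CV 0.15 (plasma bioanalysis errors scale
with concentration); LOD censoring at 0.5 ng/ml is applied after noise.
Between-animal variability is log-normal with 30% CV on CL and V — the true
covariance structure is unreported, so this is a modelling choice; each
analyte's deviations are drawn independently.

The generators do **not** emulate: per-analyte assay sensitivities (a single
global LOD cannot reproduce the published low/medium-dose inestimable
pattern, which is therefore an annotated input to the favorable-PK rule,
not a simulation output), inter-occasion variability, absorption phases
(the preparation is IV-only), correlated multi-analyte residuals, or the
matrix effects of real plasma. Passing tests therefore demonstrate the
correctness and statistical behaviour of the *computations* under the
stated error model, not bioanalytical validity on real plasma data.

## Numerical choices and problem sizes

Adjusted-R² ties in λz selection break at 10⁻⁴ toward the larger window.
Weight normalization is checked to 10⁻¹²; trapezoid linearity identities
hold to ≤ 10⁻⁹ in tests. Degenerate inputs fail loudly: zero-total
composition samples, od_normal = od_model plates, all-BLQ profiles,
non-positive doses and molecular weights all raise typed errors. The
simulation studies in the test suite and acceptance script use 200 profiles
for the λz window-selection cross-check, a ~100-animal cohort for
parameter-recovery summaries, and 1000-protein matrices for the null
false-positive rate — sizes at which the checked medians and rates are
stable across seeds.

## Known limitations

The published summary table is an *input* (the raw animal data are not
deposited), so per-animal reproduction of the original table is impossible;
agreement is instead checked through internal-consistency identities
(Vz = CL·t½/ln2), exposure ratios, and plant-and-recover simulations. The
exact point set behind the published effect AUCs (473.19 and 12.18 %·µM) is
not printed; those values enter the weighting step as measured inputs. The
single-tailed representativeness convention inherits the original study's
anti-conservatism; use the two-tailed flag for confirmatory work.
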