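# Methods

## The model

`altiop` analyses how intraocular pressure (IOP) in gas-tamponade eyes
responds to altitude during ground travel, and translates excursions
measured in one species (rabbit) into estimates for another (human) via
Friedenwald's scleral-rigidity model.

Friedenwald's relation states that, above roughly 5 mmHg, the ocular wall
responds to a change in intraocular volume with a proportional change in
the *logarithm* of pressure:

    E = (log10 P2 − log10 P1) / (V2 − V1)

where E, the ocular (scleral) rigidity, is a per-eye constant in
log10(mmHg) per mm³. Base-10 logarithms are used throughout: the chain's
final step exponentiates with 10^Δ, which forces the base. The volume unit
is fixed as mm³; only the product E·ΔV is observable, so any consistent
unit choice gives identical pressures.

The cross-species chain rests on one physical assumption: the volume
displaced by an expanding gas bubble is a property of the bubble, not of
the globe around it. A measured excursion P1→P2 in a source eye of
rigidity E_s therefore maps to a target eye of rigidity E_t and baseline
p1 as

    P_target = p1 · 10^( E_t · (log10(P2/P1) / E_s) )
             = p1 · (P2/P1)^(E_t/E_s).

With E_s = E_t and p1 = P1 this is the identity, which the tests enforce
to machine precision; the mapped pressure is strictly increasing in E_t
for rising excursions and strictly decreasing for falling ones.

## Rigidity coefficients

The packaged configuration (`altiop/data/rigidity_coefficients.json`)
carries:

| name             | E (log10 mmHg / mm³) | role                              |
|------------------|----------------------|-----------------------------------|
| rabbit_mean      | 0.01811667           | source-species mean (range 0.0179–0.0182) |
| friedenwald      | 0.0215               | human average                     |
| pallikaris       | 0.0126               | low human rigidity (live eyes)    |
| dastiridou_mean  | 0.0224               | mean from live human eyes         |
| dastiridou_max   | 0.0343               | stiff human globe                 |

The rabbit mean is a shipped constant rather than a recomputed quantity:
the per-eye paired Schiötz readings that produced it are not available, so
the two-weight estimator is validated on synthetic calibration data
instead. One published variant of the rabbit mean (0.1811667) is an
order-of-magnitude typo inconsistent with its own stated range and is not
used.

## Schiötz two-weight rigidity estimation

A Schiötz tonometer's scale reading maps, via a calibration table specific
to the plunger weight, to an intraocular pressure and an indentation
volume. Reading one eye with two weights (5.5 g and 10 g in the study
design) gives two points on that eye's pressure–volume curve, and E follows
directly from the defining relation.

Because the historical calibration tables are data, not algorithm, the
module accepts any table as CSV (`weight_g, scale_reading, pressure_mmhg,
volume_mm3`), validating that pressure strictly falls and volume strictly
rises with the scale reading within each weight. Between grid points,
pressure is interpolated linearly in log10 P — the rigidity framework is
linear in log pressure, so this is the natural interpolant — and volume
linearly. Replicate readings at a station are averaged on the scale-reading
axis *before* the nonlinear lookup (`average_replicates`); averaging after
lookup would bias the pressure through the curvature of the table.

Degenerate inputs: readings at the same plunger weight, or readings whose
looked-up volumes coincide, raise domain errors rather than returning an
unusable quotient. A reading pair implying E ≤ 0 (pressure falling with
added weight) is rejected as physically inconsistent.

## Altitude regression

Each eye's IOP series is fit by ordinary least squares of IOP (mmHg) on
altitude expressed in hundreds of metres, so the slope reads directly as
mmHg per 100 m of altitude rise and the intercept is the line's value at
altitude 0 in those units. All nine stations — five ascent, four descent —
enter the fit by default; this choice reproduces the published slopes and
intercepts from the raw station table. An `ascent_only` policy (stations up
to the trip's highest point) is provided as a sensitivity analysis; for the
benchmark eye it raises the human-equivalent slope from ≈1.96 to ≈2.21
mmHg/100 m, bracketing the published 2.1.

Slope uncertainty uses the t-interval slope ± t(1−α/2, n−2)·SE at 95% by
default. Eyes are compared against the benchmark (the 100% SF₆ eye, which
shows the largest response) by CI overlap: disjoint intervals are "Sig",
overlapping "NS". This is deliberately the simple published procedure, not
a formal two-sample test; it is conservative relative to a t-test on the
slope difference.

The repeated-measures structure (nine stations on one eye) is *not*
modelled — no autocorrelation correction, no mixed effects — matching the
plain-OLS design this package reproduces. The CIs are exact only under
independent homoscedastic Gaussian errors.

Method agreement between the applanation (Tono-pen) and indentation
(Schiötz) channels is summarised by a paired two-sided Wilcoxon signed-rank
test with zero differences dropped and mid-rank ties (the underlying scipy
implementation uses the exact null distribution where available), plus both
Pearson and Spearman correlations; r² is the squared Pearson r. The
all-zero-difference case is reported as p = 1 with an explicit flag rather
than an error. Published p-values for this test depend on an unstated
zero/tie policy and are not reproduced exactly; the correlations are.

## Extrapolation report and travel advisory

`extrapolation_table` transforms every eye under every configured human
coefficient, refits, and classifies significance against the benchmark
eye *under the same coefficient*. Each eye's own first-station pressure is
the default baseline anchor (an explicit baseline in mmHg may be supplied,
e.g. to anchor a human estimate at a clinical pre-travel IOP). Because the
first station anchors the transform, the extrapolated series — unlike the
OLS fit itself — is not invariant to reordering the stations; pipeline
order-invariance holds for any permutation that keeps the baseline row
first.

Under every human coefficient the recomputed ranking is: 100% SF₆ highest,
50% SF₆ second, then the 100%-air and 25%-SF₆ eyes statistically tied
(their slopes differ by ≲0.02 mmHg/100 m under the Friedenwald coefficient,
far inside either CI), then the non-vitrectomized bubble eye, then the
saline control with a slope indistinguishable from zero. The published
report lists air above 25% SF₆; direct recomputation gives the opposite
sign on that gap, which is why the package's ordering check treats the pair
as a tie rather than asserting either direction.

`predict_travel_iop` is deliberately linear: ΔIOP = slope × Δaltitude/100
added to the baseline, with the slope CI's endpoints propagated the same
way. It answers "what does the fitted line predict for this ascent", with
no claim of clinical validity; descents are out of scope (the fitted lines
describe rises, and gas resorption over time is not modelled).

## Synthetic data generator

`simulate` emulates the study's measurement design, and its defaults are
the study conditions:

- nine stations, 2260→3198 m and back (`STUDY_STATIONS`);
- linear mean response: baseline + slope × (altitude − first)/100, with
  baseline 16 mmHg (the benchmark eye's start-of-trip pressure) and slope
  1.5 mmHg/100 m (the scale of the measured responses, and the
  recovery-benchmark truth);
- Gaussian homoscedastic noise, sd 1.5 mmHg per replicate reading — the
  minimal error model consistent with OLS, chosen because the study states
  none;
- triplicate readings per station, averaged (the study measured in
  triplicate);
- integer-mmHg rounding of the averaged reading (every recorded pressure
  in the study table is an integer);
- two channels (applanation/indentation) with independent noise and an
  optional additive method offset.

Everything is deterministic given the seed (`numpy.random.default_rng`);
generated CSV fixtures are byte-reproducible.

What the generator does **not** emulate: gas-volume dynamics over days
(expansile-phase behaviour), autocorrelated measurement error along the
trip, operator drift between tonometers, or any nonlinearity in the
pressure–altitude response. Passing recovery tests therefore demonstrate
that the regression stage is unbiased and correctly calibrated *under the
stated linear-Gaussian design*, not that real trips satisfy that design.

`recovery_experiment` (500 replications in the shipped check) confirms the
slope estimator is unbiased within 0.1 mmHg/100 m and that the 95%
t-interval attains nominal coverage (0.92–0.98 observed band) under the
default conditions, integer rounding included. Rounding adds a
near-symmetric perturbation bounded, for any single fit, by half a step
over the smallest altitude gap in 100 m units. CI membership in the
coverage count uses a 1e-9 relative tolerance so that the noiseless
degenerate case (zero-width intervals) counts as covered.

## Numerical and design choices

- The ambiguous typography of the published human-step relation is read as
  *multiplication* by the human rigidity (ΔlogP_h = ΔV × E_h), the only
  reading consistent with the defining relation; it reproduces the
  published report's ordering and magnitudes.
- Regression requires ≥ 3 stations (the CI needs n−2 ≥ 1 degrees of
  freedom); two-point inputs are rejected rather than fit without
  uncertainty.
- Perfectly collinear stations yield a zero-width CI, not an error.
- The saline-control slope is kept signed internally (it is negative on
  the packaged data); comparisons against the published magnitude take the
  absolute value.
- Station altitudes in the packaged fixture are the raw table's values;
  the trip's peak altitude is quoted inconsistently across the source
  material (3198/3209/3228 m) and the per-station table wins.
- CSV parse errors name the offending line; empty input is a warning plus
  an empty result, not a crash.

## Problem sizes

The packaged dataset is 6 eyes × 9 stations; every deterministic check
runs in well under a second. The recovery experiment uses 500 replications
of the 9-station design (standard error on the coverage estimate ≈ 0.01,
comfortably resolving the 0.92–0.98 band) and completes in a few seconds.

## Known limitations

- Human estimates inherit every caveat of the source model: one eye per
  tamponade condition, 24 h post-surgery (the undiluted bubble may still
  have been expanding), and a rigidity transform that ignores age, axial
  length and vascular covariates.
- No barometric/gas-law model: the package describes the pressure–volume–
  rigidity relation, not why the bubble expands.
- The CI-overlap significance rule is conservative; non-overlap at 95% is
  stricter than p < 0.05 on the slope difference.
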