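# Methods

This note documents the models and numerical choices behind `vo2verify`:
what each stage computes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Peak values

For V̇O₂, V̇CO₂-derived RER, VE and f_R, the reported peak is the maximum
over all contiguous 60-s windows of the window mean of the 10-, 15- or 30-s
sampling averages, restricted to the incremental phase. Two open choices
were resolved as follows:

- **Window alignment.** Whether the 60-s windows roll one sample at a time
  or anchor to whole minutes is not fixed by the definition; rolling is the
  default because the maximum of a rising trace occurs at the end either
  way, and minute anchoring is available via `alignment="minute"` (CLI
  `--window-alignment`) as a sensitivity knob. "The last part of the test"
  is implemented as searching all incremental windows rather than a fixed
  tail, avoiding an arbitrary tail length.
- **RER convention.** The RER peak is the highest 60-s mean of the
  per-sample V̇CO₂/V̇O₂ ratio (mean of ratios), treating RER as a channel
  like the others, not the ratio of the windowed channel means. The helper
  `peaks.rer_peak_convention_gap` quantifies the difference; on realistic
  traces it is below 0.02 (typically ≪ 0.5 %).

Windows never straddle the warm-up boundary. A window containing a flagged
missing sample is skipped with a warning, never interpolated; HRpeak is the
maximum per-interval average, and an absent HR channel yields NaN, never 0.
Predicted HRmax uses the unrounded Tanaka value 208 − 0.7·age.

## Plateau detection

The highest 60-s V̇O₂ window is compared with the adjacent,
*non-overlapping* 60-s windows immediately before and after it (overlapping
neighbours would drive the difference to zero trivially). Either side
suffices: Δ = min over the available sides, and threshold T is fulfilled
iff Δ ≤ T, inclusively, for T = 150, 80, 50 mL/min. When the peak window is
the final window — the common case on a ramp to exhaustion — only the
preceding minute exists. Deltas are non-negative by construction because
the reference window is the maximum, so the thresholds nest
(50 ⇒ 80 ⇒ 150). A series whose incremental phase spans fewer than two
full minutes (or where no adjacent full minute exists beside the peak)
raises an undefined-plateau error, which is distinct from "not fulfilled";
cohort assembly records such tests as missing. Only the 150 mL/min
definition enters the exhaustion models, matching a protocol with small
per-stage V̇O₂ increments. Body-mass-relative plateau definitions are
deliberately out of scope.

## Criteria scoring and stratified comparisons

All cut-point comparisons are inclusive (≥ for peaks, ≤ for the plateau
delta). The default grid covers RER ≥ {1.00, 1.05, 1.10, 1.15},
RPE ≥ {17, 18, 19}, %predicted HRmax ≥ {85, 90, 95}, f_R ≥ 40 and plateau
Δ ≤ {150, 80, 50}; it is configurable because published figures rarely
print their full grids as text. Missing inputs yield missing cells excluded
from margins. Stratified V̇O₂peak comparisons use Welch's unequal-variance
t-test: fulfilment splits are often extremely unbalanced (e.g. 514 vs 21),
where pooled-variance assumptions are unsafe. An empty stratum is reported
as not computable, never as p = 1.

## Exhaustion models

The outcome is the test leader's binary "to exhaustion" evaluation. Each
key variable (plateau at 150 mL/min, HRpeak, RERpeak, RPEpeak, f_Rpeak) is
screened in its own logistic model adjusted for age, diagnosis (indicator
contrasts, breast as the reference — the largest group), V̇O₂peak and test
duration. Variables with screen Wald p < 0.25 enter a single multivariate
model with the adjusters; there is no further elimination inside the final
model (the step-down is one inclusion step). Inference is Wald throughout —
the era-typical default of the major commercial packages — with listwise
deletion and the used n recorded. Odds ratios are scaled per 0.10 RER and
per one unit otherwise; per-breath scaling for f_R follows how such tables
print the estimate (an OR of ~1.06 per breath/min compounds to ~1.8 per 10
breaths). Pairwise Pearson correlations (point-biserial for the binary
plateau) document the collinearity among the key variables, V̇O₂peak and
test time; the correlation type is an open choice and Pearson was selected.

Separation handling: a non-existent MLE is flagged (`converged=False`) with
the fit reported as non-converged rather than raised mid-pipeline.

## ROC cut-points and the combined classifier

Candidate thresholds are the observed unique score values with ≥
orientation, so every reported operating point is achievable exactly. AUC
uses the trapezoid rule, which equals the tie-corrected concordance
(Mann–Whitney) statistic — asserted against a pair-counting oracle in the
tests. "Sensitivity and specificity highest" is operationalised as maximum
Youden J = sens + spec − 1 (ties broken toward higher sensitivity, then the
lower threshold); the closest-to-(0,1)-corner alternative is available via
`rule="closest01"` and coincides with Youden on the recovery simulations at
the stated noise. The TPR interval is a Wilson score interval, chosen over
Wald for small-sample behaviour (its exact coverage at n = 80 and n = 465
stays above 94 % across the relevant rates).

The combined classifier is a logistic model on the three criterion booleans
with a 0.5 predicted-probability rule — "combined predicted probability" is
an interpretation, recorded as such. Under separation the MLE does not
exist; a lightly ridge-penalized fit (elastic net with L1 weight 0,
α = 1e−4) then supplies the coefficients so that, e.g., labels identical to
one member criterion are still classified perfectly; only if that also
fails does the deterministic "≥ 2 of 3 criteria" rule apply. Both downgrades
are recorded on the result object.

## Cross-validation

The derivation-fitted classifier is applied unchanged to the hold-out
cohort; any subject-id overlap raises a leakage error. The cross-table
reports the four counts, overall accuracy and the two class accuracies
(overall accuracy is exactly their prevalence-weighted mixture). Reported
percentages round half-up to integers; machine outputs keep full precision.
Severe hold-out class imbalance (fewer than 10 in the minority class)
triggers a warning, because class-specific accuracies are then descriptive
at best.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without any
data download. Per subject:

- **Protocol.** Modified Balke: 5-min warm-up, then 1-min stages; incline
  min(2k, 12) %, speed 4 km/h until the incline cap, then +0.5 km/h per
  stage. Metabolic demand is stepwise linear in stage index,
  `demand_intercept + demand_slope·k` mL/kg/min (12.0 + 2.066·k by
  default): no published workload→V̇O₂ mapping exists for this exact
  protocol, so linearity keeps the generator analytically tractable, and
  the slope is set so the closed-form expected incremental duration
  (`expected_incremental_duration`, which integrates the stage-count
  distribution over the truncated-normal capacity draw and the premature-
  termination model) equals ~9.9 min, putting the median subject near
  stage 10.
- **Kinetics.** Latent V̇O₂ follows first-order kinetics toward
  min(demand, capacity) with τ = 30 s on a 5-s grid, bin-averaged into 10/15/
  30-s sampling averages; Gaussian measurement noise (60 mL/min per sampling
  average on V̇O₂ and V̇CO₂; 2 bpm HR; 1.5 br/min f_R) is added after
  binning. Pre-noise traces are monotone within the test by construction.
- **Responses.** HR rises linearly with relative intensity toward an
  individual HRmax drawn around Tanaka(age) + bias; RER and f_R rise as
  power functions (exponents 2.2 and 1.7) from resting values (0.80,
  14 br/min) toward individual maxima; VE is V̇O₂ times a ventilatory
  equivalent rising from 21 to 38.
- **Termination.** With probability 0.85 the test ends one hold period
  (120 s) after demand first exceeds capacity — long enough, given τ, that
  the final two minutes sit in the saturation region, which is what
  guarantees noiseless agreement between the latent plateau flag and the
  150 mL/min detector. Otherwise termination is premature, at a uniform
  0.60–0.95 fraction of the full-effort duration (floored to the sampling
  grid, minimum three minutes so the plateau comparison is defined).
- **Perception.** End RPE = round(6 + span·rel^1.5 + noise) clipped to
  [6, 20], where rel is the achieved fraction of capacity over the final
  minute. A fixed span of 14 (the full Borg range) cannot reproduce the
  reference mean of 17.9 — maximal subjects finish at rel ≈ 0.99, which
  would pin RPE at 19–20 — so the span is a calibrated parameter
  (default 12.21): even at a true maximum, reported perceived exertion in
  this population averages below the scale ceiling.
- **Evaluation.** The test leader's label is Bernoulli with logit linear in
  the *measured* peak RER (0.0728 per 0.01), end RPE (0.718 per unit) and
  measured peak f_R (0.0583 per breath/min) — observable exertion signs,
  not latent truth — so models fitted to recorded peak values are correctly
  specified and coefficient recovery has nominal coverage. The slopes
  correspond to odds ratios of ~2.07 per 0.1 RER, ~2.05 per RPE unit and
  ~1.06 per breath; the intercept (−21.07) sets the marginal "to
  exhaustion" rate at ~87 %.

**Calibration.** Defaults were fixed by iterating large-n (30 000) runs,
adjusting the capacity, RER-max, f_R-max means, the RPE span, the HRmax
bias, the demand slope (against the closed-form duration) and the
evaluation intercept until cohort means matched the reference targets
(29.8 mL/kg/min, 166 bpm, 1.16, 40 br/min, 17.9, 9.9 min, 87 %); the input
means differ from the observed output means because of kinetics lag,
window-maximum noise bias and the 15 % premature terminations. The tests
verify all targets within 3 SE at n = 2000 on fresh seeds.

**What the generator does not emulate.** Breath-by-breath noise structure
(autocorrelation, outlier breaths), inter-site device differences,
medication effects (beta-blockade), day-to-day biological variability,
diagnosis- or age-dependence of capacity, and any dependence of the test
leader on observations other than the three modelled signs. Plateau
prevalences at the stricter 80/50 mL/min cuts therefore track the
qualitative pattern (monotone decreasing, ~90 % at 150) rather than the
exact reference percentages, and passing tests demonstrate correctness of
the analysis pipeline under this stylised data model, not properties of
real cancer-patient data.

**Randomness.** One `numpy.random.Generator` is threaded explicitly through
every draw; identical configurations (including seed) reproduce cohorts
bit-for-bit. The pipeline fans one seed out to per-stage child seeds via
`SeedSequence`.

## Known limitations

- The Hosmer-style screen admits each truly inactive key variable with
  probability ≈ entry level (0.25); with several inactive candidates the
  probability that the final model contains *exactly* the active set is
  bounded by ~0.75 per inactive variable, an inherent property of
  fixed-level screening rather than an implementation artefact (the suite
  verifies the attainable facts: active variables enter essentially always,
  inactive ones at the nominal rate).
- In-sample cut-point accuracies are optimistic relative to the external
  cross-table, especially under severe hold-out imbalance.
- Proprietary metabolic-cart exports are not parsed; users convert to the
  canonical CSV first.
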