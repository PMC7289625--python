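# vo2verify

Tools for deciding whether a maximal oxygen-uptake (V̇O₂max) test was really
maximal.

Direct measurement of V̇O₂max on a graded treadmill test is the gold
standard for cardiorespiratory fitness, but its value is only trustworthy if
the subject actually reached exhaustion. In clinical populations — here,
patients newly diagnosed with breast, prostate or colorectal cancer tested
before (neo-)adjuvant treatment — both patients and test leaders may stop
short of a true maximum, so *verification criteria* are applied to each
test: a plateau in V̇O₂ despite rising workload, peak respiratory exchange
ratio (RER = V̇CO₂/V̇O₂), percent of age-predicted maximal heart rate
(Tanaka: HRmax = 208 − 0.7·age), end-of-test Borg RPE (6–20), and peak
breathing frequency (f_R). `vo2verify` implements the complete baseline
analysis around these criteria as a tested, reusable pipeline:

- **Peak extraction** — the peak value of V̇O₂, VE, f_R and RER is the
  highest 60-s mean of the 10/15/30-s sampling averages within the
  incremental phase; HRpeak is the highest single 5- or 15-s average.
- **Plateau detection** — the highest 1-min V̇O₂ mean is compared with the
  adjacent non-overlapping minutes; the criterion at threshold T is met
  when ΔV̇O₂ ≤ T for T ∈ {150, 80, 50} mL/min.
- **Criteria scoring** — per-subject fulfilment of a configurable grid of
  criterion/cut-point pairs, with prevalences and V̇O₂peak stratified by
  fulfilment (Welch two-sample comparison).
- **Exhaustion modelling** — logistic regression of the test leader's
  binary "to exhaustion" evaluation on the five key variables, each screened
  in an adjusted bivariate model (adjusters: age, diagnosis, V̇O₂peak, test
  duration); variables with screen p < 0.25 enter one multivariate model
  (Hosmer-style step-down). Odds ratios are reported per 0.10 RER and per
  unit otherwise, with 95 % Wald CIs.
- **ROC cut-points** — for the associated criteria, the operating threshold
  maximising Youden's J, with a Wilson 95 % CI on the true-positive rate and
  in-sample classification accuracy; a logistic combination of the three
  derived criterion booleans gives the combined classifier.
- **External cross-validation** — the derivation-fitted classifier applied
  unchanged to an independent hold-out cohort, summarised in a 2×2
  cross-table.
- **Synthetic cohorts** — a generator for modified-Balke treadmill tests
  (5-min warm-up; 4 km/h with incline +2 %/min to 12 %, then speed
  +0.5 km/h/min) with first-order V̇O₂ kinetics, monotone HR/RER/f_R
  responses, premature terminations, and a latent exhaustion-evaluation
  model, calibrated so default cohorts match the reference population
  (V̇O₂peak 29.8 mL/kg/min, HRpeak 166, RERpeak 1.16, f_R 40, RPE 17.9,
  ~9.9 min incremental duration, 87 % evaluated "to exhaustion").

## Worked example

```python
import numpy as np
from vo2verify import (SimulationConfig, draw_profiles, simulate_test,
                       extract_peak_values, detect_plateau)

cfg = SimulationConfig(n_subjects=1, seed=42)
rng = np.random.default_rng(cfg.seed)
profile = draw_profiles(cfg, rng)[0]
test = simulate_test(profile, None, cfg, rng)
pv = extract_peak_values(test.series, profile.body_mass, profile.age, test.end_rpe)
plat = detect_plateau(test.series)
```

This subject has a true V̇O₂max of 36.6 mL/kg/min (age 63, 82.0 kg) but the
simulated test terminated prematurely, and the criteria flag it:

```
VO2peak 31.3 mL/kg/min   HRpeak 136 bpm (83% of predicted)
RERpeak 0.97   fRpeak 34 br/min   RPE 14   duration 9.8 min
plateau min delta 165 mL/min -> fulfilled at 150: False, 80: False, 50: False
leader evaluation: False
```

The observed V̇O₂peak underestimates the true capacity by 5 mL/kg/min; no
secondary criterion is met (RER below 1.0, 83 % of predicted HRmax, RPE 14)
and the simulated test leader accordingly evaluated the test as "not to
exhaustion".

The full pipeline runs from one config:

```bash
vo2verify run --config analysis.yaml     # synthetic or file-based cohorts
vo2verify peaks --input series.csv --body-mass 70 --age 59 --rpe 18
vo2verify plateau --input series.csv --thresholds 150,80,50
vo2verify fit --cohort cohort.csv        # OR table (bivariate + multivariate)
vo2verify roc --cohort cohort.csv --variables rerpeak,rpepeak,frpeak
vo2verify crossval --derivation a.csv --holdout b.csv
```

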