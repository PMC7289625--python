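"""Synthetic incremental-treadmill CPET cohorts.

This module generates gas-exchange test data with the statistical structure
the downstream analysis assumes, so the whole pipeline is testable without
any external data.  The generative model, per subject:

* A modified Balke schedule (see :mod:`vo2verify.protocols`) drives a
  stepwise metabolic demand that is linear in stage index,
  ``demand_intercept + demand_slope * k`` mL/kg/min.
* Achieved VO2 follows first-order kinetics toward
  ``min(demand, true_vo2max) * body_mass`` with time constant
  ``vo2_kinetics_tau``; HR, RER, fR and VE rise monotonically (pre-noise)
  toward subject maxima as power functions of relative intensity
  (achieved VO2 / capacity).
* The test ends either at the effort limit -- a configurable hold time
  after demand first exceeds capacity, which is what produces a VO2
  plateau -- or prematurely, at a random fraction of that duration, with
  probability ``prob_submaximal_termination``.
* End-of-test Borg RPE is ``round(6 + 14 * rel**rpe_gamma + noise)``
  clipped to [6, 20], where ``rel`` is the achieved fraction of capacity
  over the final minute.
* The test leader's binary "to exhaustion" evaluation is Bernoulli with a
  logit linear in the *measured* peak RER (per 0.01), end RPE (per unit)
  and peak fR (per breath/min): the label depends on observable exertion
  signs, not on latent truth, so downstream models are correctly specified
  when fitted to recorded peak values.

All randomness flows through one explicitly threaded
:class:`numpy.random.Generator`; there is no global random state.

Default parameter values are calibrated so that, with the shipped
defaults, cohort means of VO2peak, HRpeak, RERpeak, fRpeak and end RPE
match the reference targets in :data:`CALIBRATION_TARGETS` and the mean
incremental test duration is ~9.9 min (median termination near stage 10).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.signal import lfilter

from .errors import ConfigurationError, UndefinedPlateauError
from .io import GasExchangeSeries
from .peaks import hr_peak, rolling_60s_peak, tanaka_predicted_hrmax
from .plateau import DEFAULT_THRESHOLDS, detect_plateau_values
from .protocols import ProtocolSchedule, build_balke_schedule

# Latent physiology is simulated on a 5-s grid (divides every supported
# acquisition interval) and bin-averaged into sampling averages.
LATENT_DT = 5.0

# Shortest incremental phase generated (stages): three full minutes, so that
# the plateau comparison always has an adjacent minute next to the peak one.
MIN_INCREMENTAL_STAGES = 3

# Resting values and response-shape exponents (dimensionless, frozen after
# calibrating cohort means against the reference targets below).
VO2_REST_REL = 5.0     # mL/kg/min
HR_REST = 70.0         # beats/min
RER_REST = 0.80
FR_REST = 14.0         # breaths/min
WARMUP_START_REL = 8.0  # mL/kg/min at the start of the warm-up ramp
HR_SHAPE = 1.0  # HR rises linearly with relative intensity
RER_SHAPE = 2.2
FR_SHAPE = 1.7
VE_EQUIV_BASE = 21.0   # VE (L/min) per L/min VO2 at rest
VE_EQUIV_RISE = 17.0   # additional ventilatory equivalent at max intensity
VE_NOISE_SD = 2.0      # L/min

#: Intended cohort means of the default configuration (the reference
#: population this generator emulates): VO2peak mL/kg/min, HRpeak bpm,
#: RERpeak, fRpeak breaths/min, end RPE, incremental duration min.
CALIBRATION_TARGETS = {
    "vo2peak_rel": 29.8,
    "hrpeak": 166.0,
    "rerpeak": 1.16,
    "frpeak": 40.0,
    "rpepeak": 17.9,
    "test_duration": 9.9,
}

DIAGNOSES = ("breast", "prostate", "colorectal")


@dataclass(frozen=True)
class SubjectProfile:
    """Latent characteristics of one simulated subject."""

    subject_id: str
    age: float                 # years, in [18, 95]
    diagnosis: str             # breast | prostate | colorectal
    body_mass: float           # kg
    true_vo2max: float         # mL/kg/min -- physiological capacity
    true_hrmax: float          # beats/min
    rer_max: float             # attainable RER at capacity
    fr_max: float              # breaths/min at capacity
    effort_propensity: float   # logit-scale willingness to reach exhaustion

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 95:
            raise ConfigurationError(f"age {self.age} outside [18, 95]")
        if not self.body_mass > 0:
            raise ConfigurationError("body_mass must be positive")
        if not self.true_vo2max > 0:
            raise ConfigurationError("true_vo2max must be positive")
        if not 0.7 < self.rer_max < 1.5:
            raise ConfigurationError(f"rer_max {self.rer_max} outside (0.7, 1.5)")
        if not 15 < self.fr_max < 80:
            raise ConfigurationError(f"fr_max {self.fr_max} outside (15, 80)")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic cohort generator.

    Defaults are calibrated so the generated cohort reproduces the
    reference peak-value means in :data:`CALIBRATION_TARGETS`; see
    ``docs/methods.md`` for the calibration procedure.
    """

    n_subjects: int = 535
    seed: int = 0
    diagnosis_probabilities: tuple[float, float, float] = (0.79, 0.17, 0.04)
    age_mean: float = 59.0
    age_sd: float = 12.0
    body_mass_mean: float = 73.0
    body_mass_sd: float = 12.0
    vo2max_mean: float = 29.676     # calibrated: observed VO2peak mean 29.8
    vo2max_sd: float = 7.4
    hrmax_noise_sd: float = 10.0    # spread of HRmax around the Tanaka prediction
    hrmax_bias: float = -1.586      # mean HRmax offset vs Tanaka (calibrated)
    rer_max_mean: float = 1.1551    # calibrated: observed RERpeak mean 1.16
    rer_max_sd: float = 0.105
    fr_max_mean: float = 40.25      # calibrated: observed fRpeak mean 40
    fr_max_sd: float = 8.0
    vo2_kinetics_tau: float = 30.0  # s, first-order VO2 response
    measurement_noise_sd_vo2: float = 60.0  # mL/min, per sampling average
    acquisition_interval: int = 15  # s, in {10, 15, 30}
    prob_submaximal_termination: float = 0.15
    # (intercept, per 0.01 RER, per RPE unit, per breath/min fR) on the
    # logit scale of the test leader's "to exhaustion" evaluation.
    exhaustion_logit_coefficients: tuple[float, float, float, float] = (
        -21.07, 0.0728, 0.718, 0.0583)
    # protocol / termination model
    warmup_duration: float = 300.0
    stage_duration: float = 60.0
    max_stages: int = 30
    demand_intercept: float = 12.0  # mL/kg/min at a hypothetical stage 0
    demand_slope: float = 2.066     # mL/kg/min per stage; calibrated for ~9.9 min
    exhaustion_hold: float = 120.0  # s sustained after demand exceeds capacity
    submax_fraction_min: float = 0.60
    submax_fraction_max: float = 0.95
    # perception & secondary measurement noise
    rpe_gamma: float = 1.5
    rpe_span: float = 12.21         # RPE units above 6 at full capacity (calibrated)
    rpe_noise_sd: float = 1.2
    hr_noise_sd: float = 2.0
    fr_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        p = np.asarray(self.diagnosis_probabilities, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "diagnosis_probabilities must be 3 non-negative values summing to 1")
        if self.acquisition_interval not in (10, 15, 30):
            raise ConfigurationError("acquisition_interval must be 10, 15 or 30 s")
        for name in ("age_sd", "body_mass_sd", "vo2max_sd", "hrmax_noise_sd",
                     "rer_max_sd", "fr_max_sd", "measurement_noise_sd_vo2",
                     "rpe_noise_sd", "hr_noise_sd", "fr_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.prob_submaximal_termination <= 1:
            raise ConfigurationError("prob_submaximal_termination must be in [0, 1]")
        if len(self.exhaustion_logit_coefficients) != 4:
            raise ConfigurationError("exhaustion_logit_coefficients needs 4 values")

    # -- serialisation (flat key-value YAML) --------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["diagnosis_probabilities"] = list(self.diagnosis_probabilities)
        payload["exhaustion_logit_coefficients"] = list(
            self.exhaustion_logit_coefficients)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        payload["diagnosis_probabilities"] = tuple(payload["diagnosis_probabilities"])
        payload["exhaustion_logit_coefficients"] = tuple(
            payload["exhaustion_logit_coefficients"])
        return cls(**payload)


@dataclass(frozen=True)
class SimulatedTest:
    """One simulated test: profile, measured series, outcomes, latent truth.

    ``truth`` records the latent quantities the measured data were generated
    from: achieved fraction of capacity over the final minute, whether a
    plateau is present by construction (demand exceeded capacity and was
    sustained for the full hold), the time capacity was first exceeded, and
    whether termination was premature.
    """

    profile: SubjectProfile
    series: GasExchangeSeries
    end_rpe: int
    leader_evaluation: bool
    truth: dict


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated-normal draws by resampling (vectorised, exact)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _demand_rel(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Metabolic demand (mL/kg/min) at latent times ``t`` (s from test start)."""
    stage1 = config.demand_intercept + config.demand_slope
    warm = WARMUP_START_REL + (stage1 - WARMUP_START_REL) * np.minimum(
        t / config.warmup_duration, 1.0)
    k = np.floor((t - config.warmup_duration) / config.stage_duration) + 1
    k = np.clip(k, 1, config.max_stages)
    inc = config.demand_intercept + config.demand_slope * k
    return np.where(t < config.warmup_duration, warm, inc)


def _terminal_stage(cap_rel: float, config: SimulationConfig) -> int | None:
    """First 1-based stage whose demand exceeds capacity, or None within schedule."""
    k = int(np.floor((cap_rel - config.demand_intercept) / config.demand_slope)) + 1
    k = max(k, 1)
    return k if k <= config.max_stages else None


def _full_effort_duration(cap_rel: float, config: SimulationConfig) -> tuple[float, float | None]:
    """(incremental duration in s at full effort, time capacity exceeded or None)."""
    k = _terminal_stage(cap_rel, config)
    if k is None:
        return config.max_stages * config.stage_duration, None
    t_cap_incr = (k - 1) * config.stage_duration
    dur = min(t_cap_incr + config.exhaustion_hold,
              config.max_stages * config.stage_duration)
    dur = max(dur, MIN_INCREMENTAL_STAGES * config.stage_duration)
    return dur, t_cap_incr


def expected_incremental_duration(config: SimulationConfig,
                                  n_grid: int = 4001) -> float:
    """Closed-form expected incremental duration (minutes) under ``config``.

    Integrates the stage-count distribution implied by the truncated-normal
    capacity draw and the premature-termination model on a quantile grid;
    used as the calibration oracle for the demand-slope default.
    """
    a, b = (15.0 - config.vo2max_mean) / config.vo2max_sd, \
           (60.0 - config.vo2max_mean) / config.vo2max_sd
    q = (np.arange(n_grid) + 0.5) / n_grid
    caps = stats.truncnorm.ppf(q, a, b, loc=config.vo2max_mean,
                               scale=config.vo2max_sd)
    d_full = np.array([_full_effort_duration(c, config)[0] for c in caps])
    u = np.linspace(config.submax_fraction_min, config.submax_fraction_max, 201)
    dt = float(config.acquisition_interval)
    d_sub = np.maximum(np.floor(np.outer(d_full, u) / dt) * dt,
                       MIN_INCREMENTAL_STAGES * config.stage_duration)
    p = config.prob_submaximal_termination
    per_cap = (1 - p) * d_full + p * d_sub.mean(axis=1)
    return float(per_cap.mean() / 60.0)


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _simulate_arrays(profile: SubjectProfile, config: SimulationConfig,
                     rng: np.random.Generator) -> dict:
    """Simulate one test; returns latent and measured arrays plus outcomes."""
    dt = float(config.acquisition_interval)
    cap_abs = profile.true_vo2max * profile.body_mass  # mL/min

    d_full, t_cap_incr = _full_effort_duration(profile.true_vo2max, config)
    submax = bool(rng.uniform() < config.prob_submaximal_termination)
    if submax:
        u = rng.uniform(config.submax_fraction_min, config.submax_fraction_max)
        d_incr = max(np.floor(u * d_full / dt) * dt,
                     MIN_INCREMENTAL_STAGES * config.stage_duration)
    else:
        u = 1.0
        d_incr = d_full
    total = config.warmup_duration + d_incr

    # latent grid: bin starts 0, 5, ..., total-5
    t5 = np.arange(0.0, total, LATENT_DT)
    demand = _demand_rel(t5, config)
    target = np.minimum(demand, profile.true_vo2max) * profile.body_mass
    decay = np.exp(-LATENT_DT / config.vo2_kinetics_tau)
    v0 = VO2_REST_REL * profile.body_mass
    # v[i] = target[i] + (v[i-1] - target[i]) * decay  (linear recurrence)
    vo2_lat, _ = lfilter([1 - decay], [1, -decay], target, zi=[decay * v0])

    rel = np.clip(vo2_lat / cap_abs, 0.0, 1.0)
    hr_lat = HR_REST + (profile.true_hrmax - HR_REST) * rel ** HR_SHAPE
    rer_lat = RER_REST + (profile.rer_max - RER_REST) * rel ** RER_SHAPE
    fr_lat = FR_REST + (profile.fr_max - FR_REST) * rel ** FR_SHAPE
    ve_lat = (vo2_lat / 1000.0) * (VE_EQUIV_BASE + VE_EQUIV_RISE * rel ** 3)
    vco2_lat = vo2_lat * rer_lat

    # bin-average the latent grid into sampling averages at the acquisition dt
    per_bin = int(round(dt / LATENT_DT))
    n_bins = len(t5) // per_bin

    def bin_mean(x: np.ndarray) -> np.ndarray:
        return x[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)

    time = np.arange(n_bins) * dt
    vo2 = bin_mean(vo2_lat)
    vco2 = bin_mean(vco2_lat)
    hr = bin_mean(hr_lat)
    fr = bin_mean(fr_lat)
    ve = bin_mean(ve_lat)

    sv = config.measurement_noise_sd_vo2
    vo2_m = np.clip(vo2 + rng.normal(0, sv, n_bins) if sv else vo2, 0.0, None)
    vco2_m = np.clip(vco2 + rng.normal(0, sv, n_bins) if sv else vco2, 0.0, None)
    hr_m = np.clip(hr + rng.normal(0, config.hr_noise_sd, n_bins)
                   if config.hr_noise_sd else hr, 1.0, None)
    fr_m = np.clip(fr + rng.normal(0, config.fr_noise_sd, n_bins)
                   if config.fr_noise_sd else fr, 1.0, None)
    ve_m = np.clip(ve + rng.normal(0, VE_NOISE_SD, n_bins), 0.0, None)

    warm = time < config.warmup_duration
    inc = ~warm

    # perception: achieved fraction of capacity over the final minute (latent)
    w60 = int(round(60.0 / LATENT_DT))
    rel_term = float(vo2_lat[-w60:].mean() / cap_abs)
    rpe_raw = 6.0 + config.rpe_span * rel_term ** config.rpe_gamma
    if config.rpe_noise_sd:
        rpe_raw += rng.normal(0, config.rpe_noise_sd)
    end_rpe = int(np.clip(np.round(rpe_raw), 6, 20))

    # measured peaks (identical computation to peaks.extract_peak_values)
    with np.errstate(divide="ignore", invalid="ignore"):
        rer_m = np.where(vo2_m[inc] > 0, vco2_m[inc] / vo2_m[inc], np.nan)
    vo2peak_abs = rolling_60s_peak(vo2_m[inc], config.acquisition_interval)
    rerpeak = rolling_60s_peak(rer_m, config.acquisition_interval)
    frpeak = rolling_60s_peak(fr_m[inc], config.acquisition_interval)
    vepeak = rolling_60s_peak(ve_m[inc], config.acquisition_interval)
    hrpeak = hr_peak(hr_m[inc])

    b0, b_rer, b_rpe, b_fr = config.exhaustion_logit_coefficients
    logit = b0 + b_rer * (rerpeak * 100.0) + b_rpe * end_rpe + b_fr * frpeak
    p_exh = 1.0 / (1.0 + np.exp(-logit))
    leader = bool(rng.uniform() < p_exh)

    plateau_present = bool((not submax) and t_cap_incr is not None
                           and d_incr >= t_cap_incr + config.exhaustion_hold)
    truth = {
        "achieved_fraction": rel_term,
        "plateau_present": plateau_present,
        "capacity_abs": cap_abs,
        "t_capacity_incremental_s": t_cap_incr,
        "submaximal": submax,
        "effort_fraction": float(u),
        "p_exhaustion": float(p_exh),
    }
    return {
        "time": time, "warm": warm,
        "vo2": vo2_m, "vco2": vco2_m, "ve": ve_m, "fr": fr_m, "hr": hr_m,
        "vo2_latent": vo2, "end_rpe": end_rpe, "leader": leader, "truth": truth,
        "peaks": {"vo2peak_abs": vo2peak_abs, "rerpeak": rerpeak,
                  "frpeak": frpeak, "vepeak": vepeak, "hrpeak": hrpeak},
    }


def _to_series(subject_id: str, sim: dict, config: SimulationConfig) -> GasExchangeSeries:
    data = pd.DataFrame({
        "time": sim["time"],
        "vo2": sim["vo2"],
        "vco2": sim["vco2"],
        "ve": sim["ve"],
        "fr": sim["fr"],
        "hr": sim["hr"],
        "phase": np.where(sim["warm"], "warmup", "incremental"),
    })
    return GasExchangeSeries(subject_id=subject_id,
                             acquisition_interval=config.acquisition_interval,
                             data=data)


def simulate_test(profile: SubjectProfile,
                  schedule: ProtocolSchedule | None,
                  config: SimulationConfig,
                  rng: np.random.Generator) -> SimulatedTest:
    """Simulate one incremental test for ``profile``.

    ``schedule`` is accepted for interface symmetry; when given, its warm-up
    and stage durations must agree with the config (the demand model is the
    config's linear-in-stage rule).  All randomness comes from ``rng``.
    """
    if schedule is not None:
        if (abs(schedule.warmup_duration - config.warmup_duration) > 1e-9
                or abs(schedule.stage_duration - config.stage_duration) > 1e-9):
            raise ConfigurationError(
                "schedule warm-up/stage durations disagree with the config")
    sim = _simulate_arrays(profile, config, rng)
    return SimulatedTest(profile=profile,
                         series=_to_series(profile.subject_id, sim, config),
                         end_rpe=sim["end_rpe"],
                         leader_evaluation=sim["leader"],
                         truth=sim["truth"])


def draw_profiles(config: SimulationConfig,
                  rng: np.random.Generator,
                  id_prefix: str = "S") -> list[SubjectProfile]:
    """Draw ``n_subjects`` profiles from the configured population."""
    n = config.n_subjects
    age = _truncated_normal(rng, config.age_mean, config.age_sd, 18, 95, n)
    diag_idx = rng.choice(3, size=n, p=np.asarray(config.diagnosis_probabilities))
    bm = _truncated_normal(rng, config.body_mass_mean, config.body_mass_sd,
                           40, 130, n)
    cap = _truncated_normal(rng, config.vo2max_mean, config.vo2max_sd, 15, 60, n)
    hrmax = np.clip(208.0 - 0.7 * age + config.hrmax_bias
                    + rng.normal(0, config.hrmax_noise_sd, n), 120, 220)
    rermax = _truncated_normal(rng, config.rer_max_mean, config.rer_max_sd,
                               0.9, 1.49, n)
    frmax = _truncated_normal(rng, config.fr_max_mean, config.fr_max_sd, 20, 79, n)
    effort = rng.normal(0, 1, n)
    return [
        SubjectProfile(subject_id=f"{id_prefix}{i:05d}", age=float(age[i]),
                       diagnosis=DIAGNOSES[int(diag_idx[i])],
                       body_mass=float(bm[i]), true_vo2max=float(cap[i]),
                       true_hrmax=float(hrmax[i]), rer_max=float(rermax[i]),
                       fr_max=float(frmax[i]), effort_propensity=float(effort[i]))
        for i in range(n)
    ]


def generate_cohort(config: SimulationConfig,
                    study_arm: str = "intervention",
                    keep_series: bool = True,
                    plateau_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                    id_prefix: str | None = None,
                    ) -> tuple[list[SimulatedTest], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns the per-test :class:`SimulatedTest` objects (empty list when
    ``keep_series=False``, which skips building per-test DataFrames for
    large simulation studies) and a one-row-per-subject cohort table with
    demographics, peak values, plateau results, the leader evaluation and
    the latent truth columns (prefixed ``truth_``).
    """
    if config.n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if id_prefix is None:
        id_prefix = study_arm[:1].upper() or "S"
    rng = np.random.default_rng(config.seed)
    profiles = draw_profiles(config, rng, id_prefix=id_prefix)
    tests: list[SimulatedTest] = []
    rows: list[dict] = []
    for prof in profiles:
        sim = _simulate_arrays(prof, config, rng)
        inc = ~sim["warm"]
        pk = sim["peaks"]
        try:
            plat = detect_plateau_values(sim["vo2"][inc],
                                         config.acquisition_interval,
                                         thresholds=plateau_thresholds)
            min_delta = plat.min_delta
            fulfilled = {t: plat.fulfilled[float(t)] for t in plateau_thresholds}
        except UndefinedPlateauError:
            min_delta = np.nan
            fulfilled = {t: pd.NA for t in plateau_thresholds}
        predicted = tanaka_predicted_hrmax(prof.age)
        duration = inc.sum() * config.acquisition_interval / 60.0
        row = {
            "subject_id": prof.subject_id,
            "study_arm": study_arm,
            "age": prof.age,
            "diagnosis": prof.diagnosis,
            "body_mass": prof.body_mass,
            "vo2peak_abs": pk["vo2peak_abs"],
            "vo2peak_rel": pk["vo2peak_abs"] / prof.body_mass,
            "hrpeak": pk["hrpeak"],
            "rerpeak": pk["rerpeak"],
            "vepeak": pk["vepeak"],
            "frpeak": pk["frpeak"],
            "rpepeak": sim["end_rpe"],
            "predicted_hrmax": predicted,
            "pct_predicted_hr": 100.0 * pk["hrpeak"] / predicted,
            "test_duration": duration,
            "plateau_min_delta": min_delta,
            "leader_evaluation": sim["leader"],
            "truth_vo2max": prof.true_vo2max,
            "truth_plateau_present": sim["truth"]["plateau_present"],
            "truth_submaximal": sim["truth"]["submaximal"],
            "truth_achieved_fraction": sim["truth"]["achieved_fraction"],
        }
        for t in plateau_thresholds:
            row[f"plateau_{int(t)}"] = fulfilled[t]
        rows.append(row)
        if keep_series:
            tests.append(SimulatedTest(
                profile=prof, series=_to_series(prof.subject_id, sim, config),
                end_rpe=sim["end_rpe"], leader_evaluation=sim["leader"],
                truth=sim["truth"]))
    return tests, pd.DataFrame(rows)


def default_schedule(config: SimulationConfig) -> ProtocolSchedule:
    """Balke schedule matching the config's protocol parameters."""
    return build_balke_schedule(config.max_stages,
                                warmup_duration=config.warmup_duration,
                                stage_duration=config.stage_duration)
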