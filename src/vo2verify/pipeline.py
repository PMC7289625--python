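"""End-to-end analysis pipeline.

Orchestrates: input (synthetic generation or cohort files) -> criteria
scoring -> stratified VO2peak comparison -> adjusted bivariate screen ->
step-down multivariate logistic model -> ROC cut-point derivation ->
combined classifier -> external cross-validation on the hold-out cohort.

Every artifact is a CSV (plus one plain-text report) stamped with the
configuration hash and seed; the log records the row count at each stage so
that rows in = rows out + rows excluded reconciles end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import criteria as criteria_mod
from .criteria import CriterionDefinition, evaluate_criteria, stratified_vo2_comparison
from .crossval import CrossTable, cross_validate, round_half_up
from .errors import ConfigurationError, LeakageError
from .exhaustion import KEY_VARIABLES, adjusted_bivariate_screen, hosmer_stepdown
from .io import read_cohort, write_cohort
from .roc import CombinationResult, CutpointResult, combine_criteria, derive_cutpoint, roc_curve
from .synthetic import SimulationConfig, generate_cohort

logger = logging.getLogger("vo2verify")

#: variables eligible for ROC cut-point derivation (continuous peaks; the
#: binary plateau indicator has no threshold to derive)
ROC_ELIGIBLE = ("hrpeak", "rerpeak", "rpepeak", "frpeak")


@dataclass
class AnalysisConfig:
    """Full pipeline parameterisation.

    Exactly one input mode is active: ``synthetic`` (cohorts are generated
    from ``simulation`` with child seeds derived from ``seed``) or ``files``
    (derivation/hold-out cohort tables are read from disk).
    """

    mode: str = "synthetic"
    seed: int = 0
    output_dir: str | Path = "vo2verify_output"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_holdout: int = 80
    derivation_path: str | None = None
    holdout_path: str | None = None
    grid: list[CriterionDefinition] | None = None
    entry_p: float = 0.25
    alpha: float = 0.05
    window_alignment: str = "rolling"
    cutpoint_rule: str = "youden"
    roc_variables: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError("mode must be 'synthetic' or 'files'")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.mode == "files" and not (self.derivation_path and self.holdout_path):
            raise ConfigurationError(
                "files mode needs derivation_path and holdout_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = payload.pop("simulation", None)
        if sim is not None:
            if "diagnosis_probabilities" in sim:
                sim["diagnosis_probabilities"] = tuple(sim["diagnosis_probabilities"])
            if "exhaustion_logit_coefficients" in sim:
                sim["exhaustion_logit_coefficients"] = tuple(
                    sim["exhaustion_logit_coefficients"])
            payload["simulation"] = SimulationConfig(**sim)
        grid = payload.pop("grid", None)
        if grid is not None:
            payload["grid"] = [CriterionDefinition(**g) for g in grid]
        return cls(**payload)

    def config_hash(self) -> str:
        """Digest of the analysis parameters (the output location excluded,
        so re-running the same analysis elsewhere reproduces the stamp)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """In-memory results of one pipeline run (files live in ``output_dir``)."""

    config: AnalysisConfig
    derivation: pd.DataFrame
    holdout: pd.DataFrame
    cohort_summary: pd.DataFrame
    peak_summary: pd.DataFrame
    prevalence: pd.DataFrame
    stratified: pd.DataFrame
    or_table: pd.DataFrame
    cutpoints: dict[str, CutpointResult]
    roc_coordinates: pd.DataFrame
    combination: CombinationResult | None
    crosstable: CrossTable | None
    log_lines: list[str]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds (< 2**31) fanned out from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % 2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def _summary_block(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    rows = []
    for c in columns:
        x = pd.to_numeric(df[c], errors="coerce")
        rows.append({"variable": c, "n": int(x.notna().sum()),
                     "mean": x.mean(), "sd": x.std(ddof=1)})
    return pd.DataFrame(rows)


def _cohort_summary(derivation: pd.DataFrame, holdout: pd.DataFrame) -> pd.DataFrame:
    blocks = []
    for arm, df in (("derivation", derivation), ("holdout", holdout)):
        n = len(df)
        rows = [{"arm": arm, "variable": "n_subjects", "value": n}]
        rows.append({"arm": arm, "variable": "age_mean", "value": df["age"].mean()})
        rows.append({"arm": arm, "variable": "age_sd", "value": df["age"].std(ddof=1)})
        for d in ("breast", "prostate", "colorectal"):
            rows.append({"arm": arm, "variable": f"diagnosis_{d}_pct",
                         "value": 100.0 * (df["diagnosis"] == d).mean()})
        rows.append({"arm": arm, "variable": "evaluated_to_exhaustion_pct",
                     "value": 100.0 * df["leader_evaluation"].mean()})
        blocks.append(pd.DataFrame(rows))
    return pd.concat(blocks, ignore_index=True)


PEAK_COLUMNS = ["vo2peak_rel", "hrpeak", "pct_predicted_hr", "rerpeak",
                "vepeak", "frpeak", "rpepeak", "test_duration"]


def run_pipeline(config: AnalysisConfig) -> PipelineReport:
    """Run the full analysis and write the report bundle to ``output_dir``.

    Raises at the first failing stage with the stage name in the message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]

    # --- stage 1: input ----------------------------------------------------
    if config.mode == "synthetic":
        seed_a, seed_b = _child_seeds(config.seed, 2)
        sim_a = dataclasses.replace(config.simulation, seed=seed_a)
        sim_b = dataclasses.replace(config.simulation, seed=seed_b,
                                    n_subjects=config.n_holdout)
        _, derivation = generate_cohort(sim_a, study_arm="intervention",
                                        keep_series=False)
        _, holdout = generate_cohort(sim_b, study_arm="cohort", keep_series=False)
    else:
        if Path(config.derivation_path).resolve() == Path(config.holdout_path).resolve():
            raise LeakageError("derivation and hold-out paths are identical")
        derivation = read_cohort(config.derivation_path)
        holdout = read_cohort(config.holdout_path)
        overlap = set(derivation["subject_id"]) & set(holdout["subject_id"])
        if overlap:
            raise LeakageError(
                f"stage input: {len(overlap)} subject(s) in both cohorts")
    log.append(f"stage input: derivation n={len(derivation)}, "
               f"holdout n={len(holdout)}, excluded 0")

    cohort_summary = _cohort_summary(derivation, holdout)
    peak_summary = pd.concat([
        _summary_block(derivation, PEAK_COLUMNS).assign(arm="derivation"),
        _summary_block(holdout, PEAK_COLUMNS).assign(arm="holdout"),
    ], ignore_index=True)

    # --- stage 2: criteria -------------------------------------------------
    grid = config.grid if config.grid is not None else criteria_mod.default_grid()
    matrix = evaluate_criteria(derivation, grid)
    stratified = stratified_vo2_comparison(matrix, derivation)
    prevalence = pd.DataFrame({
        "criterion": [c.name for c in matrix.definitions],
        "n_fulfilled": matrix.counts.to_numpy(),
        "n_nonmissing": matrix.n_nonmissing.to_numpy(),
        "pct_fulfilled": matrix.percentages.to_numpy(),
    })
    log.append(f"stage criteria: rows in={len(derivation)}, "
               f"out={len(matrix.values)}, excluded 0")

    # --- stage 3: exhaustion models -----------------------------------------
    screen = adjusted_bivariate_screen(derivation)
    stepdown = hosmer_stepdown(derivation, screen, entry_p=config.entry_p)
    or_rows = []
    for var in KEY_VARIABLES:
        fit, orr = screen[var]
        row = {"variable": var, "scaling_unit": orr.scaling_unit,
               "bivariate_or": orr.or_value, "bivariate_ci_low": orr.ci_low,
               "bivariate_ci_high": orr.ci_high, "bivariate_p": orr.p,
               "bivariate_n": fit.n_used,
               "multivariate_or": np.nan, "multivariate_ci_low": np.nan,
               "multivariate_ci_high": np.nan, "multivariate_p": np.nan}
        for morr in stepdown.odds_ratios:
            if morr.variable == var:
                row.update(multivariate_or=morr.or_value,
                           multivariate_ci_low=morr.ci_low,
                           multivariate_ci_high=morr.ci_high,
                           multivariate_p=morr.p)
        or_rows.append(row)
    or_table = pd.DataFrame(or_rows)
    n_model = stepdown.fit.n_used if stepdown.fit is not None else 0
    log.append(f"stage models: rows in={len(derivation)}, used={n_model}, "
               f"excluded {len(derivation) - n_model} (listwise deletion)")

    # --- stage 4: ROC cut-points ---------------------------------------------
    if config.roc_variables is not None:
        roc_vars = list(config.roc_variables)
    else:
        roc_vars = [v for v in stepdown.included
                    if v in ROC_ELIGIBLE
                    and any(o.variable == v and np.isfinite(o.p) and o.p < config.alpha
                            for o in stepdown.odds_ratios)]
    cutpoints: dict[str, CutpointResult] = {}
    coord_rows = []
    labels = derivation["leader_evaluation"].astype(bool).to_numpy()
    for var in roc_vars:
        scores = pd.to_numeric(derivation[var], errors="coerce").to_numpy()
        roc = roc_curve(scores, labels, variable=var)
        cutpoints[var] = derive_cutpoint(roc, scores=scores, labels=labels,
                                         rule=config.cutpoint_rule)
        coord_rows.append(pd.DataFrame({
            "variable": var, "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "auc": roc.auc}))
    roc_coordinates = (pd.concat(coord_rows, ignore_index=True)
                       if coord_rows else pd.DataFrame(
                           columns=["variable", "threshold", "sensitivity",
                                    "specificity", "auc"]))
    log.append(f"stage roc: variables={roc_vars}")

    # --- stage 5: combined classifier + cross-validation ----------------------
    combination = None
    crosstable = None
    if cutpoints:
        def flags_for(df: pd.DataFrame) -> pd.DataFrame:
            return pd.DataFrame({
                v: pd.to_numeric(df[v], errors="coerce") >= cp.cutpoint
                for v, cp in cutpoints.items()}, index=df.index)

        combination = combine_criteria(flags_for(derivation), labels)
        log.append(f"stage combine: accuracy={combination.accuracy:.4f}, "
                   f"fallback={combination.used_fallback}")
        crosstable = cross_validate(
            holdout, predict=lambda df: combination.predict(flags_for(df)),
            derivation_ids=derivation.get("subject_id"))
        log.append(
            f"stage crossval: rows in={len(holdout)}, out={crosstable.n}, "
            f"excluded {len(holdout) - crosstable.n}")

    # --- write bundle ---------------------------------------------------------
    stamp = f"# config_hash={config.config_hash()} seed={config.seed}\n"

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write(stamp)
            df.to_csv(fh, index=False, float_format="%.9g")

    write_cohort(derivation, out / "derivation_cohort.csv")
    write_cohort(holdout, out / "holdout_cohort.csv")
    write_csv(cohort_summary, "cohort_summary.csv")
    write_csv(peak_summary, "peak_summary.csv")
    write_csv(prevalence, "criteria_prevalence.csv")
    write_csv(stratified, "criteria_stratified_vo2.csv")
    write_csv(or_table, "odds_ratios.csv")
    write_csv(roc_coordinates, "roc_coordinates.csv")
    cut_df = pd.DataFrame([dataclasses.asdict(cp) for cp in cutpoints.values()])
    write_csv(cut_df, "cutpoints.csv")

    report_lines = [stamp.strip(), ""]
    report_lines += log + [""]
    if cutpoints:
        for v, cp in cutpoints.items():
            report_lines.append(
                f"cut-point {v} >= {cp.cutpoint:g}: TPR {cp.tpr:.3f} "
                f"(95% CI {cp.tpr_ci_low:.3f}-{cp.tpr_ci_high:.3f}), "
                f"accuracy {round_half_up(100 * cp.accuracy):.0f}%")
    if combination is not None:
        report_lines.append(
            f"combined criteria accuracy: "
            f"{round_half_up(100 * combination.accuracy):.0f}%"
            + (" (deterministic >=2/3 fallback)" if combination.used_fallback else ""))
    if crosstable is not None:
        report_lines.append("")
        report_lines.append(crosstable.report())
    (out / "report.txt").write_text("\n".join(report_lines) + "\n", encoding="utf-8")

    for line in log:
        logger.info(line)
    return PipelineReport(config=config, derivation=derivation, holdout=holdout,
                          cohort_summary=cohort_summary, peak_summary=peak_summary,
                          prevalence=prevalence, stratified=stratified,
                          or_table=or_table, cutpoints=cutpoints,
                          roc_coordinates=roc_coordinates,
                          combination=combination, crosstable=crosstable,
                          log_lines=log)
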