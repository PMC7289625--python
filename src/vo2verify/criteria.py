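"""Scoring of VO2max-verification criteria across a cohort.

A criterion is a (variable, direction, cut-point) triple such as
"RERpeak >= 1.10" or "plateau delta <= 80 mL/min".  All comparisons are
inclusive.  The default grid covers the cut-points commonly applied when
verifying VO2max: RER >= {1.00, 1.05, 1.10, 1.15}, Borg RPE >= {17, 18, 19},
percent of Tanaka-predicted HRmax >= {85, 90, 95}, fR >= 40 breaths/min and
plateau delta <= {150, 80, 50} mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

#: cohort-table column backing each criterion variable
VARIABLE_COLUMNS = {
    "rerpeak": "rerpeak",
    "rpepeak": "rpepeak",
    "pct_predicted_hr": "pct_predicted_hr",
    "frpeak": "frpeak",
    "plateau": "plateau_min_delta",
}


@dataclass(frozen=True)
class CriterionDefinition:
    """One criterion/cut-point pair.

    ``direction`` is ">=" for peak-value criteria and "<=" for the plateau
    delta (smaller change in VO2 from one minute to the next = plateau).
    """

    name: str
    variable: str
    direction: str
    cutpoint: float

    def __post_init__(self) -> None:
        if self.variable not in VARIABLE_COLUMNS:
            raise ConfigurationError(
                f"unknown criterion variable {self.variable!r}; expected one of "
                f"{sorted(VARIABLE_COLUMNS)}")
        if self.direction not in (">=", "<="):
            raise ConfigurationError("direction must be '>=' or '<='")
        if self.direction == "<=" and self.variable != "plateau":
            raise ConfigurationError(
                "'<=' criteria are only defined for the plateau delta")
        if not np.isfinite(self.cutpoint):
            raise ConfigurationError("cutpoint must be finite")


def default_grid() -> list[CriterionDefinition]:
    grid = [CriterionDefinition(f"RER>={c:.2f}", "rerpeak", ">=", c)
            for c in (1.00, 1.05, 1.10, 1.15)]
    grid += [CriterionDefinition(f"RPE>={c}", "rpepeak", ">=", c)
             for c in (17, 18, 19)]
    grid += [CriterionDefinition(f"%predHR>={c}", "pct_predicted_hr", ">=", c)
             for c in (85, 90, 95)]
    grid += [CriterionDefinition("fR>=40", "frpeak", ">=", 40)]
    grid += [CriterionDefinition(f"plateau<={c}", "plateau", "<=", c)
             for c in (150, 80, 50)]
    return grid


@dataclass
class CriteriaMatrix:
    """Per-subject boolean fulfilment of each criterion, with margins.

    ``values`` has one row per subject and one (nullable boolean) column per
    criterion; missing inputs yield missing cells, which are excluded from
    the margins.  ``percentages`` are 100 * fulfilled / non-missing.
    """

    values: pd.DataFrame
    definitions: list[CriterionDefinition]

    @property
    def counts(self) -> pd.Series:
        return self.values.sum(skipna=True).astype(int)

    @property
    def n_nonmissing(self) -> pd.Series:
        return self.values.notna().sum()

    @property
    def percentages(self) -> pd.Series:
        return 100.0 * self.counts / self.n_nonmissing


def evaluate_criteria(cohort: pd.DataFrame,
                      grid: list[CriterionDefinition] | None = None) -> CriteriaMatrix:
    """Score every criterion/cut-point pair for every subject.

    Cells are True/False where the input is present, <NA> where missing.
    """
    if grid is None:
        grid = default_grid()
    out = {}
    for crit in grid:
        col = VARIABLE_COLUMNS[crit.variable]
        if col not in cohort.columns:
            raise ConfigurationError(
                f"cohort table lacks column {col!r} needed by criterion "
                f"{crit.name!r}")
        x = pd.to_numeric(cohort[col], errors="coerce")
        if crit.direction == ">=":
            cell = x >= crit.cutpoint
        else:
            cell = x <= crit.cutpoint
        out[crit.name] = cell.astype("boolean").mask(x.isna())
    values = pd.DataFrame(out, index=cohort.index)
    return CriteriaMatrix(values=values, definitions=list(grid))


def stratified_vo2_comparison(matrix: CriteriaMatrix,
                              cohort: pd.DataFrame,
                              value_column: str = "vo2peak_rel") -> pd.DataFrame:
    """Mean (SD) VO2peak among fulfillers vs non-fulfillers of each criterion.

    The two strata are compared with Welch's unequal-variance two-sample
    t-test (two-sided).  A criterion with an empty stratum is reported with
    ``computable = False`` and a missing p-value, never p = 1.
    """
    rows = []
    vo2 = pd.to_numeric(cohort[value_column], errors="coerce")
    for crit in matrix.definitions:
        cell = matrix.values[crit.name]
        ok = cell.notna() & vo2.notna()
        yes = vo2[ok & (cell == True)]  # noqa: E712 (nullable boolean mask)
        no = vo2[ok & (cell == False)]  # noqa: E712
        row = {
            "criterion": crit.name,
            "n_fulfilled": len(yes),
            "mean_fulfilled": yes.mean() if len(yes) else np.nan,
            "sd_fulfilled": yes.std(ddof=1) if len(yes) > 1 else np.nan,
            "n_not_fulfilled": len(no),
            "mean_not_fulfilled": no.mean() if len(no) else np.nan,
            "sd_not_fulfilled": no.std(ddof=1) if len(no) > 1 else np.nan,
        }
        if len(yes) >= 2 and len(no) >= 2:
            t, p = stats.ttest_ind(yes, no, equal_var=False)
            row.update(p_value=float(p), computable=True)
        else:
            row.update(p_value=np.nan, computable=False)
        rows.append(row)
    return pd.DataFrame(rows)


def combination_counts(flags: pd.DataFrame) -> pd.Series:
    """Counts of subjects fulfilling exactly 0..k of k boolean criteria."""
    total = flags.astype(bool).sum(axis=1)
    k = flags.shape[1]
    return total.value_counts().reindex(range(k + 1), fill_value=0).sort_index()
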