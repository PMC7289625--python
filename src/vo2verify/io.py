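"""Reading, writing and validating the two tabular CPET formats.

Two on-disk shapes are supported:

* **Gas-exchange series** -- one file per test, UTF-8 CSV, one header row,
  columns ``time,vo2,vco2,ve,fr,hr,phase``.  Time is seconds from the start
  of the warm-up, VO2/VCO2 in mL/min, VE in L/min, fR in breaths/min, HR in
  beats/min, ``phase`` in {warmup, incremental}.  File-level metadata is
  carried in leading ``# key=value`` comment lines (``subject_id``,
  ``acquisition_interval``, optional ``hr_interval``).
* **Cohort table** -- one row per subject with demographics, peak values,
  test duration and the test leader's binary exhaustion evaluation.  CSV is
  canonical; XLSX is accepted read-only (study supplements usually ship as
  spreadsheets).

Missing values are empty fields; no sentinel numbers.  Validation never
mutates data and all failures carry row/column coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_ACQUISITION_INTERVALS = (10, 15, 30)
VALID_HR_INTERVALS = (5, 15)

SERIES_COLUMNS = ["time", "vo2", "vco2", "ve", "fr", "hr", "phase"]
PHASES = ("warmup", "incremental")

#: Canonical cohort-table columns.  ``leader_evaluation`` is the analysis
#: outcome and must be present and non-missing.
COHORT_REQUIRED = [
    "subject_id", "age", "diagnosis", "leader_evaluation",
    "hrpeak", "rerpeak", "rpepeak", "frpeak", "vo2peak_rel",
]
DIAGNOSES = ("breast", "prostate", "colorectal")


@dataclass
class GasExchangeSeries:
    """Time-stamped gas-exchange samples for one test.

    ``data`` holds one row per acquisition-interval sample with columns
    ``time, vo2, vco2, ve, fr, hr, phase``; times are strictly increasing
    and equally spaced at ``acquisition_interval`` seconds.
    """

    subject_id: str
    acquisition_interval: int
    data: pd.DataFrame = field(repr=False)
    hr_interval: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- views ------------------------------------------------------------
    @property
    def incremental(self) -> pd.DataFrame:
        """Samples belonging to the incremental phase (warm-up excluded)."""
        return self.data[self.data["phase"] == "incremental"]

    @property
    def duration_min(self) -> float:
        """Total recorded duration in minutes (each sample spans one interval)."""
        return len(self.data) * self.acquisition_interval / 60.0

    @property
    def incremental_duration_min(self) -> float:
        return len(self.incremental) * self.acquisition_interval / 60.0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.acquisition_interval not in VALID_ACQUISITION_INTERVALS:
            raise ValidationError(
                f"acquisition_interval must be one of {VALID_ACQUISITION_INTERVALS}, "
                f"got {self.acquisition_interval}")
        if self.hr_interval is not None and self.hr_interval not in VALID_HR_INTERVALS:
            raise ValidationError(
                f"hr_interval must be one of {VALID_HR_INTERVALS}, got {self.hr_interval}")
        missing = [c for c in SERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"series is missing columns {missing}")
        t = self.data["time"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValidationError("series has no samples")
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - self.acquisition_interval) > 1e-6)[0]
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"unequal time spacing: gap of {dt[i]:g} s where "
                f"{self.acquisition_interval} s was declared", row=i + 1, column="time")
        for col in ("vo2", "vco2", "ve", "fr", "hr"):
            v = self.data[col].to_numpy(dtype=float)
            neg = np.nonzero(v < 0)[0]
            if neg.size:
                raise ValidationError(f"negative value {v[neg[0]]:g}",
                                      row=int(neg[0]), column=col)
        bad_phase = ~self.data["phase"].isin(PHASES)
        if bad_phase.any():
            i = int(np.nonzero(bad_phase.to_numpy())[0][0])
            raise ValidationError(
                f"unknown phase {self.data['phase'].iloc[i]!r}", row=i, column="phase")
        fr_inc = self.incremental["fr"].to_numpy(dtype=float)
        zero = np.nonzero(~np.isnan(fr_inc) & (fr_inc <= 0))[0]
        if zero.size:
            raise ValidationError("fr must be > 0 during the incremental phase",
                                  row=int(zero[0]), column="fr")

    def flag_missing(self) -> pd.Series:
        """Boolean mask of rows with any missing gas value (flagged, never dropped)."""
        return self.data[["vo2", "vco2", "ve", "fr", "hr"]].isna().any(axis=1)


# ---------------------------------------------------------------------------
# series files
# ---------------------------------------------------------------------------

def write_series(series: GasExchangeSeries, path: str | Path) -> None:
    """Write a series to the canonical CSV dialect (metadata in ``#`` lines)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# subject_id={series.subject_id}\n")
        fh.write(f"# acquisition_interval={series.acquisition_interval}\n")
        if series.hr_interval is not None:
            fh.write(f"# hr_interval={series.hr_interval}\n")
        series.data.to_csv(fh, index=False, float_format="%.17g")


def read_series(path: str | Path,
                acquisition_interval: int | None = None,
                hr_interval: int | None = None,
                subject_id: str | None = None) -> GasExchangeSeries:
    """Read and validate a gas-exchange series file.

    The acquisition interval is taken from the ``# acquisition_interval=``
    header line; an explicit ``acquisition_interval`` argument overrides it.
    Rows with missing gas values are kept and flagged downstream.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_comment = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    if acquisition_interval is None:
        if "acquisition_interval" not in meta:
            raise FormatError(
                f"{path.name}: no acquisition interval declared in the header "
                "and none supplied")
        acquisition_interval = int(meta["acquisition_interval"])
    if hr_interval is None and "hr_interval" in meta:
        hr_interval = int(meta["hr_interval"])
    if subject_id is None:
        subject_id = meta.get("subject_id", path.stem)

    data = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing_cols = [c for c in SERIES_COLUMNS if c not in data.columns]
    if missing_cols:
        raise FormatError(f"{path.name}: missing columns {missing_cols}")
    return GasExchangeSeries(subject_id=subject_id,
                             acquisition_interval=acquisition_interval,
                             data=data[SERIES_COLUMNS].copy(),
                             hr_interval=hr_interval)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "to exhaustion"}
_FALSY = {"0", "false", "no", "n", "not to exhaustion"}


def _normalize_bool(value, row: int, column: str) -> bool | float:
    if pd.isna(value):
        return np.nan
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean",
                          row=row, column=column)


def read_cohort(path: str | Path,
                column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-subject cohort table (CSV or XLSX).

    Parameters
    ----------
    path : path
        CSV (canonical) or XLSX (read-only convenience) file.
    column_map : dict, optional
        Mapping from the file's column names to the canonical names, for
        tables whose layout differs from the canonical one.

    Returns
    -------
    pandas.DataFrame
        One row per subject, canonical column names, diagnosis case-folded
        to the controlled vocabulary, ``leader_evaluation`` boolean.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    if len(table) == 0:
        return table
    if "leader_evaluation" not in table.columns:
        raise FormatError("cohort table lacks the 'leader_evaluation' column "
                          "(the analysis outcome)", column="leader_evaluation")
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table is missing required columns {missing}")
    table = table.copy()
    table["diagnosis"] = (
        table["diagnosis"].astype(str).str.strip().str.lower())
    unknown = ~table["diagnosis"].isin(DIAGNOSES) & table["diagnosis"].notna()
    if unknown.any():
        i = int(np.nonzero(unknown.to_numpy())[0][0])
        raise ValidationError(
            f"unknown diagnosis {table['diagnosis'].iloc[i]!r}; expected one of "
            f"{DIAGNOSES}", row=i, column="diagnosis")
    table["leader_evaluation"] = [
        _normalize_bool(v, i, "leader_evaluation")
        for i, v in enumerate(table["leader_evaluation"])
    ]
    if table["leader_evaluation"].isna().any():
        i = int(np.nonzero(table["leader_evaluation"].isna().to_numpy())[0][0])
        raise ValidationError("leader_evaluation must be non-missing",
                              row=i, column="leader_evaluation")
    table["leader_evaluation"] = table["leader_evaluation"].astype(bool)
    dupes = table.duplicated(
        subset=[c for c in ("subject_id", "study_arm") if c in table.columns])
    if dupes.any():
        i = int(np.nonzero(dupes.to_numpy())[0][0])
        raise ValidationError("duplicate subject_id within study arm",
                              row=i, column="subject_id")
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as canonical CSV (empty fields for missing)."""
    table.to_csv(path, index=False, float_format="%.17g")
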