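"""Logistic modelling of the test leader's exhaustion evaluation.

The analysis follows a purposeful (Hosmer-style step-down) selection:

1. *Adjusted bivariate screen* -- one logistic model per key variable
   (plateau at 150 mL/min, HRpeak, RERpeak, Borg RPEpeak, fRpeak), each
   adjusted for age, diagnosis, VO2peak and test duration, with the binary
   leader evaluation as outcome.
2. *Step-down* -- every key variable whose screen Wald p-value is below the
   entry level (default 0.25) enters one final multivariate model together
   with the adjusters.

Odds ratios are reported per interpretable unit: per 0.10 RER and per one
unit otherwise, with 95 % Wald confidence intervals.  Pairwise Pearson
correlations among the key variables, VO2peak and test duration document
collinearity.  Missing covariates are handled by listwise deletion with the
used n recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError

KEY_VARIABLES = ["plateau_150", "hrpeak", "rerpeak", "rpepeak", "frpeak"]
ADJUSTERS = ["age", "diagnosis", "vo2peak_rel", "test_duration"]
OUTCOME = "leader_evaluation"
DIAGNOSIS_REFERENCE = "breast"  # largest group

#: amount of the variable corresponding to one OR unit
OR_SCALING = {"rerpeak": 0.10}
Z95 = 1.959963984540054


@dataclass
class LogisticFit:
    """A fitted logistic regression: term table, fit metadata."""

    terms: pd.DataFrame  # index: term name; columns: coef, se, z, p
    n_used: int
    log_likelihood: float
    converged: bool
    outcome: str = OUTCOME

    def coef(self, name: str) -> float:
        return float(self.terms.loc[name, "coef"])

    def p(self, name: str) -> float:
        return float(self.terms.loc[name, "p"])


@dataclass(frozen=True)
class ORResult:
    """Odds ratio per ``scaling_unit`` of ``variable`` with 95 % Wald CI."""

    variable: str
    scaling_unit: float
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    model: str  # bivariate | multivariate


@dataclass
class StepdownResult:
    fit: LogisticFit | None
    odds_ratios: list[ORResult]
    included: list[str]
    excluded: dict[str, float]  # variable -> screen p that failed entry


def _design(cohort: pd.DataFrame, variables: list[str]) -> tuple[pd.Series, pd.DataFrame, int]:
    """Listwise-deleted outcome/design matrices with diagnosis contrasts."""
    needed = [OUTCOME] + [v for v in variables]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort table lacks columns {missing}")
    data = cohort[needed].dropna()
    y = data[OUTCOME].astype(float)
    cols = {}
    for v in variables:
        if v == "diagnosis":
            for level in sorted(data["diagnosis"].unique()):
                if level == DIAGNOSIS_REFERENCE:
                    continue
                cols[f"diagnosis[{level}]"] = (data["diagnosis"] == level).astype(float)
        else:
            cols[v] = pd.to_numeric(data[v], errors="coerce").astype(float)
    X = pd.DataFrame(cols, index=data.index)
    X = sm.add_constant(X, prepend=True)
    return y, X, len(data)


def fit_logistic(cohort: pd.DataFrame, variables: list[str]) -> LogisticFit:
    """Fit outcome ~ variables by maximum likelihood (Wald inference).

    Quasi-separated fits are returned flagged ``converged=False`` (with a
    diagnostic in the term table) rather than raised.
    """
    y, X, n = _design(cohort, variables)
    if y.nunique() < 2:
        raise ConfigurationError("outcome has a single class; model undefined")
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation / overflow diagnostics
            res = model.fit(disp=0, maxiter=200, method="newton", tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:  # perfect separation raises in some statsmodels versions
        res = None
        converged = False
    if res is None or not np.isfinite(res.bse).all():
        converged = False
    if res is None:
        terms = pd.DataFrame(
            {"coef": np.nan, "se": np.nan, "z": np.nan, "p": np.nan},
            index=X.columns)
        return LogisticFit(terms=terms, n_used=n, log_likelihood=np.nan,
                           converged=False)
    terms = pd.DataFrame({
        "coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues,
    })
    return LogisticFit(terms=terms, n_used=n, log_likelihood=float(res.llf),
                       converged=converged)


def odds_ratio(fit: LogisticFit, variable: str, model: str,
               scaling: dict[str, float] | None = None) -> ORResult:
    """Wald OR and 95 % CI for one term, scaled per ``OR_SCALING`` units."""
    scaling = OR_SCALING if scaling is None else scaling
    unit = float(scaling.get(variable, 1.0))
    coef = fit.coef(variable)
    se = float(fit.terms.loc[variable, "se"])
    return ORResult(
        variable=variable,
        scaling_unit=unit,
        or_value=float(np.exp(unit * coef)),
        ci_low=float(np.exp(unit * (coef - Z95 * se))),
        ci_high=float(np.exp(unit * (coef + Z95 * se))),
        p=fit.p(variable),
        model=model,
    )


def adjusted_bivariate_screen(cohort: pd.DataFrame,
                              key_variables: list[str] | None = None,
                              adjusters: list[str] | None = None,
                              ) -> dict[str, tuple[LogisticFit, ORResult]]:
    """One adjusted logistic model per key variable.

    Returns a mapping ``variable -> (fit, scaled OR)``; non-converged fits
    carry a missing OR (NaN) and are flagged on the fit object.
    """
    key_variables = KEY_VARIABLES if key_variables is None else key_variables
    adjusters = ADJUSTERS if adjusters is None else adjusters
    out = {}
    for var in key_variables:
        fit = fit_logistic(cohort, [var] + list(adjusters))
        if fit.converged:
            out[var] = (fit, odds_ratio(fit, var, model="bivariate"))
        else:
            out[var] = (fit, ORResult(var, OR_SCALING.get(var, 1.0),
                                      np.nan, np.nan, np.nan, np.nan, "bivariate"))
    return out


def hosmer_stepdown(cohort: pd.DataFrame,
                    screen: dict[str, tuple[LogisticFit, ORResult]] | None = None,
                    key_variables: list[str] | None = None,
                    adjusters: list[str] | None = None,
                    entry_p: float = 0.25) -> StepdownResult:
    """Single-step purposeful selection into one multivariate model.

    Key variables with screen Wald p below ``entry_p`` enter the final model
    jointly with the adjusters.  If none passes entry, an explicitly empty
    model (fit=None) is returned together with every screen p-value.
    """
    key_variables = KEY_VARIABLES if key_variables is None else key_variables
    adjusters = ADJUSTERS if adjusters is None else adjusters
    if screen is None:
        screen = adjusted_bivariate_screen(cohort, key_variables, adjusters)
    included, excluded = [], {}
    for var in key_variables:
        fit, _ = screen[var]
        p = fit.p(var) if fit.converged else np.nan
        if np.isfinite(p) and p < entry_p:
            included.append(var)
        else:
            excluded[var] = p
    if not included:
        return StepdownResult(fit=None, odds_ratios=[], included=[],
                              excluded=excluded)
    final = fit_logistic(cohort, included + list(adjusters))
    ors = [odds_ratio(final, v, model="multivariate") for v in included]
    return StepdownResult(fit=final, odds_ratios=ors, included=included,
                          excluded=excluded)


CORRELATION_VARIABLES = ["plateau_150", "hrpeak", "rerpeak", "rpepeak",
                         "frpeak", "vo2peak_rel", "test_duration"]


def pairwise_correlations(cohort: pd.DataFrame,
                          variables: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations among the key variables, VO2peak and test time.

    The binary plateau indicator enters as 0/1 (point-biserial, numerically
    identical to Pearson).  Zero-variance variables yield missing entries.
    Requires at least 3 complete rows.
    """
    variables = CORRELATION_VARIABLES if variables is None else variables
    data = cohort[variables].astype(float).dropna()
    if len(data) < 3:
        raise ConfigurationError("need at least 3 complete rows for correlations")
    return data.corr(method="pearson")
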