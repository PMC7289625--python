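"""ROC analysis and optimal cut-point derivation.

For each candidate criterion variable the ROC curve is traced over the
observed unique score values with ">= threshold" orientation; the area
under the curve is computed by the trapezoid rule, which equals the
tie-corrected concordance (Mann-Whitney) statistic.  The operating
cut-point maximises Youden's J = sensitivity + specificity - 1 (a
closest-to-(0,1)-corner rule is available as an alternative), and the true
positive rate at the cut-point is reported with a Wilson score 95 %
confidence interval.  A logistic model on the three derived criterion
booleans gives the combined predicted-probability classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, UndefinedROCError
from .exhaustion import fit_logistic

Z95 = 1.959963984540054


@dataclass
class ROCResult:
    """ROC coordinates for one score against binary labels.

    ``thresholds`` are the observed unique score values in decreasing order;
    ``sensitivity[i]``/``specificity[i]`` are the operating characteristics
    of the classifier "positive iff score >= thresholds[i]".
    """

    variable: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutpointResult:
    """An ROC-derived operating threshold and its performance."""

    variable: str
    cutpoint: float
    sensitivity: float
    specificity: float
    youden_j: float
    tpr: float
    tpr_ci_low: float
    tpr_ci_high: float
    accuracy: float


@dataclass
class CombinationResult:
    """Combined classification from three criterion booleans.

    ``counts[k]`` is the number of subjects fulfilling exactly k criteria.
    ``penalized`` records that the maximum-likelihood fit did not exist
    (separation) and a ridge-penalized fit supplied the coefficients;
    ``used_fallback`` that even that failed and the deterministic
    ">= 2 of 3 criteria" rule was used instead.
    """

    criteria: list[str]
    counts: pd.Series
    accuracy: float
    coefficients: pd.Series | None
    used_fallback: bool
    penalized: bool = False

    def predict(self, flags: pd.DataFrame) -> np.ndarray:
        """Classify new subjects from their criterion booleans."""
        X = flags[self.criteria].astype(float).to_numpy()
        if self.used_fallback:
            return X.sum(axis=1) >= 2
        beta = self.coefficients.to_numpy()
        logit = beta[0] + X @ beta[1:]
        return 1.0 / (1.0 + np.exp(-logit)) >= 0.5


def wilson_interval(successes: int, n: int, z: float = Z95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    phat = successes / n
    denom = 1 + z ** 2 / n
    centre = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def roc_curve(scores, labels, variable: str = "score") -> ROCResult:
    """Trace the ROC curve of ``scores`` against binary ``labels``.

    Raises
    ------
    UndefinedROCError
        If only one outcome class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ConfigurationError("scores and labels must have the same length")
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(
            f"both outcome classes are required (got {n_pos} positives, "
            f"{n_neg} negatives)")
    thresholds = np.unique(scores)[::-1]  # decreasing
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)
    # index of the last sample with score >= each threshold
    last = np.searchsorted(-s_sorted, -thresholds, side="right") - 1
    tp = cum_tp[last]
    fp = cum_fp[last]
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    # trapezoid AUC over the full curve including the (0,0) and (1,1) corners
    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(variable=variable, thresholds=thresholds,
                     sensitivity=sens, specificity=spec, auc=auc,
                     n_pos=n_pos, n_neg=n_neg)


def derive_cutpoint(roc: ROCResult, scores=None, labels=None,
                    rule: str = "youden") -> CutpointResult:
    """Choose the operating threshold from an ROC curve.

    ``rule="youden"`` (default) maximises J = sensitivity + specificity - 1;
    ``rule="closest01"`` minimises the Euclidean distance to the (0, 1)
    corner.  Ties are broken toward higher sensitivity, then toward the
    lower threshold.  When the original ``scores``/``labels`` are supplied,
    classification accuracy at the cut-point is computed from them;
    otherwise it is reconstructed from the curve's class counts (identical).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    if rule == "youden":
        objective = j
    elif rule == "closest01":
        objective = -np.sqrt((1 - roc.sensitivity) ** 2 + (1 - roc.specificity) ** 2)
    else:
        raise ConfigurationError(f"unknown cut-point rule {rule!r}")
    best = objective.max()
    candidates = np.nonzero(objective >= best - 1e-12)[0]
    # ties: higher sensitivity first, then lower threshold (later index)
    sens_c = roc.sensitivity[candidates]
    keep = candidates[sens_c >= sens_c.max() - 1e-12]
    idx = int(keep.max())  # thresholds are decreasing: max index = lowest value
    cut = float(roc.thresholds[idx])
    sens = float(roc.sensitivity[idx])
    spec = float(roc.specificity[idx])
    tp = int(round(sens * roc.n_pos))
    tn = int(round(spec * roc.n_neg))
    accuracy = (tp + tn) / (roc.n_pos + roc.n_neg)
    if scores is not None and labels is not None:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        ok = ~np.isnan(scores)
        pred = scores[ok] >= cut
        accuracy = float((pred == labels[ok]).mean())
    lo, hi = wilson_interval(tp, roc.n_pos)
    return CutpointResult(variable=roc.variable, cutpoint=cut,
                          sensitivity=sens, specificity=spec,
                          youden_j=float(j[idx]), tpr=sens,
                          tpr_ci_low=lo, tpr_ci_high=hi,
                          accuracy=float(accuracy))


def combine_criteria(flags: pd.DataFrame, labels) -> CombinationResult:
    """Fit the combined classifier on criterion booleans.

    A logistic model of the leader evaluation on the criterion indicator
    columns of ``flags`` is fitted and subjects are classified at predicted
    probability 0.5.  Under separation the maximum-likelihood estimate does
    not exist; a lightly ridge-penalized fit then supplies the classifier
    (recorded via ``penalized``), and only if that also fails does the
    deterministic "positive iff >= 2 of 3 criteria" rule apply (recorded
    via ``used_fallback``).
    """
    labels = np.asarray(labels, dtype=bool)
    criteria = list(flags.columns)
    X = flags.astype(bool)
    counts = X.sum(axis=1).value_counts().reindex(
        range(len(criteria) + 1), fill_value=0).sort_index()
    data = X.astype(float).copy()
    data["leader_evaluation"] = labels
    fit = fit_logistic(data, criteria)
    coefficients: pd.Series | None = None
    penalized = False
    if fit.converged:
        coefficients = fit.terms["coef"]
    else:
        try:
            Xd = sm.add_constant(X.astype(float), prepend=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(labels.astype(float), Xd,
                             family=sm.families.Binomial()).fit_regularized(
                                 alpha=1e-4, L1_wt=0.0)
            if np.isfinite(res.params).all():
                coefficients = pd.Series(res.params, index=Xd.columns)
                penalized = True
        except Exception:
            coefficients = None
    if coefficients is not None:
        beta = coefficients.to_numpy()
        logit = beta[0] + X.astype(float).to_numpy() @ beta[1:]
        pred = 1.0 / (1.0 + np.exp(-logit)) >= 0.5
        used_fallback = False
    else:
        pred = X.sum(axis=1).to_numpy() >= 2
        used_fallback = True
    accuracy = float((pred == labels).mean())
    return CombinationResult(criteria=criteria, counts=counts,
                             accuracy=accuracy, coefficients=coefficients,
                             used_fallback=used_fallback, penalized=penalized)
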