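"""External cross-validation of derived cut-points on a hold-out cohort.

The classifier fitted on the derivation cohort is applied unchanged to an
independent hold-out cohort and summarised in a 2x2 cross-table: counts of
true/false positives/negatives against the test leader's evaluation,
overall accuracy and the per-class accuracies.  Percentages in reports are
rounded half-up to integers; unrounded values stay in machine output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import LeakageError

SMALL_CLASS_WARNING_N = 10


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero (matching printed-report conventions)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTable:
    """2x2 classification table of predictions against leader evaluations."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def overall_accuracy(self) -> float:
        """Percent of all evaluations correctly classified."""
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def accuracy_positive_class(self) -> float:
        """Percent of 'to exhaustion' evaluations correctly classified."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def accuracy_negative_class(self) -> float:
        """Percent of 'not to exhaustion' evaluations correctly classified."""
        return 100.0 * self.tn / (self.tn + self.fp)

    def report(self) -> str:
        """Human-readable summary with integer (half-up) percentages."""
        lines = [
            "Cross-validation cross-table",
            f"  n = {self.n}  (positives {self.tp + self.fn}, "
            f"negatives {self.tn + self.fp})",
            f"  TP={self.tp}  FN={self.fn}  TN={self.tn}  FP={self.fp}",
            f"  overall accuracy: {round_half_up(self.overall_accuracy):.0f}%",
            f"  'to exhaustion' class accuracy: "
            f"{round_half_up(self.accuracy_positive_class):.0f}%",
            f"  'not to exhaustion' class accuracy: "
            f"{round_half_up(self.accuracy_negative_class):.0f}%",
        ]
        return "\n".join(lines)


def majority_rule(flags: pd.DataFrame, k: int = 2) -> np.ndarray:
    """Deterministic rule: positive iff at least ``k`` criteria fulfilled."""
    return flags.astype(bool).sum(axis=1).to_numpy() >= k


def cross_validate(holdout: pd.DataFrame,
                   predict: Callable[[pd.DataFrame], np.ndarray],
                   label_column: str = "leader_evaluation",
                   derivation_ids: Iterable | None = None) -> CrossTable:
    """Apply a derivation-fitted classifier to an independent cohort.

    Parameters
    ----------
    holdout : DataFrame
        Hold-out cohort with the feature columns the classifier needs and
        the leader-evaluation labels.
    predict : callable
        Classifier fitted on the derivation cohort only; receives the
        hold-out table, returns a boolean prediction per row.
    derivation_ids : iterable, optional
        Subject ids of the derivation cohort; any overlap with the hold-out
        raises :class:`LeakageError`.
    """
    if derivation_ids is not None and "subject_id" in holdout.columns:
        overlap = set(derivation_ids) & set(holdout["subject_id"])
        if overlap:
            raise LeakageError(
                f"{len(overlap)} derivation-cohort subject(s) present in the "
                f"hold-out cohort (e.g. {sorted(overlap)[:3]})")
    labels = holdout[label_column].astype(bool).to_numpy()
    pred = np.asarray(predict(holdout), dtype=bool)
    if pred.shape != labels.shape:
        raise ValueError("classifier returned a prediction vector of wrong length")
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    n_neg = tn + fp
    n_pos = tp + fn
    if min(n_neg, n_pos) < SMALL_CLASS_WARNING_N:
        warnings.warn(
            f"hold-out class imbalance: only {min(n_neg, n_pos)} subjects in the "
            "minority class; class-specific accuracies are unstable",
            stacklevel=2)
    return CrossTable(tp=tp, fp=fp, tn=tn, fn=fn)
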