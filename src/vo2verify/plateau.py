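"""VO2-plateau detection.

A plateau (levelling-off of oxygen uptake despite increasing workload) is
scored by comparing the highest 1-minute mean of VO2 with the adjacent,
non-overlapping minutes immediately before and after it.  The plateau
criterion at threshold T (mL/min) is fulfilled when the smaller of the two
available differences is <= T.  Three classical thresholds are scored:
150, 80 and 50 mL/min; 150 mL/min is the one carried into the exhaustion
models because protocols with small per-stage VO2 increments fit it best.

Because the reference window is the maximum, both deltas are non-negative
by construction and the thresholds nest: fulfilment at 50 implies 80
implies 150.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, UndefinedPlateauError
from .io import GasExchangeSeries

DEFAULT_THRESHOLDS = (150.0, 80.0, 50.0)


@dataclass(frozen=True)
class PlateauResult:
    """Outcome of plateau detection on one series.

    ``delta_prev`` / ``delta_next`` are (highest minute mean) minus the
    adjacent minute's mean, in mL/min; either may be None when the adjacent
    full minute does not exist (e.g. there is no "minute after" once the
    test has terminated).  ``min_delta`` is the minimum over the available
    deltas, and ``fulfilled[T]`` is ``min_delta <= T``.
    """

    highest_minute_mean: float
    delta_prev: float | None
    delta_next: float | None
    fulfilled: dict[float, bool] = field(default_factory=dict)

    @property
    def min_delta(self) -> float:
        deltas = [d for d in (self.delta_prev, self.delta_next) if d is not None]
        return float(min(deltas))

    @property
    def fulfilled_150(self) -> bool:
        return self.fulfilled[150.0]

    @property
    def fulfilled_80(self) -> bool:
        return self.fulfilled[80.0]

    @property
    def fulfilled_50(self) -> bool:
        return self.fulfilled[50.0]


def detect_plateau_values(vo2: np.ndarray,
                          interval: int,
                          thresholds=DEFAULT_THRESHOLDS,
                          alignment: str = "rolling") -> PlateauResult:
    """Plateau detection on a raw incremental-phase VO2 vector (mL/min)."""
    vo2 = np.asarray(vo2, dtype=float)
    w = int(round(60.0 / interval))
    if len(vo2) < 2 * w:
        raise UndefinedPlateauError(
            f"plateau is undefined for series shorter than two full minutes "
            f"({len(vo2)} samples at {interval} s)")
    if alignment == "rolling":
        means = np.lib.stride_tricks.sliding_window_view(vo2, w).mean(axis=1)
        i = int(np.argmax(means))
        peak = float(means[i])
        delta_prev = peak - float(vo2[i - w:i].mean()) if i >= w else None
        delta_next = (peak - float(vo2[i + w:i + 2 * w].mean())
                      if i + 2 * w <= len(vo2) else None)
    elif alignment == "minute":
        n_full = len(vo2) // w
        means = vo2[: n_full * w].reshape(n_full, w).mean(axis=1)
        i = int(np.argmax(means))
        peak = float(means[i])
        delta_prev = peak - float(means[i - 1]) if i >= 1 else None
        delta_next = peak - float(means[i + 1]) if i + 1 < n_full else None
    else:
        raise ConfigurationError(
            f"window alignment must be 'rolling' or 'minute', got {alignment!r}")
    if delta_prev is None and delta_next is None:
        raise UndefinedPlateauError(
            "no adjacent full minute exists on either side of the peak minute")
    min_delta = min(d for d in (delta_prev, delta_next) if d is not None)
    fulfilled = {float(t): bool(min_delta <= t) for t in thresholds}
    return PlateauResult(highest_minute_mean=peak,
                         delta_prev=delta_prev,
                         delta_next=delta_next,
                         fulfilled=fulfilled)


def detect_plateau(series: GasExchangeSeries,
                   thresholds=DEFAULT_THRESHOLDS,
                   alignment: str = "rolling") -> PlateauResult:
    """Detect a VO2 plateau in the incremental phase of a series.

    Raises
    ------
    UndefinedPlateauError
        If the incremental phase spans fewer than two full minutes; this is
        distinct from "criterion not fulfilled".
    """
    vo2 = series.incremental["vo2"].to_numpy(dtype=float)
    return detect_plateau_values(vo2, series.acquisition_interval,
                                 thresholds=thresholds, alignment=alignment)
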