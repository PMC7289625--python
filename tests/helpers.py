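"""Shared test utilities: independent oracles and small builders.

The oracles here deliberately re-derive results by direct enumeration so
they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vo2verify import GasExchangeSeries


def make_series(vo2, interval=15, warmup_samples=0, vco2=None, ve=None,
                fr=None, hr=None, subject_id="T1") -> GasExchangeSeries:
    """Build a series from raw channel arrays (constants where unspecified)."""
    vo2 = np.asarray(vo2, dtype=float)
    n = len(vo2) + warmup_samples
    full = np.concatenate([np.full(warmup_samples, vo2[0]), vo2])
    data = pd.DataFrame({
        "time": np.arange(n) * interval,
        "vo2": full,
        "vco2": np.asarray(vco2, dtype=float) if vco2 is not None else full * 0.9,
        "ve": np.asarray(ve, dtype=float) if ve is not None else full / 25.0,
        "fr": np.asarray(fr, dtype=float) if fr is not None else np.full(n, 30.0),
        "hr": np.asarray(hr, dtype=float) if hr is not None else np.full(n, 150.0),
        "phase": ["warmup"] * warmup_samples + ["incremental"] * len(vo2),
    })
    return GasExchangeSeries(subject_id=subject_id,
                             acquisition_interval=interval, data=data)


def brute_force_plateau(vo2, interval):
    """Enumerate every 60-s window directly; independent plateau oracle.

    Returns (peak_mean, delta_prev, delta_next) or raises ValueError when
    undefined (fewer than two full minutes, or no adjacent full minute).
    """
    vo2 = np.asarray(vo2, dtype=float)
    w = 60 // interval
    if len(vo2) < 2 * w:
        raise ValueError("undefined")
    best_i, best = None, -np.inf
    for i in range(len(vo2) - w + 1):
        m = vo2[i:i + w].mean()
        if m > best:
            best, best_i = m, i
    dprev = best - vo2[best_i - w:best_i].mean() if best_i - w >= 0 else None
    dnext = (best - vo2[best_i + w:best_i + 2 * w].mean()
             if best_i + 2 * w <= len(vo2) else None)
    if dprev is None and dnext is None:
        raise ValueError("undefined")
    return best, dprev, dnext


def brute_force_window_peak(values, interval):
    """Independent highest-60-s-mean oracle by explicit enumeration."""
    values = np.asarray(values, dtype=float)
    w = 60 // interval
    return max(values[i:i + w].mean() for i in range(len(values) - w + 1))


def concordance_auc(scores, labels):
    """Tie-corrected pair-counting concordance (Mann-Whitney) AUC oracle."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        total += (p > neg).sum() + 0.5 * (p == neg).sum()
    return total / (len(pos) * len(neg))


def random_vo2_trace(rng, interval, min_minutes=2, max_minutes=14):
    """A plausible random incremental VO2 trace: rising ramp + noise."""
    w = 60 // interval
    n = rng.integers(min_minutes * w, max_minutes * w + 1)
    ramp = np.linspace(800, rng.uniform(1500, 3500), n)
    flat_from = rng.integers(n // 2, n + 1)
    ramp[flat_from:] = ramp[min(flat_from, n - 1)]
    return ramp + rng.normal(0, rng.uniform(0, 120), n)
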