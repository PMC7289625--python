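"""Incremental treadmill protocols.

The protocol modelled here is a modified Balke test: a 5-minute warm-up,
then walking at a constant 4 km/h while the incline rises 2 % per minute
up to 12 %, after which the incline stays at 12 % and the speed increases
by 0.5 km/h per minute until exhaustion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

WARMUP_DURATION_S = 300.0
STAGE_DURATION_S = 60.0


@dataclass(frozen=True)
class Stage:
    start_time: float  # seconds from test start (warm-up begins at 0)
    speed: float  # km/h
    incline: float  # percent grade


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered stage plan for one incremental test.

    Attributes
    ----------
    warmup_duration : float
        Warm-up length in seconds; stage 1 starts when it ends.
    stage_duration : float
        Length of each incremental stage in seconds.
    stages : tuple of Stage
        Stages in temporal order, strictly increasing start times.
    """

    warmup_duration: float = WARMUP_DURATION_S
    stage_duration: float = STAGE_DURATION_S
    stages: tuple[Stage, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        starts = [s.start_time for s in self.stages]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError("stage start times must be strictly increasing")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def stage_index_at(self, t: float) -> int:
        """1-based stage index at time ``t`` (0 during warm-up)."""
        if t < self.warmup_duration:
            return 0
        k = int((t - self.warmup_duration) // self.stage_duration) + 1
        return min(k, self.n_stages)


def balke_speed(stage: int) -> float:
    """Treadmill speed (km/h) at 1-based stage index."""
    return 4.0 + 0.5 * max(0, stage - 6)


def balke_incline(stage: int) -> float:
    """Incline (% grade) at 1-based stage index: 2 % per stage, capped at 12 %."""
    return float(min(2 * stage, 12))


def build_balke_schedule(max_stages: int,
                         warmup_duration: float = WARMUP_DURATION_S,
                         stage_duration: float = STAGE_DURATION_S) -> ProtocolSchedule:
    """Build a modified Balke schedule with ``max_stages`` one-minute stages.

    Stage k (1-based) has incline min(2k, 12) % and speed 4 km/h while the
    incline is still below 12 %, then 4 + 0.5*(k - 6) km/h.

    Raises
    ------
    ConfigurationError
        If ``max_stages`` is not a positive integer.
    """
    if max_stages < 1:
        raise ConfigurationError(f"max_stages must be >= 1, got {max_stages}")
    stages = tuple(
        Stage(start_time=warmup_duration + (k - 1) * stage_duration,
              speed=balke_speed(k),
              incline=balke_incline(k))
        for k in range(1, max_stages + 1)
    )
    return ProtocolSchedule(warmup_duration=warmup_duration,
                            stage_duration=stage_duration,
                            stages=stages)
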