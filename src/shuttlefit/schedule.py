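"""Stage schedule of the 20-m shuttle run test (20mSRT / PACER).

The test is paced in one-minute stages: the first stage is run at
8.5 km/h and every subsequent stage is 0.5 km/h faster.  A "lap" is one
20-m shuttle (15-m courses are converted to the 20-m scale via a
published conversion chart, consumed here as an external table).  The
number of laps in a stage follows from the distance covered in the
stage at its speed, rounded half-up to a whole lap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import math

import numpy as np
import pandas as pd

__all__ = [
    "StageSchedule",
    "build_default_schedule",
    "laps_to_completed_stage",
    "stage_to_speed",
    "load_conversion_table",
    "convert_15m_laps",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class StageSchedule:
    """Speeds and lap counts per one-minute stage.

    Parameters
    ----------
    initial_speed : float
        Speed of stage 1 in km/h.
    increment : float
        Speed increase per stage in km/h.
    stage_duration : float
        Stage length in seconds.
    course_length : float
        Shuttle course length in metres.
    laps_per_stage : tuple of int
        Laps required to complete each stage (1-indexed conceptually;
        ``laps_per_stage[0]`` is stage 1).
    """

    initial_speed: float = 8.5
    increment: float = 0.5
    stage_duration: float = 60.0
    course_length: float = 20.0
    laps_per_stage: tuple[int, ...] = ()
    cumulative_laps: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.initial_speed <= 0 or self.increment <= 0:
            raise ValueError("initial_speed and increment must be positive")
        if self.stage_duration <= 0 or self.course_length <= 0:
            raise ValueError("stage_duration and course_length must be positive")
        if any(l < 1 for l in self.laps_per_stage):
            raise ValueError("every stage must require at least one lap")
        cum = tuple(np.cumsum(self.laps_per_stage).tolist())
        object.__setattr__(self, "cumulative_laps", cum)

    @property
    def n_stages(self) -> int:
        return len(self.laps_per_stage)

    def speed_at(self, stage: int) -> float:
        """Speed (km/h) of stage ``stage``; stage 0 is the below-scale sentinel."""
        return stage_to_speed(stage, self)


def build_default_schedule(
    initial_speed: float = 8.5,
    increment: float = 0.5,
    stage_duration: float = 60.0,
    course_length: float = 20.0,
    n_stages: int = 21,
    laps_per_stage: tuple[int, ...] | None = None,
) -> StageSchedule:
    """Build a stage schedule from protocol constants.

    Laps per stage are derived as round-half-up of
    ``stage_duration * speed / 3.6 / course_length`` (metres covered in
    the stage divided by the course length); an explicit
    ``laps_per_stage`` table overrides the derivation.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if laps_per_stage is None:
        laps = []
        for k in range(1, n_stages + 1):
            speed = initial_speed + increment * (k - 1)
            laps.append(_round_half_up(stage_duration * speed / 3.6 / course_length))
        laps_per_stage = tuple(laps)
    return StageSchedule(
        initial_speed=initial_speed,
        increment=increment,
        stage_duration=stage_duration,
        course_length=course_length,
        laps_per_stage=tuple(laps_per_stage),
    )


def laps_to_completed_stage(laps: int, schedule: StageSchedule) -> int:
    """Largest stage ``k`` with ``cumulative_laps[k] <= laps`` (0 if none)."""
    if laps < 0:
        raise ValueError("laps must be non-negative")
    cum = schedule.cumulative_laps
    # np.searchsorted on the right edge counts completed stages directly
    return int(np.searchsorted(np.asarray(cum), laps, side="right"))


def stage_to_speed(stage: int, schedule: StageSchedule) -> float:
    """Speed (km/h) at stage ``stage``.

    Stage 0 (no stage completed) maps to the below-scale sentinel one
    increment under the starting speed, keeping the speed variable
    ordinal for ROC analysis.
    """
    if stage < 0:
        raise ValueError("stage must be non-negative")
    if stage == 0:
        return schedule.initial_speed - schedule.increment
    return schedule.initial_speed + schedule.increment * (stage - 1)


def load_conversion_table(path) -> dict[int, int]:
    """Read a 15 m -> 20 m lap conversion chart (CSV: laps_15m, laps_20m)."""
    df = pd.read_csv(path)
    missing = {"laps_15m", "laps_20m"} - set(df.columns)
    if missing:
        raise ValueError(f"conversion table missing columns: {sorted(missing)}")
    table = dict(zip(df["laps_15m"].astype(int), df["laps_20m"].astype(int)))
    _check_monotone(table)
    return table


def _check_monotone(conversion: Mapping[int, int]) -> None:
    keys = sorted(conversion)
    vals = [conversion[k] for k in keys]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("conversion table must be monotone non-decreasing")


def convert_15m_laps(
    laps: int, conversion: Mapping[int, int], course_length: float = 15.0
) -> int:
    """Map a 15-m lap count onto the 20-m scale; identity for 20-m records."""
    if course_length == 20:
        return int(laps)
    if course_length != 15:
        raise ValueError("course_length must be 15 or 20")
    _check_monotone(conversion)
    try:
        return int(conversion[int(laps)])
    except KeyError:
        raise KeyError(
            f"lap count {laps} outside the conversion table range "
            f"[{min(conversion)}, {max(conversion)}]"
        ) from None
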