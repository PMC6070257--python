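"""Shuttle-run scoring: laps → stage, speed, V̇O2peak and METs.

Composes the stage schedule with the equation registry.  The
:class:`ShuttleRunScorer` transformer applies the scoring to a cohort
DataFrame; :func:`score_participant` scores a single child.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .equations import (
    Vo2Equation,
    default_equations,
    predict_vo2peak,
    vo2_to_mets,
)
from .schedule import (
    StageSchedule,
    build_default_schedule,
    convert_15m_laps,
    laps_to_completed_stage,
    stage_to_speed,
)

__all__ = ["CrfScore", "ShuttleResult", "score_participant", "ShuttleRunScorer"]


@dataclass(frozen=True)
class ShuttleResult:
    laps_completed: int
    course_length: float = 20.0

    def __post_init__(self) -> None:
        if self.laps_completed < 0:
            raise ValueError("laps_completed must be non-negative")
        if self.course_length not in (15, 20):
            raise ValueError("course_length must be 15 or 20")


@dataclass(frozen=True)
class CrfScore:
    """A child's shuttle-run performance on the three reporting metrics."""

    laps: int
    last_completed_stage: int
    speed: float
    vo2peak: Mapping[str, float]
    mets: Mapping[str, float]


def score_participant(
    result: ShuttleResult,
    age: float,
    equations: Iterable[Vo2Equation] | None = None,
    schedule: StageSchedule | None = None,
    conversion: Mapping[int, int] | None = None,
) -> CrfScore:
    """Score one child: 20-m laps, last completed stage, speed, V̇O2peak, METs."""
    if schedule is None:
        schedule = build_default_schedule()
    if equations is None:
        equations = default_equations()
    if result.course_length == 15:
        if conversion is None:
            raise ValueError("a conversion table is required for 15-m records")
        laps = convert_15m_laps(result.laps_completed, conversion, 15)
    else:
        laps = int(result.laps_completed)
    stage = laps_to_completed_stage(laps, schedule)
    speed = stage_to_speed(stage, schedule)
    vo2: dict[str, float] = {}
    for eq in equations:
        vo2[eq.id] = predict_vo2peak(age=age, equation=eq, speed=speed, laps=laps)
    mets = {k: vo2_to_mets(v) for k, v in vo2.items()}
    return CrfScore(
        laps=laps, last_completed_stage=stage, speed=speed, vo2peak=vo2, mets=mets
    )


class ShuttleRunScorer(TransformerMixin, BaseEstimator):
    """Transformer adding shuttle-run metrics to a cohort table.

    Expects columns ``laps``, ``age`` and optionally ``course_length``
    (defaults to 20 m).  ``transform`` appends ``laps_20m``, ``stage``,
    ``speed`` and, per registered equation id, ``vo2_<id>`` and
    ``mets_<id>`` columns.

    Parameters
    ----------
    schedule : StageSchedule, optional
        Protocol schedule; the standard 8.5 km/h + 0.5 km/h/min, 20-m
        schedule by default.
    equations : iterable of Vo2Equation, optional
        Prediction equations; the built-in registry by default.
    conversion : mapping, optional
        15 m -> 20 m lap conversion chart, required only when 15-m
        records are present.
    """

    def __init__(self, schedule=None, equations=None, conversion=None):
        self.schedule = schedule
        self.equations = equations
        self.conversion = conversion

    def fit(self, X: pd.DataFrame, y=None):
        if "laps" not in X.columns or "age" not in X.columns:
            raise ValueError("cohort table must have 'laps' and 'age' columns")
        self.schedule_ = self.schedule or build_default_schedule()
        self.equations_ = list(self.equations) if self.equations else default_equations()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "schedule_"):
            raise AttributeError("ShuttleRunScorer is not fitted; call fit first")
        out = X.copy()
        course = (
            out["course_length"]
            if "course_length" in out.columns
            else pd.Series(20, index=out.index)
        )
        scored = [
            score_participant(
                ShuttleResult(int(laps), float(cl)),
                float(age),
                self.equations_,
                self.schedule_,
                self.conversion,
            )
            for laps, cl, age in zip(out["laps"], course, out["age"])
        ]
        out["laps_20m"] = [s.laps for s in scored]
        out["stage"] = [s.last_completed_stage for s in scored]
        out["speed"] = [s.speed for s in scored]
        for eq in self.equations_:
            out[f"vo2_{eq.id}"] = [s.vo2peak[eq.id] for s in scored]
            out[f"mets_{eq.id}"] = [s.mets[eq.id] for s in scored]
        return out
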