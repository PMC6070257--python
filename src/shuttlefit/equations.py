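"""V̇O2peak prediction equations for the 20-m shuttle run.

Two families of equations are shipped that need no anthropometry:

* the Léger speed-and-age equation for 8–19-year-olds,
  ``31.025 + 3.238·X − 3.248·A + 0.1536·A·X`` with X the running speed
  (km/h) at the last completed stage and A the age in whole years;
* a FitnessGram-style laps-and-age equation,
  ``45.619 + 0.353·laps − 1.121·age``.

Coefficient sets are data, not code: they live in a small registry
(:data:`DEFAULT_REGISTRY` or a user YAML file) with per-equation id,
predictor kind, coefficient map and valid age range, so alternative
transcriptions can be swapped in without touching the scoring code.
METs are derived by dividing V̇O2peak by 3.5 mL·kg⁻¹·min⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "Vo2Equation",
    "AgeRangeWarning",
    "DEFAULT_REGISTRY",
    "default_equations",
    "load_equation_registry",
    "predict_vo2peak",
    "vo2_to_mets",
]

ML_PER_KG_MIN_PER_MET = 3.5


class AgeRangeWarning(UserWarning):
    """Age outside an equation's validated range."""


@dataclass(frozen=True)
class Vo2Equation:
    """A linear V̇O2peak prediction equation.

    predictor_kind is ``"speed_age"`` (terms: intercept, speed, age,
    speed_age interaction) or ``"laps_age"`` (terms: intercept, laps,
    age).  Ages outside ``valid_age_range`` warn by default and raise
    when ``strict_age=True`` is passed to :func:`predict_vo2peak`.
    """

    id: str
    predictor_kind: str
    coefficients: Mapping[str, float]
    valid_age_range: tuple[float, float] = (8.0, 19.0)
    note: str = ""

    def __post_init__(self) -> None:
        if self.predictor_kind not in ("speed_age", "laps_age"):
            raise ValueError(f"unknown predictor_kind {self.predictor_kind!r}")
        if not self.coefficients:
            raise ValueError("coefficients must be non-empty")


# Default coefficient transcriptions; provenance noted per set.  Verify
# against the primary sources before scientific use.
DEFAULT_REGISTRY: dict[str, Vo2Equation] = {
    "leger": Vo2Equation(
        id="leger",
        predictor_kind="speed_age",
        coefficients={
            "intercept": 31.025,
            "speed": 3.238,
            "age": -3.248,
            "speed_age": 0.1536,
        },
        valid_age_range=(8.0, 19.0),
        note="Léger child/adolescent equation; speed in km/h, age in years.",
    ),
    "fitnessgram": Vo2Equation(
        id="fitnessgram",
        predictor_kind="laps_age",
        coefficients={"intercept": 45.619, "laps": 0.353, "age": -1.121},
        valid_age_range=(8.0, 18.0),
        note=(
            "FitnessGram-style laps/age transcription; flagged for "
            "verification against the primary source."
        ),
    ),
}


def default_equations() -> list[Vo2Equation]:
    return list(DEFAULT_REGISTRY.values())


def load_equation_registry(path) -> dict[str, Vo2Equation]:
    """Load equations from a YAML file keyed by equation id."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for eq_id, entry in raw.items():
        registry[eq_id] = Vo2Equation(
            id=eq_id,
            predictor_kind=entry["predictor_kind"],
            coefficients={k: float(v) for k, v in entry["coefficients"].items()},
            valid_age_range=tuple(entry.get("valid_age_range", (8.0, 19.0))),
            note=entry.get("note", ""),
        )
    return registry


def predict_vo2peak(
    *,
    age: float,
    equation: Vo2Equation,
    speed: float | None = None,
    laps: float | None = None,
    strict_age: bool = False,
) -> float:
    """Evaluate a prediction equation at one child's inputs.

    Exactly the predictor the equation declares is required: ``speed``
    (km/h at the last completed stage) for ``speed_age`` equations,
    ``laps`` for ``laps_age`` equations.
    """
    lo, hi = equation.valid_age_range
    if not (lo <= age <= hi):
        msg = f"age {age} outside valid range [{lo}, {hi}] for equation {equation.id!r}"
        if strict_age:
            raise ValueError(msg)
        warnings.warn(msg, AgeRangeWarning, stacklevel=2)
    c = equation.coefficients
    if equation.predictor_kind == "speed_age":
        if speed is None:
            raise ValueError(f"equation {equation.id!r} requires a speed predictor")
        return (
            c.get("intercept", 0.0)
            + c.get("speed", 0.0) * speed
            + c.get("age", 0.0) * age
            + c.get("speed_age", 0.0) * speed * age
        )
    if laps is None:
        raise ValueError(f"equation {equation.id!r} requires a laps predictor")
    return c.get("intercept", 0.0) + c.get("laps", 0.0) * laps + c.get("age", 0.0) * age


def vo2_to_mets(vo2peak: float) -> float:
    """METs from V̇O2peak (mL·kg⁻¹·min⁻¹ divided by 3.5)."""
    if vo2peak < 0:
        raise ValueError("vo2peak must be non-negative")
    return vo2peak / ML_PER_KG_MIN_PER_MET
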