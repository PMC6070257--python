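"""Anthropometry: duplicate-measure consolidation, BMI, z-scores, obesity labels.

Field protocol: height, mass and waist are taken twice and the two
readings averaged; when they differ by more than a tolerance (0.5 cm or
0.5 kg) a third reading is taken and the closest two of the three are
averaged.  BMI and waist circumference are standardised to age- and
sex-specific z-scores — against an external LMS growth reference where
one exists (BMI), or by internal empirical standardisation within
(sex, age) groups (waist, for which no reference cut-points exist at
these ages).  Obesity is a z-score exceeding +2 SD; the combined label
requires obesity by BMI and waist simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RepeatMeasure",
    "ObesityLabels",
    "consolidate_repeats",
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "load_lms_table",
    "lookup_lms",
    "empirical_group_zscore",
    "classify_obesity",
    "EmpiricalZScorer",
    "LmsZScorer",
    "ObesityLabeler",
]

_L_EPS = 1e-7


class IncompleteMeasurementError(ValueError):
    """Two discordant readings with no third to adjudicate."""


class DegenerateGroupError(ValueError):
    """A standardisation group with <2 members or zero dispersion."""


@dataclass(frozen=True)
class RepeatMeasure:
    readings: tuple[float, ...]
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if not 2 <= len(self.readings) <= 3:
            raise ValueError("expected 2 or 3 readings")
        if any(r <= 0 for r in self.readings):
            raise ValueError("readings must be positive")


@dataclass(frozen=True)
class ObesityLabels:
    bmi_obese: bool
    wc_obese: bool
    combined_obese: bool


def consolidate_repeats(measure: RepeatMeasure) -> float:
    """Average of two concordant readings, else mean of the closest pair of three.

    A closest-pair tie (three readings with equal pairwise gaps) resolves
    to the pair containing the median reading, which is deterministic and
    coincides with every other choice when the gaps are symmetric.
    """
    r = sorted(measure.readings)
    if len(r) == 2:
        if abs(r[1] - r[0]) > measure.tolerance:
            raise IncompleteMeasurementError(
                f"readings {measure.readings} differ by more than "
                f"{measure.tolerance} and no third reading was taken"
            )
        return (r[0] + r[1]) / 2.0
    # sorted triple: the closest pair is one of the two adjacent pairs;
    # ties go to the lower-gap-with-median pair (r[0],r[1]) vs (r[1],r[2])
    if (r[1] - r[0]) <= (r[2] - r[1]):
        return (r[0] + r[1]) / 2.0
    return (r[1] + r[2]) / 2.0


def compute_bmi(mass: float, height_cm: float) -> float:
    """Body-mass index (kg/m²) from mass (kg) and height (cm)."""
    if mass <= 0 or height_cm <= 0:
        raise ValueError("mass and height must be positive")
    return mass / (height_cm / 100.0) ** 2


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS z-score: ((x/M)^L − 1)/(L·S), with the log limit at L = 0."""
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError("x, M and S must be positive")
    if abs(L) < _L_EPS:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value whose LMS z-score is ``z`` (inverse of lms_zscore)."""
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be positive")
    if abs(L) < _L_EPS:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValueError("z outside the representable range for these L, S")
    return M * base ** (1.0 / L)


def load_lms_table(path) -> pd.DataFrame:
    """Read an LMS reference (CSV with columns sex, age, L, M, S)."""
    df = pd.read_csv(path)
    missing = {"sex", "age", "L", "M", "S"} - set(df.columns)
    if missing:
        raise ValueError(f"LMS table missing columns: {sorted(missing)}")
    if (df["M"] <= 0).any() or (df["S"] <= 0).any():
        raise ValueError("M and S must be positive in every row")
    if df.duplicated(["sex", "age"]).any():
        raise ValueError("duplicate (sex, age) keys in LMS table")
    return df.sort_values(["sex", "age"]).reset_index(drop=True)


def lookup_lms(table: pd.DataFrame, sex: str, age: float) -> tuple[float, float, float]:
    """(L, M, S) for a child of ``age`` completed years.

    Monthly grids (detected when the age column exceeds 30) are entered
    at the mid-year point ``age*12 + 6``; otherwise the age is matched
    to the nearest grid point.  Ages outside the grid raise.
    """
    rows = table[table["sex"] == sex]
    if rows.empty:
        raise KeyError(f"sex {sex!r} not present in LMS table")
    grid = rows["age"].to_numpy(dtype=float)
    key = age * 12.0 + 6.0 if grid.max() > 30 else float(age)
    lo, hi = grid.min(), grid.max()
    if key < lo - 0.5 or key > hi + 0.5:
        raise ValueError(f"age {age} outside LMS grid [{lo}, {hi}]")
    row = rows.iloc[int(np.argmin(np.abs(grid - key)))]
    return float(row["L"]), float(row["M"]), float(row["S"])


def empirical_group_zscore(
    values: Sequence[float], group_keys: Sequence[tuple]
) -> np.ndarray:
    """Standardise within (sex, age) groups: z = (x − mean) / sample SD."""
    s = pd.Series(np.asarray(values, dtype=float))
    keys = pd.Series(list(group_keys))
    out = np.empty(len(s))
    for key, idx in s.groupby(keys).groups.items():
        grp = s.loc[idx]
        if len(grp) < 2 or grp.std(ddof=1) == 0:
            raise DegenerateGroupError(
                f"group {key!r} has size {len(grp)} or zero dispersion"
            )
        out[idx] = (grp - grp.mean()) / grp.std(ddof=1)
    return out


def classify_obesity(
    bmi_z: float, wc_z: float, threshold: float = 2.0, strict: bool = True
) -> ObesityLabels:
    """Obesity labels from z-scores; strict '>' by default (configurable to '>=')."""
    if not (np.isfinite(bmi_z) and np.isfinite(wc_z)):
        raise ValueError("z-scores must be finite")
    if strict:
        bmi_ob, wc_ob = bmi_z > threshold, wc_z > threshold
    else:
        bmi_ob, wc_ob = bmi_z >= threshold, wc_z >= threshold
    return ObesityLabels(bool(bmi_ob), bool(wc_ob), bool(bmi_ob and wc_ob))


class EmpiricalZScorer(TransformerMixin, BaseEstimator):
    """Internal standardisation of columns within (sex, age) groups.

    fit() learns per-group means and sample SDs; transform() appends
    ``<col>_z`` columns.  Adding a constant within a group leaves the
    z-scores unchanged, and each fitted group has mean 0 / SD 1 on the
    training data.
    """

    def __init__(self, columns=("bmi", "waist"), by=("sex", "age")):
        self.columns = columns
        self.by = by

    def fit(self, X: pd.DataFrame, y=None):
        by = list(self.by)
        self.stats_ = {}
        for col in self.columns:
            g = X.groupby(by)[col]
            mean, sd, n = g.mean(), g.std(ddof=1), g.size()
            if (n < 2).any() or (sd == 0).any() or sd.isna().any():
                bad = sd.index[(n < 2) | (sd == 0) | sd.isna()].tolist()
                raise DegenerateGroupError(f"degenerate groups for {col!r}: {bad}")
            self.stats_[col] = pd.DataFrame({"mean": mean, "sd": sd})
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        by = list(self.by)
        for col in self.columns:
            stats = self.stats_[col]
            keys = pd.MultiIndex.from_frame(out[by])
            mean = stats["mean"].reindex(keys).to_numpy()
            sd = stats["sd"].reindex(keys).to_numpy()
            out[f"{col}_z"] = (out[col].to_numpy() - mean) / sd
        return out


class LmsZScorer(TransformerMixin, BaseEstimator):
    """LMS-reference z-scores for a measurement column.

    Parameters
    ----------
    table : DataFrame
        LMS reference with columns sex, age, L, M, S.
    column : str
        Measurement column to standardise (e.g. ``"bmi"``).
    out_column : str, optional
        Defaults to ``"<column>_z"``.
    restrict_extreme : bool
        When True, applies the WHO-style restricted application of the
        reference for |z| > 3 (values beyond ±3 are re-expressed on a
        linear scale anchored at the ±3 reference values). Off by default.
    """

    def __init__(self, table=None, column="bmi", out_column=None,
                 restrict_extreme=False):
        self.table = table
        self.column = column
        self.out_column = out_column
        self.restrict_extreme = restrict_extreme

    def fit(self, X: pd.DataFrame, y=None):
        if self.table is None:
            raise ValueError("an LMS reference table is required")
        self.table_ = self.table
        self.n_features_in_ = X.shape[1]
        return self

    def _one(self, x, sex, age):
        L, M, S = lookup_lms(self.table_, sex, age)
        z = lms_zscore(x, L, M, S)
        if self.restrict_extreme and abs(z) > 3:
            sd3 = lms_inverse(3.0 if z > 0 else -3.0, L, M, S)
            sd2 = lms_inverse(2.0 if z > 0 else -2.0, L, M, S)
            z = math.copysign(3.0 + (abs(x - sd3)) / abs(sd3 - sd2), z)
        return z

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        dst = self.out_column or f"{self.column}_z"
        out[dst] = [
            self._one(x, s, a)
            for x, s, a in zip(out[self.column], out["sex"], out["age"])
        ]
        return out


class ObesityLabeler(TransformerMixin, BaseEstimator):
    """Adds bmi_obese / wc_obese / combined_obese from z-score columns."""

    def __init__(self, threshold=2.0, strict=True,
                 bmi_col="bmi_z", wc_col="wc_z"):
        self.threshold = threshold
        self.strict = strict
        self.bmi_col = bmi_col
        self.wc_col = wc_col

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        bz, wz = out[self.bmi_col], out[self.wc_col]
        if not (np.isfinite(bz).all() and np.isfinite(wz).all()):
            raise ValueError("z-score columns must be finite")
        if self.strict:
            out["bmi_obese"] = bz > self.threshold
            out["wc_obese"] = wz > self.threshold
        else:
            out["bmi_obese"] = bz >= self.threshold
            out["wc_obese"] = wz >= self.threshold
        out["combined_obese"] = out["bmi_obese"] & out["wc_obese"]
        return out
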