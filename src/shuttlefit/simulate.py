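"""Synthetic cohorts with the statistical structure the analysis assumes.

Each child gets a latent (fitness, adiposity) draw from a trivariate
Gaussian: one fitness factor and two adiposity factors (BMI-scale and
waist-scale) that correlate 0.8 with each other and negatively
(default −0.40) with fitness.  Laps are the fitness factor rescaled to
the sex-specific lap mean/SD, truncated at zero and rounded to whole
laps; BMI and waist z-scores are the adiposity factors shifted so the
+2 SD tail hits the target prevalences (15.1% by BMI, 5.0% by waist).
Covariates (screen time, MVPA, study site) are drawn independently of
the latents.

All randomness flows through one fixed-width block of uniform draws
per child from a counter-based Philox stream keyed by the seed, so a
child's draws do not change when the cohort is enlarged or rows are
reordered downstream.

Closed-form helpers (:func:`binormal_auc`,
:func:`binormal_youden_cutpoint`, :func:`solve_latent_shift`,
:func:`conditional_latent_moments`) serve as analytic oracles for
parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "CohortConfig",
    "solve_latent_shift",
    "generate_cohort",
    "binormal_auc",
    "binormal_youden_cutpoint",
    "conditional_latent_moments",
    "synthetic_lms_reference",
    "synthetic_conversion_chart",
]

_DRAWS_PER_CHILD = 10  # fixed block width of the per-child uniform stream


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters; defaults emulate the study cohort's structure."""

    n: int = 8740
    age_probs: tuple[float, ...] = (0.112, 0.197, 0.254, 0.326, 0.111)  # ages 8..12
    sex_ratio: float = 0.5  # proportion boys
    laps_mean_sd: dict = field(
        default_factory=lambda: {"M": (26.0, 16.0), "F": (21.0, 11.0)}
    )
    latent_corr_fit_adiposity: float = -0.40
    corr_bmi_wc: float = 0.8
    target_prev: dict = field(default_factory=lambda: {"bmi": 0.151, "wc": 0.050})
    zscore_sd: float = 1.0
    threshold: float = 2.0
    screen_mean_sd: dict = field(
        default_factory=lambda: {"M": (2.7, 2.1), "F": (2.2, 1.7)}
    )
    mvpa_mean_sd: dict = field(
        default_factory=lambda: {"M": (302.5, 118.4), "F": (293.5, 111.2)}
    )
    n_sites: int = 11
    with_measurements: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.age_probs) - 1.0) > 1e-9:
            raise ValueError("age_probs must sum to 1")
        if not -1 < self.latent_corr_fit_adiposity <= 0:
            raise ValueError("latent fitness-adiposity correlation must be in (-1, 0]")
        if not 0 < self.corr_bmi_wc < 1:
            raise ValueError("corr_bmi_wc must be in (0, 1)")
        rho, c = self.latent_corr_fit_adiposity, self.corr_bmi_wc
        corr = np.array([[1, rho, rho], [rho, 1, c], [rho, c, 1]])
        if np.linalg.eigvalsh(corr).min() < -1e-12:
            raise ValueError("latent correlation structure is not positive semidefinite")


def solve_latent_shift(target_prev: float, threshold: float = 2.0, sd: float = 1.0) -> float:
    """Latent mean making P(N(mean, sd) > threshold) equal target_prev."""
    if not 0 < target_prev < 1:
        raise ValueError("target_prev must be strictly between 0 and 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    return threshold - sd * norm.ppf(1.0 - target_prev)


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """AUC of two normal score classes under 'lower score => positive'."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(norm.cdf((mean_neg - mean_pos) / math.hypot(sd_pos, sd_neg)))


def binormal_youden_cutpoint(
    mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float
) -> float:
    """Population Youden-optimal threshold for binormal classes.

    With equal variances this is the midpoint of the class means; in
    general it is the density crossing between the means, found
    numerically.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    if abs(sd_pos - sd_neg) < 1e-12:
        return (mean_pos + mean_neg) / 2.0
    f = lambda c: norm.pdf(c, mean_pos, sd_pos) - norm.pdf(c, mean_neg, sd_neg)
    lo, hi = min(mean_pos, mean_neg), max(mean_pos, mean_neg)
    return float(brentq(f, lo, hi))


def conditional_latent_moments(config: CohortConfig, sex: str, outcome: str = "bmi"):
    """Analytic (mean, sd) of the pre-truncation lap scale by obesity class.

    The adiposity factor A is standard normal; obesity is A > q with
    q = threshold − shift.  Fitness F = ρ·A + sqrt(1−ρ²)·ε, and laps
    (before truncation/rounding) are ``lap_mean + lap_sd · F``.
    Returns ((mean_pos, sd_pos), (mean_neg, sd_neg)) on the lap scale.
    """
    rho = config.latent_corr_fit_adiposity
    p = config.target_prev[outcome]
    q = norm.ppf(1.0 - p)
    lam_pos = norm.pdf(q) / p
    lam_neg = -norm.pdf(q) / (1.0 - p)
    var_pos = 1.0 + q * lam_pos - lam_pos**2
    var_neg = 1.0 + q * lam_neg - lam_neg**2
    mu, sd = config.laps_mean_sd[sex]

    def lap_moments(lam, var):
        mean_f = rho * lam
        var_f = rho**2 * var + (1.0 - rho**2)
        return mu + sd * mean_f, sd * math.sqrt(var_f)

    return lap_moments(lam_pos, var_pos), lap_moments(lam_neg, var_neg)


def synthetic_lms_reference() -> pd.DataFrame:
    """SYNTHETIC LMS growth-reference table for BMI and waist, ages 8–12.

    Plausible smooth curves fabricated for testing only — not any
    published reference.  Columns: measure, sex, age, L, M, S.
    """
    rows = []
    for sex, bmi_off, wc_off in (("M", 0.0, 0.5), ("F", 0.1, 0.0)):
        for age in range(8, 13):
            t = age - 8
            rows.append(
                ("bmi", sex, age, -2.2 + 0.05 * t, 15.8 + 0.55 * t + bmi_off, 0.11 + 0.006 * t)
            )
            rows.append(
                ("waist", sex, age, 0.8, 58.0 + 2.6 * t + wc_off, 0.075 + 0.004 * t)
            )
    return pd.DataFrame(rows, columns=["measure", "sex", "age", "L", "M", "S"])


def synthetic_conversion_chart(max_laps: int = 120) -> dict[int, int]:
    """SYNTHETIC monotone 15 m -> 20 m lap conversion (testing fixture only)."""
    return {k: int(round(k * 0.93)) for k in range(0, max_laps + 1)}


def _uniform_block(seed: int, n: int) -> np.ndarray:
    """(n, width) uniforms from a Philox counter stream; row i is stable in n."""
    rng = np.random.Generator(np.random.Philox(key=seed))
    return rng.random((n, _DRAWS_PER_CHILD))


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort; returns (records, manifest with achieved summaries)."""
    n = config.n
    u = _uniform_block(config.seed, n)
    # guard against 0/1 endpoints before the normal quantile transform
    eps = np.finfo(float).tiny
    z_raw = norm.ppf(np.clip(u[:, 2:7], eps, 1 - eps))

    ages = 8 + np.searchsorted(np.cumsum(config.age_probs), u[:, 0], side="right")
    ages = np.minimum(ages, 12)
    sex = np.where(u[:, 1] < config.sex_ratio, "M", "F")

    rho, c = config.latent_corr_fit_adiposity, config.corr_bmi_wc
    corr = np.array([[1, rho, rho], [rho, 1, c], [rho, c, 1]])
    chol = np.linalg.cholesky(corr)
    latents = z_raw[:, :3] @ chol.T  # columns: fitness, adiposity_bmi, adiposity_wc
    fitness, adi_bmi, adi_wc = latents.T

    lap_mean = np.array([config.laps_mean_sd[s][0] for s in sex])
    lap_sd = np.array([config.laps_mean_sd[s][1] for s in sex])
    laps = np.maximum(0, np.round(lap_mean + lap_sd * fitness)).astype(int)

    shift_bmi = solve_latent_shift(
        config.target_prev["bmi"], config.threshold, config.zscore_sd
    )
    shift_wc = solve_latent_shift(
        config.target_prev["wc"], config.threshold, config.zscore_sd
    )
    bmi_z = shift_bmi + config.zscore_sd * adi_bmi
    wc_z = shift_wc + config.zscore_sd * adi_wc

    st_mean = np.array([config.screen_mean_sd[s][0] for s in sex])
    st_sd = np.array([config.screen_mean_sd[s][1] for s in sex])
    screen = np.maximum(0.0, st_mean + st_sd * z_raw[:, 3])
    mv_mean = np.array([config.mvpa_mean_sd[s][0] for s in sex])
    mv_sd = np.array([config.mvpa_mean_sd[s][1] for s in sex])
    mvpa = np.maximum(0.0, mv_mean + mv_sd * z_raw[:, 4])
    site = (u[:, 7] * config.n_sites).astype(int) + 1

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": ages,
            "sex": sex,
            "course_length": 20,
            "laps": laps,
            "bmi_z": bmi_z,
            "wc_z": wc_z,
            "screen_time": screen,
            "mvpa": mvpa,
            "site": [f"site_{s:02d}" for s in site],
        }
    )

    if config.with_measurements:
        df = _attach_measurements(df, u)

    threshold = config.threshold
    bmi_ob = bmi_z > threshold
    wc_ob = wc_z > threshold
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "achieved": {
            "n": int(n),
            "prev_bmi": float(bmi_ob.mean()),
            "prev_wc": float(wc_ob.mean()),
            "prev_combined": float((bmi_ob & wc_ob).mean()),
            "laps_mean_by_sex": {
                s: float(df.loc[df.sex == s, "laps"].mean()) for s in ("M", "F")
            },
            "laps_sd_by_sex": {
                s: float(df.loc[df.sex == s, "laps"].std(ddof=1)) for s in ("M", "F")
            },
            "corr_laps_bmi_z": float(np.corrcoef(laps, bmi_z)[0, 1]),
        },
    }
    return df, manifest


def _attach_measurements(df: pd.DataFrame, u: np.ndarray) -> pd.DataFrame:
    """Inverse-LMS route: raw height/mass/waist consistent with the drawn z."""
    from .anthro import lms_inverse, lookup_lms

    ref = synthetic_lms_reference()
    bmi_ref = ref[ref.measure == "bmi"]
    wc_ref = ref[ref.measure == "waist"]
    out = df.copy()
    eps = np.finfo(float).tiny
    height_noise = norm.ppf(np.clip(u[:, 8], eps, 1 - eps))
    heights, masses, waists = [], [], []
    for i, (sex, age, bz, wz) in enumerate(
        zip(out["sex"], out["age"], out["bmi_z"], out["wc_z"])
    ):
        bmi = lms_inverse(bz, *lookup_lms(bmi_ref, sex, age))
        waist = lms_inverse(wz, *lookup_lms(wc_ref, sex, age))
        height = 120.0 + 6.0 * (age - 8) + 6.5 * height_noise[i]
        heights.append(height)
        masses.append(bmi * (height / 100.0) ** 2)
        waists.append(waist)
    out["height"] = heights
    out["mass"] = masses
    out["waist"] = waists
    return out
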