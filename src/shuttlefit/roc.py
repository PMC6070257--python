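"""ROC cut-point machinery for low-fitness screening.

Orientation is fixed throughout: a LOW score (fewer laps, slower last
stage, lower predicted V̇O2peak) calls the test POSITIVE, so a child is
test-positive when ``score <= cutpoint``.  Candidate cut-points are the
observed score values (laps, stage speeds and equation outputs at
integer ages are discrete); no interpolation between values.

The area under the empirical ROC curve is computed by the trapezoid
rule and equals the Mann–Whitney pair statistic
``mean over (pos, neg) pairs of [1 if pos < neg, 1/2 if tied]``
exactly, ties included.  Standard errors for a single AUC and the
covariance of two paired AUCs use the DeLong placement decomposition
(midrank formulation), which feeds a two-sided normal z-test of the
difference between two prediction equations scored on the same
children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocCurve",
    "AucEstimate",
    "DiagnosticTable",
    "DeLongComparison",
    "build_roc",
    "auc",
    "mann_whitney_auc",
    "delong_variance",
    "compare_aucs_delong",
    "optimal_cutpoint",
    "diagnostic_properties",
    "clopper_pearson_ci",
    "effect_band",
    "CutpointClassifier",
]


class DegenerateOutcomeError(ValueError):
    """ROC computation requires at least one case per class."""


def _validate(scores, labels, min_per_class=1):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    m, n = int(labels.sum()), int((~labels).sum())
    if m < min_per_class or n < min_per_class:
        raise DegenerateOutcomeError(
            f"need >= {min_per_class} per class, got {m} positives / {n} negatives"
        )
    return scores, labels


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: per observed threshold, sens/spec of 'score <= c'."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.spec

    def points(self) -> np.ndarray:
        """(1-spec, sens) pairs with the (0,0) and (1,1) endpoints."""
        fpr = np.concatenate(([0.0], self.fpr, [1.0]))
        tpr = np.concatenate(([0.0], self.sens, [1.0]))
        return np.column_stack([fpr, tpr])


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci95: tuple[float, float]
    effect_band: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DiagnosticTable:
    """Diagnostic properties of 'score <= cutpoint' as a positive call."""

    cutpoint: float
    tp: int
    fp: int
    fn: int
    tn: int
    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    prevalence: float


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    difference: float
    se_diff: float
    z: float
    p: float


def build_roc(scores, labels) -> RocCurve:
    """Empirical ROC curve over the observed score values."""
    scores, labels = _validate(scores, labels)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    thr = np.unique(scores)
    sens = np.searchsorted(pos, thr, side="right") / pos.size
    spec = 1.0 - np.searchsorted(neg, thr, side="right") / neg.size
    return RocCurve(thresholds=thr, sens=sens, spec=spec)


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the mean pair statistic P(pos < neg) + P(pos = neg)/2.

    Brute-force O(m·n) counting; serves as the defining identity that
    the trapezoid AUC must reproduce.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels][:, None]
    neg = scores[~labels][None, :]
    return float(np.mean((pos < neg) + 0.5 * (pos == neg)))


def effect_band(auc_value: float) -> str:
    """Discrimination band on the reported (2 dp) AUC scale.

    0.55–0.62 small, 0.63–0.71 medium, >0.71 large; below 0.55 none.
    """
    r = round(auc_value, 2)
    if r < 0.55:
        return "none"
    if r <= 0.62:
        return "small"
    if r <= 0.71:
        return "medium"
    return "large"


def _placements(scores, labels):
    """DeLong placement values under the low-score-positive orientation.

    Returns (auc, v10, v01): v10 are per-positive placements, v01
    per-negative, computed from midranks so ties contribute 1/2.
    """
    # negate so that "higher transformed score => positive" matches the
    # textbook formulation
    x = -np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    pos, neg = x[labels], x[~labels]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc_hat = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc_hat, v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong standard error of the AUC (needs >= 2 per class)."""
    scores, labels = _validate(scores, labels, min_per_class=2)
    _, v10, v01 = _placements(scores, labels)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return float(math.sqrt(max(var, 0.0)))


def auc(scores, labels) -> AucEstimate:
    """Trapezoid AUC over the empirical curve, DeLong SE, 95% CI and band."""
    scores, labels = _validate(scores, labels)
    curve = build_roc(scores, labels)
    pts = curve.points()
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    m, n = int(labels.sum()), int((~labels).sum())
    se = delong_variance(scores, labels) if min(m, n) >= 2 else float("nan")
    if np.isnan(se):
        ci = (float("nan"), float("nan"))
    else:
        half = norm.ppf(0.975) * se
        ci = (max(0.0, area - half), min(1.0, area + half))
    return AucEstimate(area, se, ci, effect_band(area), m, n)


def compare_aucs_delong(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong z-test of two AUCs computed on the same children.

    The covariance of the paired placement values accounts for the
    correlation between the two scores; the p-value is two-sided
    normal.  Rank-identical scores (any strictly monotone transform)
    give difference exactly 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have the same length")
    a, labels = _validate(a, labels, min_per_class=2)
    auc_a, v10_a, v01_a = _placements(a, labels)
    auc_b, v10_b, v01_b = _placements(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    se_diff = math.sqrt(max(float(var_diff), 0.0))
    diff = float(auc_a - auc_b)
    if se_diff == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(float("inf"), diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / se_diff
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongComparison(float(auc_a), float(auc_b), diff, se_diff, z, p)


def _confusion_grid(scores, labels):
    """Per observed threshold: tp, fp counts for 'score <= c'."""
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    thr = np.unique(scores)
    tp = np.searchsorted(pos, thr, side="right")
    fp = np.searchsorted(neg, thr, side="right")
    return thr, tp, fp, pos.size, neg.size


def optimal_cutpoint(scores, labels, criterion: str = "youden"):
    """Optimal cut-point over observed score values.

    criterion="youden" maximises sens + spec − 1; criterion="min_errors"
    minimises FP + FN (the fewest false positives and negatives).  Ties
    break toward higher sensitivity, then toward the lower threshold.
    Returns (cutpoint, DiagnosticTable).
    """
    scores, labels = _validate(scores, labels)
    thr, tp, fp, m, n = _confusion_grid(scores, labels)
    sens = tp / m
    spec = 1.0 - fp / n
    if criterion == "youden":
        objective = sens + spec - 1.0
    elif criterion == "min_errors":
        objective = -((m - tp) + fp)  # maximise the negated error count
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = objective == objective.max()
    idx = np.flatnonzero(best)
    # tie-break: highest sensitivity, then lowest threshold
    idx = idx[sens[idx] == sens[idx].max()]
    c = float(thr[idx[0]])
    return c, diagnostic_properties(scores, labels, c)


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def diagnostic_properties(
    scores, labels, cutpoint: float, prevalence: float | None = None
) -> DiagnosticTable:
    """Full diagnostic table at a cut-point ('score <= cutpoint' positive).

    Sensitivity and specificity carry exact Clopper–Pearson 95% CIs.
    PPV/NPV come from the observed 2×2, or from a supplied prevalence
    via the Bayes identities.  LR+ is +inf when specificity is 1; LR−
    is undefined (NaN) when specificity is 0.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    tp = int((pos <= cutpoint).sum())
    fp = int((neg <= cutpoint).sum())
    fn = pos.size - tp
    tn = neg.size - fp
    sens = tp / pos.size
    spec = tn / neg.size
    p = prevalence if prevalence is not None else pos.size / scores.size
    denom_ppv = sens * p + (1 - spec) * (1 - p)
    denom_npv = (1 - sens) * p + spec * (1 - p)
    ppv = sens * p / denom_ppv if denom_ppv > 0 else float("nan")
    npv = spec * (1 - p) / denom_npv if denom_npv > 0 else float("nan")
    lr_pos = sens / (1 - spec) if spec < 1 else (float("inf") if sens > 0 else float("nan"))
    lr_neg = (1 - sens) / spec if spec > 0 else float("nan")
    return DiagnosticTable(
        cutpoint=float(cutpoint),
        tp=tp, fp=fp, fn=fn, tn=tn,
        sens=sens,
        sens_ci=clopper_pearson_ci(tp, pos.size),
        spec=spec,
        spec_ci=clopper_pearson_ci(tn, neg.size),
        ppv=ppv, npv=npv, lr_pos=lr_pos, lr_neg=lr_neg,
        prevalence=float(p),
    )


class CutpointClassifier(ClassifierMixin, BaseEstimator):
    """Threshold screener: fit an optimal cut-point, predict 'low score'.

    A one-feature classifier in the scikit-learn mould.  ``fit`` takes
    the fitness scores (lower = less fit) and boolean obesity labels,
    derives the empirical ROC, the AUC with its DeLong standard error
    and discrimination band, and selects the optimal cut-point;
    ``predict`` flags scores at or below the fitted cut-point.

    Parameters
    ----------
    criterion : {"youden", "min_errors"}
        Cut-point optimality rule: maximise Youden's J (default, the
        convention behind published cut-point tables) or minimise the
        raw count of false positives plus false negatives.
    prevalence : float, optional
        External prevalence for PPV/NPV; the observed one by default.

    Attributes
    ----------
    cutpoint_ : float
        Selected threshold (a score <= cutpoint_ is called positive).
    auc_ : AucEstimate
        AUC, DeLong SE, 95% CI and effect band.
    diagnostics_ : DiagnosticTable
        Sens/spec (with exact CIs), PPV, NPV, LR+ and LR− at cutpoint_.
    roc_ : RocCurve
        The underlying empirical curve.
    """

    def __init__(self, criterion: str = "youden", prevalence: float | None = None):
        self.criterion = criterion
        self.prevalence = prevalence

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float)
        if scores.ndim == 2:
            if scores.shape[1] != 1:
                raise ValueError("CutpointClassifier expects a single score column")
            scores = scores[:, 0]
        scores, labels = _validate(scores, y)
        self.classes_ = np.array([False, True])
        self.roc_ = build_roc(scores, labels)
        self.auc_ = auc(scores, labels)
        self.cutpoint_, self.diagnostics_ = optimal_cutpoint(
            scores, labels, criterion=self.criterion
        )
        if self.prevalence is not None:
            self.diagnostics_ = diagnostic_properties(
                scores, labels, self.cutpoint_, prevalence=self.prevalence
            )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "cutpoint_"):
            raise AttributeError("CutpointClassifier is not fitted")
        scores = np.asarray(X, dtype=float)
        if scores.ndim == 2:
            scores = scores[:, 0]
        return scores <= self.cutpoint_

    def decision_function(self, X):
        scores = np.asarray(X, dtype=float)
        if scores.ndim == 2:
            scores = scores[:, 0]
        return self.cutpoint_ - scores
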