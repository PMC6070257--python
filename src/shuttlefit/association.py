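"""Odds ratios and descriptive effect sizes.

Logistic regression (crude and covariate-adjusted) links a low-fitness
indicator to obesity; odds ratios are exponentiated coefficients with
Wald 95% intervals.  Effect sizes for sex comparisons follow the
descriptive-table conventions: Cohen's d for continuous variables
(unweighted root-mean pooled SD by default), Cramér's V for
categorical ones, and Pearson r for correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "LogisticFit",
    "OrEstimate",
    "SeparationError",
    "fit_logistic",
    "odds_ratio",
    "cohens_d",
    "cramers_v",
    "pearson_r",
    "LogisticOddsModel",
]


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist, no estimates reported."""


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    converged: bool
    iterations: int
    llf: float
    n_obs: int

    def __post_init__(self) -> None:
        if not self.converged:
            raise SeparationError(
                "logistic fit did not converge (possible separation); "
                "no estimates are reported"
            )


@dataclass(frozen=True)
class OrEstimate:
    term: str
    or_value: float
    ci95: tuple[float, float]
    adjusted: bool
    covariates: tuple[str, ...]


def fit_logistic(design: pd.DataFrame, outcome, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton scoring via statsmodels).

    Raises :class:`SeparationError` when the outcome is perfectly
    separated by the design (infinite MLE) rather than returning silent
    estimates, and a collinearity error on singular designs.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is singular (collinear columns)")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False) or not np.isfinite(res.bse).all():
        raise SeparationError("logistic fit did not converge")
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        converged=True,
        iterations=int(res.mle_retvals.get("iterations", 0)),
        llf=float(res.llf),
        n_obs=int(res.nobs),
    )


def odds_ratio(fit: LogisticFit, term: str, adjusted: bool | None = None) -> OrEstimate:
    """exp(beta) with Wald 95% CI exp(beta ± 1.96·SE) for one model term."""
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    zc = stats.norm.ppf(0.975)
    covs = tuple(t for t in fit.params.index if t not in ("const", term))
    return OrEstimate(
        term=term,
        or_value=float(np.exp(beta)),
        ci95=(float(np.exp(beta - zc * se)), float(np.exp(beta + zc * se))),
        adjusted=bool(covs) if adjusted is None else adjusted,
        covariates=covs,
    )


def cohens_d(mean1, sd1, mean2, sd2, n1=None, n2=None, weighted: bool = False) -> float:
    """|standardised mean difference| between two groups.

    Default pooled SD is the unweighted root-mean of the two variances
    (appropriate for near-equal groups); ``weighted=True`` uses the
    n-weighted pooled form and then requires n1, n2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if weighted:
        if n1 is None or n2 is None:
            raise ValueError("weighted pooling requires group sizes")
        pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    else:
        pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    return float(abs(mean1 - mean2) / pooled)


def cramers_v(contingency) -> float:
    """Cramér's V = sqrt(chi² / (n · (min(r, c) − 1))), no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.min() < 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin or negative count")
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    k = min(table.shape) - 1
    if k < 1:
        raise ValueError("need at least a 2x2 table")
    return float(np.sqrt(chi2 / (n * k)))


def pearson_r(x, y) -> float:
    """Product-moment correlation (requires n >= 3 and non-zero variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


class LogisticOddsModel(BaseEstimator):
    """Estimator wrapper: logistic odds ratio for an exposure, optionally adjusted.

    ``fit(X, y)`` fits outcome ~ exposure [+ covariates] on a DataFrame
    ``X`` that contains the exposure column and any covariate columns;
    fitted attributes expose the exposure odds ratio with its Wald CI.

    Parameters
    ----------
    exposure : str
        Column of X holding the (binary) exposure, e.g. a low-fitness flag.
    covariates : sequence of str, optional
        Adjustment columns (categorical columns are expanded to
        reference-coded indicators against their first level).

    Attributes
    ----------
    fit_ : LogisticFit
    or_ : OrEstimate for the exposure term.
    """

    def __init__(self, exposure: str = "low_crf", covariates: tuple[str, ...] = ()):
        self.exposure = exposure
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y):
        cols = [self.exposure, *self.covariates]
        design = pd.get_dummies(
            X[cols], columns=[c for c in self.covariates
                              if not pd.api.types.is_numeric_dtype(X[c])],
            drop_first=True, dtype=float,
        )
        self.fit_ = fit_logistic(design, y)
        self.or_ = odds_ratio(self.fit_, self.exposure,
                              adjusted=bool(self.covariates))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame):
        cols = [self.exposure, *self.covariates]
        design = pd.get_dummies(
            X[cols], columns=[c for c in self.covariates
                              if not pd.api.types.is_numeric_dtype(X[c])],
            drop_first=True, dtype=float,
        )
        design = sm.add_constant(design.astype(float), has_constant="add")
        design = design.reindex(columns=self.fit_.params.index, fill_value=0.0)
        eta = design.to_numpy() @ self.fit_.params.to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])
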