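"""Attributing spatial variation in debts/credits to land-cover change.

A Gaussian linear model regresses per-site (or per-grid-cell) delta values
on the ten directional change magnitudes (five classes x loss/gain), with
two-stage uncertainty propagation: the model is refit to many posterior
prediction sets of deltas, each fitted coefficient vector is resampled
from its sampling distribution, and the pooled values give means and 95%
intervals per term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .params import CLASSES

__all__ = [
    "DRIVER_TERMS",
    "SingleFit",
    "DriverFit",
    "fit_driver_glm",
    "propagate",
    "DriverEffectsGLM",
]

DRIVER_TERMS = ["intercept"] + [f"{c}_{d}" for c in CLASSES for d in ("loss", "gain")]


@dataclass
class SingleFit:
    params: pd.Series
    cov: pd.DataFrame
    dropped: list
    scale: float
    df_resid: float


@dataclass
class DriverFit:
    """Pooled propagation result over n_glm x n_param coefficient values."""

    terms: list
    mean: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    samples: np.ndarray  # (n_glm * n_param, n_terms)
    n_glm: int
    n_param: int
    per_set_means: np.ndarray = field(default=None)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "mean": self.mean.values,
             "ci_low": self.ci_low.values, "ci_high": self.ci_high.values}
        )

    def sign_conclusive(self) -> pd.Series:
        """Per term: +1 / -1 if the 95% interval excludes zero, else 0."""
        s = np.where(self.ci_low > 0, 1, np.where(self.ci_high < 0, -1, 0))
        return pd.Series(s, index=self.terms)


def _design(change_covariates: pd.DataFrame) -> tuple[np.ndarray, list]:
    cols = [t for t in DRIVER_TERMS if t != "intercept"]
    missing = [c for c in cols if c not in change_covariates.columns]
    if missing:
        raise KeyError(f"missing change-covariate column(s): {missing}")
    X = change_covariates[cols].to_numpy(float)
    if np.any(X < 0):
        raise ValueError("directional change covariates must be non-negative")
    return np.column_stack([np.ones(len(X)), X]), DRIVER_TERMS.copy()


def fit_driver_glm(
    delta_values: np.ndarray, change_covariates: pd.DataFrame
) -> SingleFit:
    """OLS fit of delta on the 11-term directional-change design.

    Columns that are identically zero or linearly dependent (a direction
    never observed) are dropped with a warning; their coefficients are
    reported as NaN with zero covariance.
    """
    y = np.asarray(delta_values, dtype=float)
    X, terms = _design(change_covariates)
    if len(y) != X.shape[0]:
        raise ValueError("one delta value per site is required")

    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    # pivoted QR to catch remaining linear dependence
    Xk = X[:, keep]
    q, r = np.linalg.qr(Xk)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * max(diag.max(), 1.0)).any():
        from scipy.linalg import qr as sqr

        _, r2, piv = sqr(Xk, mode="economic", pivoting=True)
        rank = int(np.sum(np.abs(np.diag(r2)) > 1e-10 * np.abs(r2[0, 0])))
        keep = [keep[j] for j in sorted(piv[:rank])]
        Xk = X[:, keep]
    dropped = [terms[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"rank-deficient design; dropped terms: {dropped}", stacklevel=2)

    res = sm.OLS(y, Xk).fit()
    kept_terms = [terms[j] for j in keep]
    params = pd.Series(np.nan, index=terms)
    params[kept_terms] = res.params
    cov = pd.DataFrame(0.0, index=terms, columns=terms)
    cov.loc[kept_terms, kept_terms] = res.cov_params()
    return SingleFit(
        params=params, cov=cov, dropped=dropped, scale=float(res.scale),
        df_resid=float(res.df_resid),
    )


def propagate(
    delta_draw_sets: np.ndarray,
    change_covariates: pd.DataFrame,
    n_glm: int = 1000,
    n_param: int = 1000,
    seed: int = 0,
) -> DriverFit:
    """Two-stage uncertainty propagation for the driver model.

    ``delta_draw_sets`` is a site x set matrix of posterior delta
    predictions. For each of ``n_glm`` sets the GLM is refit; each fitted
    coefficient vector is then resampled ``n_param`` times from a
    multivariate normal with the OLS estimate and covariance; means and
    equal-tailed 95% intervals are taken over the pooled
    ``n_glm * n_param`` values.
    """
    D = np.atleast_2d(np.asarray(delta_draw_sets, dtype=float))
    if D.shape[1] < n_glm:
        raise ValueError(f"need >= {n_glm} delta sets, got {D.shape[1]}")
    rng = np.random.default_rng(seed)
    X, terms = _design(change_covariates)
    p = len(terms)
    samples = np.empty((n_glm, n_param, p))
    per_set_means = np.empty((n_glm, p))
    idx = np.linspace(0, D.shape[1] - 1, n_glm).round().astype(int)
    for j, col in enumerate(idx):
        f = fit_driver_glm(D[:, col], change_covariates)
        m = f.params.to_numpy()
        C = f.cov.to_numpy()
        ok = ~np.isnan(m)
        draw = np.full((n_param, p), np.nan)
        L = np.linalg.cholesky(C[np.ix_(ok, ok)] + 1e-12 * np.eye(ok.sum()))
        z = rng.standard_normal((n_param, int(ok.sum())))
        draw[:, ok] = m[ok] + z @ L.T
        samples[j] = draw
        per_set_means[j] = m
    pooled = samples.reshape(-1, p)
    mean = pd.Series(np.nanmean(pooled, axis=0), index=terms)
    lo = pd.Series(np.nanpercentile(pooled, 2.5, axis=0), index=terms)
    hi = pd.Series(np.nanpercentile(pooled, 97.5, axis=0), index=terms)
    return DriverFit(
        terms=terms, mean=mean, ci_low=lo, ci_high=hi, samples=pooled,
        n_glm=n_glm, n_param=n_param, per_set_means=per_set_means,
    )


class DriverEffectsGLM(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper around the directional-change driver model.

    ``fit`` accepts the change-covariate table as X and a single delta
    vector as y (ordinary least squares); ``propagate`` performs the
    two-stage uncertainty propagation over posterior delta sets.
    """

    def __init__(self, n_glm: int = 1000, n_param: int = 1000, seed: int = 0):
        self.n_glm = n_glm
        self.n_param = n_param
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        self.single_fit_ = fit_driver_glm(np.asarray(y), X)
        self.coef_ = self.single_fit_.params.to_numpy()[1:]
        self.intercept_ = float(self.single_fit_.params.iloc[0])
        self.feature_names_in_ = np.array(DRIVER_TERMS[1:])
        return self

    def predict(self, X: pd.DataFrame):
        Xd, _ = _design(X)
        beta = np.nan_to_num(self.single_fit_.params.to_numpy())
        return Xd @ beta

    def propagate(self, delta_draw_sets: np.ndarray, X: pd.DataFrame) -> DriverFit:
        self.driver_fit_ = propagate(
            delta_draw_sets, X, n_glm=self.n_glm, n_param=self.n_param, seed=self.seed
        )
        return self.driver_fit_
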