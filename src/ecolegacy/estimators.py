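"""Estimator-style front end for the legacy and equilibrium models.

The Bayesian regressions are exposed as scikit-learn-style estimators:
hyperparameters in ``__init__`` (inspectable via ``get_params`` /
``set_params``), a ``fit`` that consumes assembled :class:`ModelInputs`,
and fitted state in trailing-underscore attributes (``draws_``,
``diagnostics_``). ``predict`` returns the posterior-mean ENS prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .debts import predict_delta, summarize
from .inference import SamplerConfig, compare_models, fit
from .model import Design, ModelInputs
from .params import ModelSpec

__all__ = ["LegacyDiversityModel", "EquilibriumDiversityModel"]


class LegacyDiversityModel(BaseEstimator):
    """Bayesian mixture model of lagged ENS response to land-cover change.

    Parameters mirror the model-structure and sampler configuration; see
    :class:`~ecolegacy.params.ModelSpec` and
    :class:`~ecolegacy.inference.SamplerConfig` for semantics.

    Attributes (after ``fit``)
    --------------------------
    draws_ : PosteriorDraws
    diagnostics_ : FitDiagnostics
    spec_ : ModelSpec
    posterior_mean_ : pandas.Series of posterior means per parameter
    """

    _legacy = True

    def __init__(
        self,
        equilibrium_form: str = "pairwise",
        include_t1: bool = True,
        observer_random_effect: bool = True,
        landcover_scale: str = "fraction",
        change_scale: str = "percent",
        sigma_re_prior: str = "gamma_sd",
        chains: int = 4,
        iterations: int = 1000,
        warmup: int = 500,
        target_accept: float = 0.85,
        max_treedepth: int = 10,
        ess_threshold: float = 400.0,
        max_extensions: int = 1,
        seed: int = 0,
    ):
        self.equilibrium_form = equilibrium_form
        self.include_t1 = include_t1
        self.observer_random_effect = observer_random_effect
        self.landcover_scale = landcover_scale
        self.change_scale = change_scale
        self.sigma_re_prior = sigma_re_prior
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.ess_threshold = ess_threshold
        self.max_extensions = max_extensions
        self.seed = seed

    # ------------------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(
            equilibrium_form=self.equilibrium_form,
            legacy=self._legacy,
            include_t1=self.include_t1,
            observer_random_effect=self.observer_random_effect,
            landcover_scale=self.landcover_scale,
            change_scale=self.change_scale,
            sigma_re_prior=self.sigma_re_prior,
        )

    def _sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.seed,
            target_accept=self.target_accept,
            max_treedepth=self.max_treedepth,
            ess_threshold=self.ess_threshold,
            max_extensions=self.max_extensions,
        )

    def fit(self, X: ModelInputs, y=None):
        """Sample the posterior given assembled inputs (y is carried in X)."""
        self.spec_ = self._spec()
        self.draws_, self.diagnostics_ = fit(self.spec_, X, self._sampler_config())
        self.inputs_ = X
        self.posterior_mean_ = self.draws_.summary()["mean"]
        return self

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted yet; call fit first")

    def predict(self, X: ModelInputs | None = None) -> np.ndarray:
        """Posterior-mean predicted ENS at t2 for each segment."""
        self._check_fitted()
        X = X or self.inputs_
        design = Design(X, self.spec_)
        flat = self.draws_.flat()
        mu = np.zeros(design.n)
        for i in range(flat.shape[0]):
            p = self.draws_.pmap.to_params(flat[i], self.draws_.template)
            mu += design.mu(p)[0]
        return mu / flat.shape[0]

    def predict_delta(self, X: ModelInputs | None = None, n_rep: int = 1000) -> np.ndarray:
        """Site x draw matrix of equilibrium-minus-legacy predictions."""
        self._check_fitted()
        if not self._legacy:
            raise ValueError("delta predictions require the legacy model")
        X = X or self.inputs_
        return predict_delta(self.draws_, X, n_rep=n_rep, spec=self.spec_)

    def debts_credits(
        self, X: ModelInputs | None = None, n_rep: int = 1000
    ) -> tuple[pd.DataFrame, dict]:
        """Per-site debt/credit table with credible intervals and shares."""
        X = X or self.inputs_
        delta = self.predict_delta(X, n_rep=n_rep)
        return summarize(delta, site_ids=X.segment_ids, coords=X.coords)

    def score(self, X: ModelInputs, y=None) -> float:
        """Pearson correlation between predicted and observed t2 ENS."""
        from .validation import correlate_predictions

        mu = self.predict(X)
        r, _, _ = correlate_predictions(mu, X.r_t2)
        return r

    def compare_to(self, other: "LegacyDiversityModel", names=("self", "other")) -> pd.DataFrame:
        self._check_fitted()
        other._check_fitted()
        return compare_models(
            {
                names[0]: (self.draws_, self.diagnostics_),
                names[1]: (other.draws_, other.diagnostics_),
            }
        )


class EquilibriumDiversityModel(LegacyDiversityModel):
    """Current-landscape-only variant: the legacy weight is fixed at 1.

    Shares the equilibrium surface and static-term code paths with the
    legacy model exactly; only the mixture is absent.
    """

    _legacy = False
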