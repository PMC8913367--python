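"""Posterior sampling, convergence diagnostics and model comparison.

``fit`` draws from the posterior of the configured diversity model with
the package's NUTS engine (one independent chain per seed stream), checks
rank-normalized split R-hat and bulk ESS via arviz, and automatically
extends (reruns with doubled iterations) while any ESS falls below the
threshold. ``compare_models`` ranks fits by PSIS-LOO (with WAIC alongside)
from the pointwise log-likelihood matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .model import Design, ModelInputs, make_logpost, pointwise_loglik
from .nuts import nuts_sample
from .params import ModelParams, ModelSpec, ParameterMap

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "FitDiagnostics",
    "fit",
    "diagnose",
    "compare_models",
]


@dataclass
class SamplerConfig:
    chains: int = 4
    iterations: int = 1000  # post-warmup draws per chain
    warmup: int = 500
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    ess_threshold: float = 400.0
    max_extensions: int = 1
    init_retries: int = 20
    #: mass-matrix form: "diag" (robust default) or "dense"
    metric: str = "diag"
    #: seed the metric with a Laplace (inverse-Hessian) covariance at the
    #: posterior mode and start chains mode-jittered; windowed adaptation
    #: still refines the metric
    laplace_metric: bool = True


@dataclass
class PosteriorDraws:
    """Constrained posterior draws with parameter-name index."""

    draws: np.ndarray  # (chains, n_iter, dim)
    names: list
    pmap: ParameterMap
    template: ModelParams
    seed: int
    warmup: int
    iterations: int

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def params_at(self, idx: int) -> ModelParams:
        return self.pmap.to_params(self.flat()[idx], self.template)

    def iter_params(self, indices=None):
        flat = self.flat()
        if indices is None:
            indices = range(flat.shape[0])
        for i in indices:
            yield self.pmap.to_params(flat[i], self.template)

    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": np.percentile(flat, 2.5, axis=0),
                "q97.5": np.percentile(flat, 97.5, axis=0),
            },
            index=self.names,
        )

    def to_arviz(self, loglik: np.ndarray | None = None) -> az.InferenceData:
        posterior = {
            name: self.draws[:, :, j] for j, name in enumerate(self.names)
        }
        groups = {"posterior": posterior}
        if loglik is not None:
            groups["log_likelihood"] = {"r_obs": loglik}
        return az.from_dict(**groups)


@dataclass
class FitDiagnostics:
    rhat: pd.Series
    ess: pd.Series
    divergences: int
    pointwise_loglik: np.ndarray  # (chains, n_iter, n_obs)
    flagged: list = field(default_factory=list)
    extensions: int = 0
    step_sizes: list = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def min_ess(self) -> float:
        return float(self.ess.min())


def _initial_point(
    pmap: ParameterMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw an interior starting point block-by-block on the constrained scale."""
    theta = np.empty(pmap.size)
    for b in pmap.blocks:
        sl = slice(b.offset, b.offset + b.size)
        if b.kind == "lower0":
            theta[sl] = np.exp(rng.normal(0.0, 0.4, b.size))
        elif b.kind == "upper0":
            theta[sl] = -np.exp(rng.normal(0.0, 0.4, b.size))
        elif b.kind == "unit":
            theta[sl] = rng.uniform(0.05, 0.95, b.size)
        else:
            theta[sl] = rng.normal(0.0, 0.3, b.size)
    return pmap.unconstrain(theta)


def _laplace_cov(logpost, u_start: np.ndarray):
    """Mode of the posterior and eigenvalue-regularized inverse Hessian."""
    from scipy.optimize import minimize

    def neg(u):
        lp, g = logpost(u)
        return -lp, -g

    res = minimize(neg, u_start, jac=True, method="L-BFGS-B", options={"maxiter": 500})
    if not np.isfinite(res.fun):
        return None, None
    d = len(u_start)
    H = np.empty((d, d))
    eps = 1e-5
    for i in range(d):
        up, um = res.x.copy(), res.x.copy()
        up[i] += eps
        um[i] -= eps
        H[:, i] = (neg(up)[1] - neg(um)[1]) / (2 * eps)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    if not np.all(np.isfinite(w)):
        return None, None
    # bound implied variances: flat (prior-only) directions get O(10),
    # spuriously stiff ones stay sane
    w = np.clip(w, 0.1, 1e8)
    return res.x, (V / w) @ V.T


def _run_chains(
    logpost, pmap, config: SamplerConfig, iterations: int
) -> tuple[np.ndarray, list, int]:
    """Sample ``config.chains`` independent chains; return constrained draws."""
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.chains)
    all_draws = np.empty((config.chains, iterations, pmap.size))
    step_sizes = []
    divergences = 0
    init_cov = None
    u_mode = None
    chol = None
    for c in range(config.chains):
        rng = np.random.default_rng(child_seeds[c])
        u0 = None
        for attempt in range(config.init_retries):
            cand = _initial_point(pmap, rng)
            lp, _ = logpost(cand)
            if np.isfinite(lp):
                u0 = cand
                break
        if u0 is None:
            raise RuntimeError(
                "non-finite initial log-density after retries; check parameter "
                "bounds and input scaling"
            )
        if c == 0 and config.laplace_metric:
            u_mode, init_cov = _laplace_cov(logpost, u0)
            if init_cov is not None:
                try:
                    chol = np.linalg.cholesky(init_cov)
                except np.linalg.LinAlgError:
                    chol = None
        if u_mode is not None:
            # mode-jittered starts: modest dispersion along the Laplace
            # covariance avoids trapping chains on the weakly identified
            # intercept/observer-mean ridge
            for attempt in range(config.init_retries):
                z = rng.standard_normal(pmap.size)
                cand = u_mode + (0.5 * (chol @ z) if chol is not None else 0.1 * z)
                lp, _ = logpost(cand)
                if np.isfinite(lp):
                    u0 = cand
                    break
        res = nuts_sample(
            logpost,
            u0,
            n_warmup=config.warmup,
            n_draws=iterations,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
            metric=config.metric,
            init_cov=init_cov,
        )
        for i in range(iterations):
            theta, _, _, _ = pmap.constrain(res.draws[i])
            all_draws[c, i] = theta
        divergences += int(res.divergent.sum())
        step_sizes.append(res.step_size)
    return all_draws, step_sizes, divergences


def fit(
    model_spec: ModelSpec,
    inputs: ModelInputs,
    sampler_config: SamplerConfig | None = None,
) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Fit the configured model by NUTS and diagnose convergence.

    Chains are extended (rerun with doubled post-warmup iterations, for
    backend portability) while any parameter's bulk ESS sits below the
    configured threshold, up to ``max_extensions`` reruns.
    """
    config = sampler_config or SamplerConfig()
    logpost, pmap, template = make_logpost(inputs, model_spec)
    design = Design(inputs, model_spec)

    iterations = config.iterations
    extensions = 0
    while True:
        all_draws, step_sizes, divergences = _run_chains(logpost, pmap, config, iterations)
        draws = PosteriorDraws(
            draws=all_draws,
            names=pmap.names,
            pmap=pmap,
            template=template,
            seed=config.seed,
            warmup=config.warmup,
            iterations=iterations,
        )
        diags = diagnose(draws, design=design)
        diags.divergences = divergences
        diags.step_sizes = step_sizes
        diags.extensions = extensions
        if diags.min_ess >= config.ess_threshold or extensions >= config.max_extensions:
            break
        extensions += 1
        iterations *= 2
    if diags.min_ess < config.ess_threshold:
        warnings.warn(
            f"minimum ESS {diags.min_ess:.0f} below threshold "
            f"{config.ess_threshold:.0f} after {extensions} extension(s)",
            stacklevel=2,
        )
    return draws, diags


def diagnose(draws: PosteriorDraws, design: Design | None = None) -> FitDiagnostics:
    """Split R-hat (rank-normalized) and bulk ESS per parameter.

    Requires at least two chains. Parameters with R-hat > 1.01 or
    ESS < 400 are listed in ``flagged``. When a design is supplied the
    per-draw pointwise log-likelihood matrix is evaluated as well.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    idata = draws.to_arviz()
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = pd.Series({k: float(rhat_ds[k].values) for k in draws.names})
    ess = pd.Series({k: float(ess_ds[k].values) for k in draws.names})
    flagged = [n for n in draws.names if rhat[n] > 1.01 or ess[n] < 400]

    loglik = np.empty((0, 0, 0))
    if design is not None:
        n_obs = len(design.r2) + (len(design.r1) if design.r1 is not None else 0)
        loglik = np.empty((draws.n_chains, draws.iterations, n_obs))
        for c in range(draws.n_chains):
            for i in range(draws.iterations):
                p = draws.pmap.to_params(draws.draws[c, i], draws.template)
                loglik[c, i] = pointwise_loglik(design, p)
    return FitDiagnostics(
        rhat=rhat, ess=ess, divergences=0, pointwise_loglik=loglik, flagged=flagged
    )


def compare_models(
    fits: dict,
    method: str = "loo",
) -> pd.DataFrame:
    """Rank fitted models by PSIS-LOO (or WAIC) expected predictive density.

    ``fits`` maps model names to ``(PosteriorDraws, FitDiagnostics)`` pairs
    that were evaluated on the same observations. The returned table holds
    elpd estimates with SE, pairwise differences against the best model,
    and Pareto-k warning counts for the PSIS approximation.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    n_obs = {
        name: d.pointwise_loglik.shape[-1] for name, (_, d) in fits.items()
    }
    if len(set(n_obs.values())) != 1 or 0 in set(n_obs.values()):
        raise ValueError(f"fits cover different observation sets: {n_obs}")

    rows = {}
    idatas = {}
    for name, (dr, dg) in fits.items():
        idata = dr.to_arviz(loglik=dg.pointwise_loglik)
        idatas[name] = idata
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(idata, pointwise=True)
            waic = az.waic(idata)
        k = np.asarray(loo.pareto_k)
        rows[name] = {
            "elpd_loo": float(loo.elpd_loo),
            "se_loo": float(loo.se),
            "p_loo": float(loo.p_loo),
            "elpd_waic": float(waic.elpd_waic),
            "se_waic": float(waic.se),
            "pareto_k_warnings": int((k > 0.7).sum()),
        }
    table = pd.DataFrame(rows).T.sort_values("elpd_loo", ascending=False)
    key = "elpd_loo" if method == "loo" else "elpd_waic"
    table["elpd_diff"] = table[key].max() - table[key]
    table["rank"] = np.arange(len(table))
    return table
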