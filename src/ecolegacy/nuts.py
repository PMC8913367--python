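"""No-U-Turn sampler with dual-averaging step size and adaptive metric.

A self-contained Hamiltonian Monte Carlo engine over any differentiable
log-density: the target is a callable ``logp_and_grad(u) -> (float,
ndarray)`` on an unconstrained parameter space (constraint transforms and
Jacobians are the caller's responsibility; see
:func:`ecolegacy.model.make_logpost`).

Warmup follows the usual three-phase schedule: an initial step-size-only
buffer, a sequence of doubling windows in which the metric is re-estimated
from the warmup draws, and a terminal step-size buffer. The metric is a
dense posterior-covariance estimate by default (the log-linear equilibrium
surface makes strongly correlated coefficient blocks, where a diagonal
metric forces very small steps); a diagonal variant is available and is
used automatically in high dimension. Trajectories use the dynamic
doubling-tree termination criterion with slice sampling; divergences are
flagged when the Hamiltonian error exceeds 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_DELTA_H = 1000.0


class _Metric:
    """Momentum distribution p ~ N(0, Sigma^-1) for a covariance Sigma."""

    def __init__(self, dim: int):
        self.dim = dim
        self.diag: np.ndarray | None = np.ones(dim)  # Sigma diagonal
        self.chol: np.ndarray | None = None  # Cholesky of dense Sigma

    def set_diag(self, var: np.ndarray) -> None:
        self.diag = np.maximum(var, 1e-10)
        self.chol = None

    def set_dense(self, cov: np.ndarray) -> None:
        try:
            self.chol = np.linalg.cholesky(cov)
            self.diag = None
        except np.linalg.LinAlgError:
            self.set_diag(np.diag(cov).copy())

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        if self.chol is not None:
            # cov(p) = L^-T L^-1 = Sigma^-1
            from scipy.linalg import solve_triangular

            return solve_triangular(self.chol, z, lower=True, trans="T")
        return z / np.sqrt(self.diag)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        """Sigma @ p (the position update direction)."""
        if self.chol is not None:
            return self.chol @ (self.chol.T @ p)
        return self.diag * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim), post-warmup
    logp: np.ndarray  # (n_draws,)
    divergent: np.ndarray  # (n_draws,) bool
    treedepth: np.ndarray  # (n_draws,) int
    accept_stat: np.ndarray  # (n_draws,)
    step_size: float
    warmup_divergences: int = 0
    extra: dict = field(default_factory=dict)


def _leapfrog(logp_grad, q, p, grad, eps, metric):
    p = p + 0.5 * eps * grad
    q = q + eps * metric.velocity(p)
    lp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _hamiltonian(lp, p, metric):
    if not np.isfinite(lp):
        return -np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        k = metric.kinetic(p)
    return lp - k if np.isfinite(k) else -np.inf


def _find_reasonable_epsilon(logp_grad, q, grad, lp, metric, rng):
    eps = 1.0
    p = metric.sample_momentum(rng)
    h0 = _hamiltonian(lp, p, metric)
    q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
    dh = _hamiltonian(lp1, p1, metric) - h0
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(60):
        eps = eps * 2.0**direction
        q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
        dh = _hamiltonian(lp1, p1, metric) - h0
        if direction == 1.0 and dh <= np.log(0.5):
            break
        if direction == -1.0 and dh >= np.log(0.5):
            break
    return max(eps, 1e-10)


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus", "q_plus", "p_plus", "grad_plus",
        "q_prop", "lp_prop", "grad_prop", "n", "stop", "alpha", "n_alpha", "divergent",
    )


def _build_tree(logp_grad, q, p, grad, log_u, direction, depth, eps, metric, h0, rng):
    if depth == 0:
        q1, p1, lp1, grad1 = _leapfrog(logp_grad, q, p, grad, direction * eps, metric)
        h1 = _hamiltonian(lp1, p1, metric)
        t = _Tree()
        t.q_minus = t.q_plus = q1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.q_prop, t.lp_prop, t.grad_prop = q1, lp1, grad1
        t.n = int(log_u <= h1)
        t.divergent = bool(not np.isfinite(h1) or log_u > h1 + _MAX_DELTA_H)
        t.stop = t.divergent
        t.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, q, p, grad, log_u, direction, depth - 1, eps, metric, h0, rng)
    if not t.stop:
        if direction == -1:
            t2 = _build_tree(
                logp_grad, t.q_minus, t.p_minus, t.grad_minus, log_u,
                direction, depth - 1, eps, metric, h0, rng,
            )
            t.q_minus, t.p_minus, t.grad_minus = t2.q_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(
                logp_grad, t.q_plus, t.p_plus, t.grad_plus, log_u,
                direction, depth - 1, eps, metric, h0, rng,
            )
            t.q_plus, t.p_plus, t.grad_plus = t2.q_plus, t2.p_plus, t2.grad_plus
        total = t.n + t2.n
        if t2.n > 0 and rng.random() < t2.n / max(total, 1):
            t.q_prop, t.lp_prop, t.grad_prop = t2.q_prop, t2.lp_prop, t2.grad_prop
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.n = total
        dq = t.q_plus - t.q_minus
        uturn = (
            float(dq @ metric.velocity(t.p_minus)) < 0
            or float(dq @ metric.velocity(t.p_plus)) < 0
        )
        t.stop = t2.stop or uturn
        t.divergent = t.divergent or t2.divergent
    return t


def _adaptation_schedule(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    """Iteration indices at which the metric is re-estimated."""
    if n_warmup <= 20:
        return []
    if n_warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.1 * n_warmup))
        base_window = n_warmup - init_buffer - term_buffer
        if base_window <= 0:
            return []
    ends = []
    start = init_buffer
    size = base_window
    while True:
        end = start + size
        if end + term_buffer >= n_warmup or end + term_buffer + size * 2 > n_warmup:
            ends.append(n_warmup - term_buffer)
            break
        ends.append(end)
        start = end
        size *= 2
    return ends


def nuts_sample(
    logp_grad,
    u0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    metric: str = "auto",
    init_cov: np.ndarray | None = None,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and per-draw stats.

    ``metric`` is ``"dense"``, ``"diag"`` or ``"auto"`` (dense up to 200
    dimensions, diagonal beyond). ``init_cov`` seeds the metric with a
    covariance estimate (e.g. a Laplace approximation at the mode) instead
    of the identity, which removes most deep-tree warmup cost; windowed
    adaptation still refines it.
    """
    q = np.asarray(u0, dtype=float).copy()
    dim = q.size
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-density at the initial point")
    if metric == "auto":
        metric = "dense" if dim <= 200 else "diag"
    use_dense = metric == "dense"
    met = _Metric(dim)
    if init_cov is not None:
        if use_dense:
            met.set_dense(np.asarray(init_cov, dtype=float))
        else:
            met.set_diag(np.diag(init_cov).copy())

    eps = _find_reasonable_epsilon(logp_grad, q, grad, lp, met, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _adaptation_schedule(n_warmup)
    window_buf: list[np.ndarray] = []
    warmup_div = 0

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    divergent = np.zeros(n_draws, dtype=bool)
    depths = np.zeros(n_draws, dtype=int)
    accepts = np.zeros(n_draws)

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p = met.sample_momentum(rng)
        h0 = _hamiltonian(lp, p, met)
        log_u = h0 - rng.exponential(1.0)

        q_minus = q_plus = q
        p_minus = p_plus = p
        grad_minus = grad_plus = grad
        q_prop, lp_prop, grad_prop = q, lp, grad
        n_kept = 1
        depth = 0
        diverged = False
        alpha_sum, n_alpha = 0.0, 0
        while depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(
                    logp_grad, q_minus, p_minus, grad_minus, log_u,
                    -1, depth, eps, met, h0, rng,
                )
                q_minus, p_minus, grad_minus = t.q_minus, t.p_minus, t.grad_minus
            else:
                t = _build_tree(
                    logp_grad, q_plus, p_plus, grad_plus, log_u,
                    1, depth, eps, met, h0, rng,
                )
                q_plus, p_plus, grad_plus = t.q_plus, t.p_plus, t.grad_plus
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            diverged = diverged or t.divergent
            if not t.stop and t.n > 0 and rng.random() < min(1.0, t.n / n_kept):
                q_prop, lp_prop, grad_prop = t.q_prop, t.lp_prop, t.grad_prop
            n_kept += t.n
            depth += 1
            if t.stop:
                break
            dq = q_plus - q_minus
            if (
                float(dq @ met.velocity(p_minus)) < 0
                or float(dq @ met.velocity(p_plus)) < 0
            ):
                break

        q, lp, grad = q_prop, lp_prop, grad_prop
        accept_prob = alpha_sum / max(n_alpha, 1)

        if warming:
            if diverged:
                warmup_div += 1
            # dual averaging step-size update
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(da_count) / gamma_da * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            window_buf.append(q.copy())
            if windows and it + 1 == windows[0]:
                windows.pop(0)
                samples = np.asarray(window_buf)
                n_s = len(samples)
                updated = False
                if use_dense and n_s >= max(2 * dim, 40):
                    # a dense estimate from too few draws is worse than the
                    # current metric; only replace it when well determined
                    shrink = n_s / (n_s + 5.0)
                    cov = np.cov(samples, rowvar=False)
                    cov = shrink * cov + (1 - shrink) * 1e-3 * np.eye(dim)
                    cov += 1e-8 * np.eye(dim)
                    met.set_dense(cov)
                    updated = True
                elif use_dense and n_s >= 10 and init_cov is None:
                    # fall back to a diagonal update while dense is unfeasible
                    var = samples.var(axis=0, ddof=1)
                    shrink = n_s / (n_s + 5.0)
                    met.set_diag(shrink * var + (1 - shrink) * 1e-3)
                    updated = True
                elif not use_dense and n_s >= 10:
                    var = samples.var(axis=0, ddof=1)
                    shrink = n_s / (n_s + 5.0)
                    met.set_diag(shrink * var + (1 - shrink) * 1e-3)
                    updated = True
                window_buf = []
                if updated:
                    eps = _find_reasonable_epsilon(logp_grad, q, grad, lp, met, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar)) if da_count else eps
        else:
            i = it - n_warmup
            draws[i] = q
            logps[i] = lp
            divergent[i] = diverged
            depths[i] = depth
            accepts[i] = accept_prob

    return NutsResult(
        draws=draws,
        logp=logps,
        divergent=divergent,
        treedepth=depths,
        accept_stat=accepts,
        step_size=eps,
        warmup_divergences=warmup_div,
    )
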