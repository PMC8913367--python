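"""Deterministic math core: equilibrium surface, legacy weight, mixture
mean, joint density, and the analytic gradient of the sampler target."""

import numpy as np
import pytest

from ecolegacy.model import (
    ModelInputs,
    equilibrium_f,
    equilibrium_variant,
    legacy_weight,
    log_density,
    log_prior,
    make_logpost,
    mixture_mean,
)
from ecolegacy.params import (
    CLASSES,
    LINQUAD_IDX,
    PAIR_IDX,
    ModelParams,
    ModelSpec,
    ParameterMap,
)
from ecolegacy.simulate import default_true_params


# ---------------------------------------------------------------------------
# independent oracles (term-by-term loops, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_equilibrium_f(x, params):
    eta = params.beta0
    for i in range(5):
        eta += params.beta_lin[i] * x[i]
    for pos, (i, k) in enumerate(PAIR_IDX):
        eta += params.beta_pair[pos] * x[i] * x[k]
    for pos, (i, k) in enumerate(LINQUAD_IDX):
        eta += params.beta_linquad[pos] * x[i] * x[k] ** 2
    return np.exp(eta)


def oracle_omega(y, gamma):
    s = 0.0
    for i in range(5):
        for z in range(2):
            s += gamma[i, z] * y[2 * i + z]
    return np.exp(-s)


def random_params(rng, n_observers=0):
    p = ModelParams(
        beta0=rng.uniform(0, 3),
        beta_lin=rng.uniform(0, 1.5, 5),
        beta_pair=rng.normal(0, 0.8, 15),
        beta_linquad=rng.normal(0, 0.5, 20),
        gamma=rng.uniform(0, 1, (5, 2)),
        alpha_temp_lin=rng.uniform(0, 1),
        alpha_temp_quad=-rng.uniform(0, 1),
        alpha_heterogeneity=rng.normal(0, 1),
        alpha_time_of_day=rng.normal(0, 1),
        observer_effects=rng.normal(0, 0.5, n_observers),
        sigma_obs_re=rng.uniform(0.2, 1.0),
        sigma=rng.uniform(0.3, 2.0),
    )
    from ecolegacy.params import PAIR_DIAG_POS

    p.beta_pair[PAIR_DIAG_POS] = -np.abs(p.beta_pair[PAIR_DIAG_POS])
    return p


def random_inputs(rng, n=12, n_observers=3, zero_change=False):
    x1 = rng.dirichlet(np.ones(6), n)[:, :5] * 100
    if zero_change:
        x2 = x1.copy()
    else:
        x2 = np.clip(x1 + rng.normal(0, 4, x1.shape), 0, None)
        x2 *= np.minimum(1.0, 99.0 / x2.sum(axis=1))[:, None]
    delta = x2 - x1
    y = np.empty((n, 10))
    y[:, 0::2] = np.where(delta < 0, -delta, 0.0)
    y[:, 1::2] = np.where(delta < 0, 0.0, delta)
    return ModelInputs(
        segment_ids=np.arange(n),
        x_t1=x1,
        x_t2=x2,
        y=y,
        temperature=rng.normal(0, 1, n),
        heterogeneity=rng.uniform(1, 5, n),
        time_of_day=rng.normal(0, 1, n),
        observer_idx=rng.integers(0, n_observers, n),
        r_t2=rng.uniform(2, 20, n),
        r_t1=rng.uniform(2, 20, n),
    )


# ---------------------------------------------------------------------------


class TestEquilibriumF:
    def test_constant_model(self):
        p = ModelParams(beta0=np.log(10.0))
        for x in ([0.1] * 5, [0, 0.5, 0.2, 0.1, 0.05]):
            assert equilibrium_f(np.array(x), p) == pytest.approx(10.0, rel=1e-12)

    def test_zero_composition_gives_intercept(self, rng):
        p = random_params(rng)
        assert equilibrium_f(np.zeros(5), p) == pytest.approx(np.exp(p.beta0), rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(200):
            p = random_params(rng)
            x = rng.uniform(0, 1, 5)
            assert equilibrium_f(x, p) == pytest.approx(
                oracle_equilibrium_f(x, p), rel=1e-12
            )

    def test_reduces_to_quadratic_polynomial(self, rng):
        # zero all interactions -> pure 2nd-order polynomial per class
        p = random_params(rng)
        from ecolegacy.params import PAIR_DIAG_POS, PAIR_OFF_POS

        p.beta_pair[PAIR_OFF_POS] = 0.0
        p.beta_linquad[:] = 0.0
        x = rng.uniform(0, 1, 5)
        quad = p.beta0 + np.sum(
            p.beta_lin * x + p.beta_pair[PAIR_DIAG_POS] * x**2
        )
        assert equilibrium_f(x, p) == pytest.approx(np.exp(quad), rel=1e-12)

    def test_out_of_range_raises(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            equilibrium_f(np.array([1.2, 0, 0, 0, 0]), p)
        with pytest.raises(ValueError):
            equilibrium_f(np.array([-0.1, 0, 0, 0, 0]), p)


class TestLegacyWeight:
    def test_no_change_gives_unit_weight(self):
        assert legacy_weight(np.zeros(10), np.full((5, 2), 0.5)) == 1.0

    def test_single_term_closed_form(self):
        y = np.zeros(10)
        y[1] = 10.0  # urban gain of 10 points
        g = np.zeros((5, 2))
        g[0, 1] = 0.1
        assert legacy_weight(y, g) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_exponential_additivity(self, rng):
        g = rng.uniform(0, 1, (5, 2))
        y1 = np.zeros(10)
        y1[2] = 5.0
        y2 = np.zeros(10)
        y2[7] = 3.0
        assert legacy_weight(y1 + y2, g) == pytest.approx(
            legacy_weight(y1, g) * legacy_weight(y2, g), rel=1e-12
        )

    def test_matches_loop_oracle(self, rng):
        for _ in range(200):
            g = rng.uniform(0, 1, (5, 2))
            y = rng.uniform(0, 20, 10)
            assert legacy_weight(y, g) == pytest.approx(oracle_omega(y, g), rel=1e-12)

    def test_bounds_and_monotonicity(self, rng):
        g = rng.uniform(0.1, 1, (5, 2))
        y = rng.uniform(0, 20, 10)
        w = legacy_weight(y, g)
        assert 0 < w <= 1
        y_more = y.copy()
        y_more[4] += 1.0
        assert legacy_weight(y_more, g) < w

    def test_negative_y_raises(self):
        with pytest.raises(ValueError):
            legacy_weight(np.full(10, -1.0), np.zeros((5, 2)))
        with pytest.raises(ValueError):
            legacy_weight(np.zeros(10), np.full((5, 2), 1.5))


class TestMixtureMean:
    def test_equal_landscapes_independent_of_gamma(self, rng):
        inputs = random_inputs(rng, zero_change=True)
        p = random_params(rng, n_observers=3)
        mu_a = mixture_mean(inputs, p)
        p2 = p.copy()
        p2.gamma = rng.uniform(0, 1, (5, 2))
        np.testing.assert_allclose(mu_a, mixture_mean(inputs, p2), rtol=1e-12)

    def test_omega_one_limit_equals_equilibrium(self, rng):
        inputs = random_inputs(rng)
        p = random_params(rng, n_observers=3)
        p.gamma = np.zeros((5, 2))  # omega = 1 exactly
        np.testing.assert_allclose(
            mixture_mean(inputs, p), equilibrium_variant(inputs, p), rtol=1e-12
        )

    def test_matches_hand_composed_oracle(self, rng):
        spec = ModelSpec()
        inputs = random_inputs(rng)
        p = random_params(rng, n_observers=3)
        mu = mixture_mean(inputs, p, spec)
        for s in range(inputs.n_segments):
            f1 = oracle_equilibrium_f(inputs.x_t1[s] / 100.0, p)
            f2 = oracle_equilibrium_f(inputs.x_t2[s] / 100.0, p)
            w = oracle_omega(inputs.y[s], p.gamma)
            g = (
                p.alpha_temp_lin * inputs.temperature[s]
                + p.alpha_temp_quad * inputs.temperature[s] ** 2
                + p.alpha_heterogeneity * inputs.heterogeneity[s]
                + p.alpha_time_of_day * inputs.time_of_day[s]
                + p.observer_effects[inputs.observer_idx[s]]
            )
            assert mu[s] == pytest.approx(f2 * w + f1 * (1 - w) + g, rel=1e-10)

    def test_convex_combination_bounds(self, rng):
        spec = ModelSpec()
        inputs = random_inputs(rng)
        p = random_params(rng, n_observers=3)
        from ecolegacy.model import Design

        d = Design(inputs, spec)
        f1, f2 = d.f_values(p)
        g = d.static_term(p)
        mu = d.mu(p)[0]
        lo = np.minimum(f1 + g, f2 + g)
        hi = np.maximum(f1 + g, f2 + g)
        assert np.all(mu >= lo - 1e-9) and np.all(mu <= hi + 1e-9)

    def test_observer_index_out_of_range(self, rng):
        inputs = random_inputs(rng, n_observers=3)
        p = random_params(rng, n_observers=2)
        inputs.observer_idx[:] = 2
        with pytest.raises(IndexError):
            mixture_mean(inputs, p)

    def test_equilibrium_variant_ignores_t1(self, rng):
        inputs = random_inputs(rng)
        p = random_params(rng, n_observers=3)
        base = equilibrium_variant(inputs, p)
        shaken = random_inputs(rng)
        shaken.x_t1 = np.clip(inputs.x_t1 + 5.0, 0, 100)
        # rebuild with consistent y so the container accepts it
        delta = inputs.x_t2 - shaken.x_t1
        y = np.empty_like(inputs.y)
        y[:, 0::2] = np.where(delta < 0, -delta, 0.0)
        y[:, 1::2] = np.where(delta < 0, 0.0, delta)
        other = ModelInputs(
            segment_ids=inputs.segment_ids,
            x_t1=shaken.x_t1,
            x_t2=inputs.x_t2,
            y=y,
            temperature=inputs.temperature,
            heterogeneity=inputs.heterogeneity,
            time_of_day=inputs.time_of_day,
            observer_idx=inputs.observer_idx,
            r_t2=inputs.r_t2,
            r_t1=inputs.r_t1,
        )
        np.testing.assert_allclose(base, equilibrium_variant(other, p), rtol=1e-12)


class TestLogDensity:
    def test_standard_normal_peak(self, rng):
        inputs = random_inputs(rng, n=1, n_observers=1)
        spec = ModelSpec(include_t1=False)
        p = random_params(rng, n_observers=1)
        p.sigma = 1.0
        mu = mixture_mean(inputs, p, spec)
        inputs.r_t2 = mu.copy()
        data_term = log_density(inputs, p, spec) - log_prior(p, spec)
        assert data_term == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_gamma_boundary_finite(self, rng):
        inputs = random_inputs(rng)
        p = random_params(rng, n_observers=3)
        for val in (0.0, 1.0):
            p.gamma = np.full((5, 2), val)
            assert np.isfinite(log_density(inputs, p))

    def test_out_of_bounds_returns_neg_inf(self, rng):
        inputs = random_inputs(rng)
        p = random_params(rng, n_observers=3)
        p.beta0 = -0.5
        assert log_density(inputs, p) == -np.inf
        p = random_params(rng, n_observers=3)
        p.gamma[0, 0] = 1.5
        assert log_density(inputs, p) == -np.inf

    def test_term_sum_oracle(self, rng):
        spec = ModelSpec()
        inputs = random_inputs(rng, n=5, n_observers=2)
        p = random_params(rng, n_observers=2)
        from ecolegacy.model import Design

        d = Design(inputs, spec)
        mu2, mu1 = d.mu(p)
        ll = 0.0
        for s in range(5):
            for r, mu in ((inputs.r_t2[s], mu2[s]), (inputs.r_t1[s], mu1[s])):
                ll += -0.5 * ((r - mu) / p.sigma) ** 2 - np.log(p.sigma) - 0.5 * np.log(2 * np.pi)
        assert log_density(inputs, p, spec) == pytest.approx(
            ll + log_prior(p, spec), rel=1e-12
        )


class TestParams:
    def test_flatten_unflatten_roundtrip(self, rng):
        p = random_params(rng, n_observers=4)
        q = ModelParams.unflatten(p.flatten(), n_observers=4)
        np.testing.assert_array_equal(p.flatten(), q.flatten())

    def test_validate_rejects_bad_bounds(self, rng):
        p = random_params(rng)
        p.alpha_temp_quad = 0.2
        with pytest.raises(ValueError):
            p.validate()

    def test_json_roundtrip(self, tmp_path, rng):
        p = random_params(rng, n_observers=2)
        p.to_json(tmp_path / "p.json")
        q = ModelParams.from_json(tmp_path / "p.json")
        np.testing.assert_allclose(p.flatten(), q.flatten())

    def test_parameter_map_roundtrip(self, rng):
        for spec in (ModelSpec(), ModelSpec(equilibrium_form="quadratic", legacy=False)):
            pmap = ParameterMap(spec, n_observers=3)
            p = random_params(rng, n_observers=3)
            theta = pmap.constrained_vector(p)
            u = pmap.unconstrain(theta)
            theta2, _, _, _ = pmap.constrain(u)
            np.testing.assert_allclose(theta, theta2, atol=1e-9)
            assert len(pmap.names) == pmap.size


@pytest.mark.parametrize(
    "spec",
    [
        ModelSpec(),
        ModelSpec(equilibrium_form="quadratic"),
        ModelSpec(include_t1=False),
        ModelSpec(observer_random_effect=False),
        ModelSpec(legacy=False, equilibrium_form="quadratic"),
        ModelSpec(sigma_re_prior="gamma_precision"),
        ModelSpec(landcover_scale="percent", change_scale="fraction"),
    ],
    ids=["full", "quadratic", "no_t1", "no_re", "equilibrium", "prec_prior", "rescaled"],
)
def test_analytic_gradient_matches_finite_difference(spec, rng):
    """The sampler target's gradient agrees with central differences."""
    inputs = random_inputs(rng, n=8, n_observers=3)
    lpg, pmap, _ = make_logpost(inputs, spec)
    for _ in range(3):
        if spec.landcover_scale == "percent":
            # on the percent scale realistic coefficients shrink with the
            # polynomial order of the feature they multiply
            p = random_params(rng, n_observers=3)
            p.beta_lin = p.beta_lin * 1e-2
            p.beta_pair = p.beta_pair * 1e-4
            p.beta_linquad = p.beta_linquad * 1e-6
            u = pmap.unconstrain(pmap.constrained_vector(p))
        else:
            u = rng.normal(0, 0.3, pmap.size)
        lp, g = lpg(u)
        assert np.isfinite(lp)
        fd = np.empty_like(u)
        eps = 1e-6
        # the percent scale carries ~1e6-sized cubic features, which limits
        # the attainable central-difference accuracy; loosen only there
        tol = 1e-3 if spec.landcover_scale == "percent" else 1e-5
        for i in range(pmap.size):
            up, um = u.copy(), u.copy()
            up[i] += eps
            um[i] -= eps
            fd[i] = (lpg(up)[0] - lpg(um)[0]) / (2 * eps)
        denom = np.maximum(np.abs(fd) + np.abs(g), 1e-4)
        assert np.max(np.abs(fd - g) / denom) < tol


def test_prior_predictive_means_are_finite(rng):
    """Parameters drawn from the priors push through to finite means."""
    from ecolegacy.inference import _initial_point

    spec = ModelSpec()
    inputs = random_inputs(rng, n=10, n_observers=3)
    pmap = ParameterMap(spec, n_observers=3)
    for _ in range(50):
        u = _initial_point(pmap, rng)
        theta, _, _, _ = pmap.constrain(u)
        p = pmap.to_params(theta, ModelParams(observer_effects=np.zeros(3)))
        mu = mixture_mean(inputs, p, spec)
        assert np.all(np.isfinite(mu))


def test_default_truth_respects_all_bounds():
    default_true_params(n_observers=5, rng=np.random.default_rng(0)).validate()
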