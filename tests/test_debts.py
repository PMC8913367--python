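"""Debt/credit prediction, summaries, and spatial aggregation."""

import numpy as np
import pandas as pd
import pytest

from ecolegacy.debts import (
    geometric_cv,
    grid_aggregate,
    over_under_estimate,
    predict_delta,
    summarize,
)
from ecolegacy.model import Design
from ecolegacy.params import ModelSpec


class TestPredictDelta:
    def test_zero_change_sites_have_zero_delta(self, tiny_fit, small_inputs):
        spec, draws, _ = tiny_fit
        delta = predict_delta(draws, small_inputs, n_rep=100, spec=spec)
        unchanged = small_inputs.y.sum(axis=1) == 0
        assert unchanged.any()
        np.testing.assert_allclose(delta[unchanged], 0.0, atol=1e-12)

    def test_factorization_identity(self, tiny_fit, small_inputs):
        """(1-w)(f2-f1) equals the equilibrium-minus-legacy subtraction."""
        spec, draws, _ = tiny_fit
        delta, equil, legacy = predict_delta(
            draws, small_inputs, n_rep=100, spec=spec, return_components=True
        )
        np.testing.assert_allclose(delta, equil - legacy, atol=1e-10)

    def test_sign_logic(self, tiny_fit, small_inputs):
        spec, draws, _ = tiny_fit
        design = Design(small_inputs, spec)
        p = draws.params_at(0)
        f1, f2 = design.f_values(p)
        w = design.omega(p)
        delta = (1 - w) * (f2 - f1)
        gain = (f2 > f1) & (w < 1)
        assert np.all(delta[gain] > 0)

    def test_antisymmetry_under_timepoint_swap(self, small_inputs, rng):
        """Swapping landscapes (mirroring direction slots) negates f2 - f1."""
        from ecolegacy.model import ModelInputs
        from ecolegacy.simulate import default_true_params

        p = default_true_params()
        # symmetric decay rates so omega is invariant under the swap
        p.gamma = np.full((5, 2), 0.15)
        y_sw = small_inputs.y.copy()
        y_sw[:, 0::2], y_sw[:, 1::2] = (
            small_inputs.y[:, 1::2].copy(),
            small_inputs.y[:, 0::2].copy(),
        )
        swapped = ModelInputs(
            segment_ids=small_inputs.segment_ids,
            x_t1=small_inputs.x_t2,
            x_t2=small_inputs.x_t1,
            y=y_sw,
            temperature=small_inputs.temperature,
            heterogeneity=small_inputs.heterogeneity,
            time_of_day=small_inputs.time_of_day,
            observer_idx=small_inputs.observer_idx,
            r_t2=small_inputs.r_t2,
        )
        spec = ModelSpec()
        d0, ds = Design(small_inputs, spec), Design(swapped, spec)
        f1a, f2a = d0.f_values(p)
        f1b, f2b = ds.f_values(p)
        np.testing.assert_allclose(
            (1 - d0.omega(p)) * (f2a - f1a),
            -(1 - ds.omega(p)) * (f2b - f1b),
            atol=1e-10,
        )

    def test_n_rep_exceeding_draws_raises(self, tiny_fit, small_inputs):
        spec, draws, _ = tiny_fit
        with pytest.raises(ValueError):
            predict_delta(draws, small_inputs, n_rep=draws.n_draws + 1, spec=spec)


class TestSummaries:
    def test_gcv_closed_forms(self):
        assert geometric_cv(0.0) == pytest.approx(0.0)
        assert geometric_cv(np.e - 1) == pytest.approx(np.sqrt(np.e - 1), rel=1e-12)
        assert geometric_cv(np.e - 1) == pytest.approx(1.31083, abs=1e-5)

    def test_degenerate_draws_give_zero_gcv(self):
        delta = np.full((3, 200), 1.7)
        table, shares = summarize(delta)
        np.testing.assert_allclose(table["gcv"], 0.0)
        np.testing.assert_allclose(table["mean_delta"], 1.7)
        assert shares["credit_share"] == 1.0

    def test_all_credit_construction(self, rng):
        delta = np.abs(rng.normal(2, 0.3, size=(20, 150)))
        table, shares = summarize(delta)
        assert (table["classification"] == "credit").all()
        assert shares["credit_share"] == 1.0 and shares["debt_share"] == 0.0

    def test_interval_ordering_and_classification(self, rng):
        delta = rng.normal(0, 1, size=(50, 300)) + rng.normal(0, 2, size=(50, 1))
        table, _ = summarize(delta)
        assert (table["ci_low"] <= table["mean_delta"] + 1e-9).all()
        assert (table["mean_delta"] <= table["ci_high"] + 1e-9).all()
        pos = table["mean_delta"] > 0
        assert (table.loc[pos, "classification"] == "credit").all()
        assert (table.loc[~pos, "classification"].isin(["debt", "neutral"])).all()

    def test_too_few_draws_raises(self):
        with pytest.raises(ValueError):
            summarize(np.zeros((3, 50)))


class TestOverUnder:
    def test_examples(self):
        assert over_under_estimate(15.0, 10.0) == pytest.approx(50.0)
        assert over_under_estimate(10.0, 10.0) == pytest.approx(0.0)

    def test_random_pairs_match_formula(self, rng):
        e = rng.uniform(1, 30, 100)
        l = rng.uniform(1, 30, 100)
        np.testing.assert_allclose(
            over_under_estimate(e, l), 100.0 * (e - l) / l, rtol=1e-12
        )

    def test_nonpositive_legacy_raises(self):
        with pytest.raises(ValueError):
            over_under_estimate(5.0, 0.0)


class TestGridAggregate:
    def _table(self, xs, ys, vals):
        return pd.DataFrame(
            {"site_id": range(len(xs)), "x_coord": xs, "y_coord": ys, "mean_delta": vals}
        )

    def test_one_site_per_cell(self):
        t = self._table([5.0, 15.0], [5.0, 15.0], [1.0, 3.0])
        out = grid_aggregate(t, cell_size=10.0)
        assert len(out) == 2
        assert sorted(out["mean_delta"]) == [1.0, 3.0]

    def test_two_sites_in_one_cell_average(self):
        t = self._table([2.0, 8.0], [3.0, 4.0], [1.0, 3.0])
        out = grid_aggregate(t, cell_size=10.0)
        assert len(out) == 1
        assert out.loc[0, "mean_delta"] == pytest.approx(2.0)
        assert out.loc[0, "n_sites"] == 2

    def test_matches_brute_force_binning(self, rng):
        n = 200
        t = self._table(
            rng.uniform(0, 100, n), rng.uniform(0, 100, n), rng.normal(0, 1, n)
        )
        out = grid_aggregate(t, cell_size=20.0).set_index(["cell_x", "cell_y"])
        for (cx, cy), grp in t.groupby(
            [np.floor(t.x_coord / 20).astype(int), np.floor(t.y_coord / 20).astype(int)]
        ):
            assert out.loc[(cx, cy), "mean_delta"] == pytest.approx(
                grp["mean_delta"].mean()
            )

    def test_missing_coordinates_warn_and_exclude(self):
        t = self._table([1.0, 2.0, np.nan], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="without coordinates"):
            out = grid_aggregate(t, cell_size=10.0)
        assert out["n_sites"].sum() == 2

    def test_hex_binning_covers_all_sites(self, rng):
        n = 100
        t = self._table(rng.uniform(0, 50, n), rng.uniform(0, 50, n), rng.normal(size=n))
        out = grid_aggregate(t, cell_size=10.0, kind="hex")
        assert out["n_sites"].sum() == n
        assert (out["cell_area"] > 0).all()
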