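"""Hill numbers and survey-table preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecolegacy.diversity import (
    FilterRules,
    average_window,
    diversity_table,
    filter_routes,
    hill_diversity,
    segment_and_select,
)

positive_vectors = arrays(
    np.float64,
    st.integers(2, 12),
    elements=st.floats(0.01, 1000.0, allow_nan=False),
)


class TestHillDiversity:
    @pytest.mark.parametrize(
        "abund, q, expected",
        [
            ([10, 10, 10], 1.0, 3.0),
            ([10, 10, 10], 0.0, 3.0),
            ([8, 2], np.inf, 1.25),
            ([5, 0, 3, 0], 0.0, 2.0),
            ([1, 1, 1, 1], np.inf, 4.0),
        ],
    )
    def test_spot_values(self, abund, q, expected):
        assert hill_diversity(abund, q) == pytest.approx(expected, abs=1e-12)

    def test_shannon_two_species(self):
        # H = -(0.8 ln 0.8 + 0.2 ln 0.2) = 0.500402; exp(H) = 1.64938
        p = np.array([0.8, 0.2])
        h = -np.sum(p * np.log(p))
        assert h == pytest.approx(0.500402, abs=1e-6)
        assert hill_diversity([8, 2], 1.0) == pytest.approx(np.exp(h), abs=1e-12)
        assert hill_diversity([8, 2], 1.0) == pytest.approx(1.64938, abs=1e-5)

    def test_errors(self):
        with pytest.raises(ValueError):
            hill_diversity([0.0, 0.0], 1.0)
        with pytest.raises(ValueError):
            hill_diversity([-1.0, 2.0], 1.0)
        with pytest.raises(ValueError):
            hill_diversity([1.0, 2.0], -0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(positive_vectors)
    def test_monotone_nonincreasing_in_q(self, a):
        qs = [0.0, 0.5, 1.0, 1.0 + 1e-10, 2.0, 5.0, np.inf]
        vals = [hill_diversity(a, q) for q in qs]
        assert all(v1 >= v2 - 1e-8 for v1, v2 in zip(vals, vals[1:]))
        assert vals[-1] >= 1.0 - 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(positive_vectors, st.floats(1e-3, 1e3))
    def test_scale_invariance(self, a, c):
        for q in (0.0, 1.0, 2.0, np.inf):
            assert hill_diversity(c * a, q) == pytest.approx(
                hill_diversity(a, q), rel=1e-9
            )

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_replication_principle(self, k, rng):
        a = rng.uniform(0.1, 5.0, size=7)
        d = hill_diversity(a, 1.0)
        pooled = np.tile(a, k)  # k disjoint, equally weighted copies
        assert hill_diversity(pooled, 1.0) == pytest.approx(k * d, rel=1e-10)

    def test_even_community_iff_q1_equals_q0(self, rng):
        even = np.full(9, 3.7)
        assert hill_diversity(even, 1.0) == pytest.approx(hill_diversity(even, 0.0))
        uneven = rng.uniform(0.5, 2.0, size=9)
        uneven[0] = 10.0
        assert hill_diversity(uneven, 1.0) < hill_diversity(uneven, 0.0)

    def test_exp_shannon_oracle_sweep(self, rng):
        # independent brute-force Shannon sum
        for _ in range(1000):
            a = rng.uniform(0.001, 50.0, size=rng.integers(2, 20))
            p = a / a.sum()
            oracle = np.exp(-sum(pi * np.log(pi) for pi in p))
            assert abs(hill_diversity(a, 1.0) - oracle) < 1e-12


class TestFilterRoutes:
    def _fixture(self):
        rows = []
        for i in range(10):
            rows.append(
                {
                    "route_id": f"r{i}",
                    "n_stops": 50,
                    "route_type_detail": 2,
                    "run_protocol": 0,
                }
            )
        df = pd.DataFrame(rows)
        # 3 incomplete (short or low detail code), 2 flagged protocol
        df.loc[0, "n_stops"] = 42
        df.loc[1, "route_type_detail"] = 1
        df.loc[2, "n_stops"] = 10
        df.loc[3, "run_protocol"] = 1
        df.loc[4, "run_protocol"] = 1
        return df

    def test_hand_counted_fixture(self):
        kept, report = filter_routes(self._fixture())
        assert len(kept) == 5
        assert report["incomplete_length"] == 3
        assert report["flagged_protocol"] == 2
        assert report["retained"] == 5

    def test_clean_table_is_identity(self):
        df = self._fixture().iloc[5:]
        kept, report = filter_routes(df)
        pd.testing.assert_frame_equal(kept, df)
        assert report["retained"] == len(df)

    def test_empty_table(self):
        empty = self._fixture().iloc[:0]
        kept, report = filter_routes(empty)
        assert kept.empty
        assert report == {
            "input": 0, "incomplete_length": 0, "flagged_protocol": 0, "retained": 0
        }

    def test_missing_column_named(self):
        df = self._fixture().drop(columns=["run_protocol"])
        with pytest.raises(KeyError, match="run_protocol"):
            filter_routes(df)


class TestSegmentation:
    def _stops(self, n_routes=1):
        return pd.DataFrame(
            [
                {"route_id": f"r{r}", "stop": s}
                for r in range(n_routes)
                for s in range(1, 51)
            ]
        )

    def test_stop_to_segment_mapping(self):
        out = segment_and_select(self._stops())
        seg_of = dict(zip(out["stop"], out["segment"]))
        assert 11 not in seg_of  # stop 11 -> segment 2, dropped
        assert seg_of[41] == 5
        assert seg_of[1] == 1
        assert seg_of[30] == 3
        assert set(out["segment"]) == {1, 3, 5}

    def test_study_scale_segment_count(self):
        out = segment_and_select(self._stops(n_routes=960))
        assert out["segment_id"].nunique() == 2880

    def test_wrong_stop_count_raises(self):
        bad = self._stops().iloc[:-3]
        with pytest.raises(ValueError, match="filtered"):
            segment_and_select(bad)


class TestAverageWindow:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["segment_id", "species_id", "year", "count"])

    def test_three_year_mean(self):
        ab = self._table([("a", "sp1", 2000, 10), ("a", "sp1", 2001, 20), ("a", "sp1", 2002, 30)])
        out = average_window(ab, 2001)
        assert out.loc[0, "mean_count"] == pytest.approx(20.0)

    def test_denominator_conventions(self):
        # species seen only in 2015 (count 6), segment surveyed only that year
        ab = self._table([("a", "sp1", 2015, 6)])
        surveyed = average_window(ab, 2016, denominator="surveyed")
        fixed = average_window(ab, 2016, denominator="fixed")
        assert surveyed.loc[0, "mean_count"] == pytest.approx(6.0)
        assert fixed.loc[0, "mean_count"] == pytest.approx(2.0)

    def test_width_one_identity(self):
        ab = self._table([("a", "sp1", 2016, 7), ("a", "sp2", 2016, 3)])
        out = average_window(ab, 2016, width=1)
        assert sorted(out["mean_count"]) == [3.0, 7.0]

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            average_window(self._table([("a", "sp1", 2016, 7)]), 2016, width=2)

    def test_segment_outside_window_dropped_with_warning(self):
        ab = self._table([("a", "sp1", 2016, 7), ("b", "sp1", 1999, 4)])
        with pytest.warns(UserWarning, match="dropped"):
            out = average_window(ab, 2016)
        assert set(out["segment_id"]) == {"a"}


def test_diversity_table_orders(small_dataset):
    div = diversity_table(small_dataset.abundance, {"t1": 2001, "t2": 2016})
    assert {"q0", "q1", "q_inf"} <= set(div.columns)
    # Hill ordering q0 >= q1 >= q_inf >= 1
    assert (div["q0"] >= div["q1"] - 1e-9).all()
    assert (div["q1"] >= div["q_inf"] - 1e-9).all()
    assert (div["q_inf"] >= 1.0 - 1e-9).all()
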