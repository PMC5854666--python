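"""Impact statistics: gain/loss/turnover, representativity, protected
range, distributions, paired tests, robust summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicheshift import metrics, synthetic
from nicheshift.grid import make_grid
from nicheshift.metrics import (compare_periods, land_area_distribution,
                                protected_range_change, relative_gain,
                                relative_loss, representativity, summarize,
                                turnover)


class TestRelativeGainLoss:
    @pytest.mark.parametrize("g, ref, expected", [
        (0, 10, 0.0),
        (10, 10, 100.0),    # the >= 100% class boundary
        (53, 10, 530.0),    # a 5.3-fold gain
    ])
    def test_relative_gain(self, g, ref, expected):
        assert relative_gain(g, ref) == pytest.approx(expected)

    @pytest.mark.parametrize("l, ref, expected", [
        (0, 8, 0.0),
        (8, 8, 100.0),      # total loss is bounded at 100
        (11, 20, 55.0),
    ])
    def test_relative_loss(self, l, ref, expected):
        assert relative_loss(l, ref) == pytest.approx(expected)

    def test_zero_reference_richness_undefined(self):
        with pytest.raises(ValueError, match="refSR"):
            relative_gain(3, 0)
        with pytest.raises(ValueError, match="refSR"):
            relative_loss(0, 0)

    def test_loss_above_reference_is_a_bookkeeping_bug(self):
        with pytest.raises(ValueError, match="exceeds"):
            relative_loss(5, 4)


class TestTurnover:
    @pytest.mark.parametrize("g, l, ref, expected", [
        (0, 0, 12, 0.0),            # composition unchanged
        (3, 5, 5, 100.0),           # every reference species lost
        (4, 2, 10, 100.0 * 6 / 14),
    ])
    def test_worked_examples(self, g, l, ref, expected):
        assert turnover(g, l, ref) == pytest.approx(expected)

    def test_full_turnover_independent_of_gain(self):
        for g in (0, 1, 7, 100):
            assert turnover(g, 5, 5) == pytest.approx(100.0)

    def test_undefined_when_no_species_at_all(self):
        with pytest.raises(ValueError, match="undefined"):
            turnover(0, 0, 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounds_and_monotonicity_in_loss(self, g, l, ref):
        l = min(l, ref)
        if ref + g == 0:
            return
        t = turnover(g, l, ref)
        assert 0.0 <= t <= 100.0
        if l < ref:  # increasing the loss cannot decrease turnover
            assert turnover(g, l + 1, ref) >= t
        # T = 100 exactly iff every reference species is lost (refSR > 0)
        if ref > 0:
            assert (t == 100.0) == (l == ref)


class TestRepresentativity:
    def _presence(self, rows):
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])

    def test_full_pool_gives_one(self):
        mat = self._presence([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert representativity(np.array([0]), np.arange(4), mat) == 1.0

    def test_partial_pool_ratio(self):
        # region pool 4 species, PA pool 1 -> 0.25
        mat = self._presence([[1, 1], [0, 1], [0, 1], [0, 1]])
        assert representativity(np.array([0]), np.array([0, 1]),
                                mat) == 0.25

    def test_empty_region_pool_undefined(self):
        mat = self._presence([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="empty region"):
            representativity(np.array([0]), np.array([0, 1]), mat)

    def test_nonincreasing_with_coarser_scale(self):
        # nested cell sets: region within province within study area
        rng = np.random.default_rng(6)
        mat = self._presence(rng.integers(0, 2, (15, 40)).tolist())
        pa = np.array([3, 4])
        region = np.arange(0, 10)
        province = np.arange(0, 25)
        study = np.arange(0, 40)
        r = [representativity(pa, cells, mat)
             for cells in (region, province, study)]
        assert r[0] >= r[1] >= r[2]


class TestProtectedRange:
    def test_vanishing_future_range(self):
        land = np.array([10.0, 40.0, 0.0])
        rec = protected_range_change("sp", np.array([1, 1, 0]),
                                     np.array([0, 0, 0]), land)
        assert rec.ref_pr == 50.0
        assert rec.delta_pr == -100.0

    def test_no_change(self):
        land = np.array([10.0, 40.0])
        rec = protected_range_change("sp", np.array([1, 1]),
                                     np.array([1, 1]), land)
        assert rec.delta_pr == 0.0

    def test_threefold_increase(self):
        land = np.array([50.0, 100.0])
        rec = protected_range_change("sp", np.array([1, 0]),
                                     np.array([1, 1]), land)
        assert rec.ref_pr == 50.0 and rec.future_pr == 150.0
        assert rec.delta_pr == pytest.approx(200.0)

    def test_excluded_when_reference_range_unprotected(self):
        land = np.array([0.0, 10.0])
        rec = protected_range_change("sp", np.array([1, 0]),
                                     np.array([0, 1]), land)
        assert rec.excluded
        assert rec.delta_pr is None

    def test_delta_bounded_below(self):
        rng = np.random.default_rng(2)
        land = rng.uniform(0, 400, 30)
        for _ in range(20):
            ref = rng.integers(0, 2, 30)
            fut = rng.integers(0, 2, 30)
            rec = protected_range_change("sp", ref, fut, land)
            if not rec.excluded:
                assert rec.delta_pr >= -100.0


class TestLandDistribution:
    def test_single_class_gets_all(self):
        out = land_area_distribution(np.array([5.0, 7.0]),
                                     np.array([10.0, 30.0]),
                                     np.array([0.0, 10.0]))
        assert out["land_share"].iloc[0] == pytest.approx(1.0)
        assert out["land_share"].sum() == pytest.approx(1.0)

    def test_weighted_shares(self):
        out = land_area_distribution(np.array([5.0, 15.0]),
                                     np.array([10.0, 30.0]),
                                     np.array([0.0, 10.0, 20.0]))
        assert out["land_share"].tolist() == pytest.approx([0.25, 0.75, 0.0])

    def test_open_top_class(self):
        out = land_area_distribution(np.array([250.0]), np.array([5.0]),
                                     np.array([0.0, 100.0]))
        assert out["land_share"].iloc[-1] == pytest.approx(1.0)
        assert out["class"].iloc[-1].startswith(">=")

    def test_unprotected_and_undefined_cells_ignored(self):
        vals = np.array([5.0, np.nan, 5.0])
        land = np.array([10.0, 50.0, 0.0])
        out = land_area_distribution(vals, land, np.array([0.0, 10.0]))
        assert out["land_share"].sum() == pytest.approx(1.0)

    def test_unordered_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            land_area_distribution(np.array([1.0]), np.array([1.0]),
                                   np.array([10.0, 0.0]))


class TestComparePeriods:
    def test_no_change_outcome(self):
        ref = np.array([3.0, 4.0, 5.0])
        res = compare_periods(ref, ref.copy())
        assert res.no_change
        assert res.statistic is None

    def test_hand_ranked_statistic(self):
        # differences (+1, +2, +3, -1): |d| ranks with a midrank tie between
        # the two 1s -> V = 1.5 + 3 + 4 = 8.5
        ref = np.zeros(4)
        fut = np.array([1.0, 2.0, 3.0, -1.0])
        res = compare_periods(ref, fut)
        assert res.statistic == pytest.approx(8.5)
        assert res.n_used == 4

    def test_uniform_shift_exact_null(self):
        ref = np.arange(20, dtype=float)
        res = compare_periods(ref, ref + 1.0)
        assert res.statistic == pytest.approx(210.0)  # n(n+1)/2
        assert res.p_value < 0.05
        assert res.median_shift == 1.0

    def test_zero_differences_dropped(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        fut = np.array([1.0, 2.0, 5.0, 6.0])
        res = compare_periods(ref, fut)
        assert res.n_used == 2 and res.n_zero == 2

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compare_periods(np.array([1.0]), np.array([1.0]))


class TestSummarize:
    def test_constant_values(self):
        s = summarize([5.0, 5.0, 5.0])
        assert (s.mean, s.sd, s.median, s.mad) == (5.0, 0.0, 5.0, 0.0)

    def test_outlier_robustness(self):
        s = summarize([1.0, 2.0, 3.0, 4.0, 100.0])
        assert s.median == 3.0
        assert s.mad == 1.0   # |x - 3| = (2, 1, 0, 1, 97) -> median 1
        assert s.mean == pytest.approx(22.0)

    def test_single_value(self):
        s = summarize([7.5])
        assert s.mean == 7.5 and s.sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestImpactTable:
    def _setup(self):
        grid = make_grid(4, 4, 10.0)
        hierarchy = synthetic.simulate_region_hierarchy(grid, 2, 2, seed=1)
        rng = np.random.default_rng(3)
        species = [f"s{i}" for i in range(8)]
        ref = pd.DataFrame(rng.integers(0, 2, (8, 16)), index=species)
        fut = pd.DataFrame(rng.integers(0, 2, (8, 16)), index=species)
        pa_set = synthetic.simulate_protected_areas(grid, 12, seed=2,
                                                    size_cap=40.0,
                                                    median_area=3.0)
        from nicheshift.overlay import build_overlay
        index = build_overlay(list(pa_set.areas), grid)
        return index, hierarchy, ref, fut

    def test_richness_identity_and_bounds(self):
        index, hierarchy, ref, fut = self._setup()
        table = metrics.impact_table(index, hierarchy, ref, fut)
        assert (table["futureSR"] ==
                table["refSR"] + table["G"] - table["L"]).all()
        assert (table["L"] <= table["refSR"]).all()
        defined = table["T"].dropna()
        assert ((defined >= 0) & (defined <= 100)).all()

    def test_representativity_nonincreasing_with_scale(self):
        index, hierarchy, ref, fut = self._setup()
        table = metrics.impact_table(index, hierarchy, ref, fut)
        for period in ("reference", "future"):
            r = table[[f"repr_region_{period}",
                       f"repr_province_{period}",
                       f"repr_study_area_{period}"]].to_numpy()
            ok = ~np.isnan(r).any(axis=1)
            assert (np.diff(r[ok], axis=1) <= 1e-12).all()

    def test_degenerate_hierarchy_collapses_scales(self):
        grid = make_grid(4, 4, 10.0)
        hierarchy = synthetic.simulate_region_hierarchy(grid, 1, 1, seed=1)
        rng = np.random.default_rng(5)
        species = [f"s{i}" for i in range(5)]
        ref = pd.DataFrame(rng.integers(0, 2, (5, 16)), index=species)
        fut = pd.DataFrame(rng.integers(0, 2, (5, 16)), index=species)
        pa_set = synthetic.simulate_protected_areas(grid, 5, seed=2,
                                                    size_cap=40.0,
                                                    median_area=3.0)
        from nicheshift.overlay import build_overlay
        index = build_overlay(list(pa_set.areas), grid)
        table = metrics.impact_table(index, hierarchy, ref, fut)
        for period in ("reference", "future"):
            assert np.allclose(table[f"repr_region_{period}"],
                               table[f"repr_study_area_{period}"],
                               equal_nan=True)
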