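"""Synthetic landscape generator: grid geometry, climate, species, protected
areas and the region hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicheshift import synthetic
from nicheshift.grid import make_grid
from nicheshift.synthetic import (FUTURE, REFERENCE, GradientSpec,
                                  VirtualSpecies)


class TestGrid:
    def test_single_cell_grid(self):
        g = make_grid(1, 1, 20.0)
        assert g.n_cells == 1
        assert g.cell_area == 400.0

    def test_row_major_ids(self):
        g = make_grid(10, 12, 20.0)
        assert g.n_cells == 120
        assert g.cell_id(0, 0) == 0
        assert g.cell_id(9, 11) == 119

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 40), st.integers(1, 40))
    def test_id_rowcol_bijection(self, n_rows, n_cols):
        g = make_grid(n_rows, n_cols, 5.0)
        for cid in range(g.n_cells):
            assert g.cell_id(*g.rowcol(cid)) == cid

    def test_shared_edge_belongs_to_one_cell(self):
        g = make_grid(1, 2, 20.0)
        # x = 20 is the shared edge of cells 0 and 1: half-open convention
        assert g.point_to_cell(20.0, 10.0) == 1
        assert g.point_to_cell(20.0 - 1e-9, 10.0) == 0

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_grid(0, 5, 20.0)
        with pytest.raises(ValueError):
            make_grid(5, 5, 0.0)


class TestClimate:
    def test_noise_free_gradient_is_monotone_in_row(self, small_grid,
                                                    noisefree_climate):
        temp = noisefree_climate.values("temp", REFERENCE)
        per_row = temp.reshape(small_grid.n_rows, small_grid.n_cols)
        assert (np.diff(per_row[:, 0]) > 0).all()
        # every cell in a row has the identical value (no noise)
        assert (per_row.std(axis=1) == 0).all()

    def test_warming_offset_applied_to_flagged_variable_only(
            self, noisefree_climate):
        d_temp = (noisefree_climate.values("temp", FUTURE)
                  - noisefree_climate.values("temp", REFERENCE))
        d_precip = (noisefree_climate.values("precip", FUTURE)
                    - noisefree_climate.values("precip", REFERENCE))
        assert np.allclose(d_temp, 3.0)
        assert np.allclose(d_precip, 0.0)

    def test_same_seed_is_bit_identical(self, small_grid):
        grads = synthetic.default_gradients(3.0)
        a = synthetic.simulate_climate(small_grid, grads, seed=42)
        b = synthetic.simulate_climate(small_grid, grads, seed=42)
        for key in a.layers:
            assert (a.layers[key] == b.layers[key]).all()

    def test_column_axis_gradient(self, small_grid, noisefree_climate):
        precip = noisefree_climate.values("precip", REFERENCE)
        per_row = precip.reshape(small_grid.n_rows, small_grid.n_cols)
        assert (np.diff(per_row[0, :]) > 0).all()

    def test_single_variable_rejected(self, small_grid):
        with pytest.raises(ValueError, match="at least 2"):
            synthetic.simulate_climate(
                small_grid, {"temp": GradientSpec(0.0, 1.0)}, seed=1)


class TestVirtualSpecies:
    def test_step_like_niche_sampled_exactly(self, small_grid,
                                             noisefree_climate):
        # a tiny breadth makes suitability ~1 on the optimum row, ~0 off it;
        # at sampling rate 1 the sampled occurrences equal the true range
        temp_row4 = noisefree_climate.values("temp", REFERENCE)[
            small_grid.cell_id(4, 0)]
        sp = VirtualSpecies("sp_step", "bird", {"temp": temp_row4},
                            {"temp": 0.01}, sampling_rate=1.0)
        suit = sp.true_suitability(noisefree_climate, REFERENCE)
        expected = np.flatnonzero(small_grid.rows() == 4)
        assert set(np.flatnonzero(suit > 0.5)) == set(expected)

    def test_suitability_peak_at_cell_nearest_optimum(self, small_grid,
                                                      noisefree_climate):
        temps = noisefree_climate.values("temp", REFERENCE)
        sp = VirtualSpecies("sp", "bird", {"temp": 3.4}, {"temp": 2.0})
        suit = sp.true_suitability(noisefree_climate, REFERENCE)
        nearest = np.abs(temps - 3.4).min()
        assert np.isclose(np.abs(temps[suit.argmax()] - 3.4), nearest)

    def test_immigrant_species_gains_range_under_warming(
            self, small_grid, noisefree_climate):
        # thermal optimum above the warmest reference cell: empty reference
        # range, non-empty future range once warming (+3) brings it inside
        warmest = noisefree_climate.values("temp", REFERENCE).max()
        sp = VirtualSpecies("sp_im", "bird", {"temp": warmest + 2.0},
                            {"temp": 0.6})
        ref = sp.true_suitability(noisefree_climate, REFERENCE)
        fut = sp.true_suitability(noisefree_climate, FUTURE)
        assert (ref >= 0.5).sum() == 0
        assert (fut >= 0.5).sum() > 0

    def test_sampling_rate_zero_yields_no_presences(self, small_grid,
                                                    noisefree_climate):
        _, occ = synthetic.simulate_species(
            small_grid, noisefree_climate, {"bird": 3}, sampling_rate=0.0,
            seed=5)
        assert occ["presence"].sum() == 0

    def test_sampling_rate_out_of_range_rejected(self, small_grid,
                                                 noisefree_climate):
        with pytest.raises(ValueError, match="sampling rate"):
            synthetic.simulate_species(small_grid, noisefree_climate,
                                       {"bird": 1}, sampling_rate=1.5,
                                       seed=5)

    def test_tree_species_depend_on_soil(self, small_grid,
                                         noisefree_climate):
        soil = synthetic.simulate_soil(small_grid, seed=3)
        species, _ = synthetic.simulate_species(
            small_grid, noisefree_climate, {"tree": 4}, seed=6, soil=soil)
        sp = species[0]
        assert sp.soil_preference is not None
        suit = sp.true_suitability(noisefree_climate, REFERENCE, soil=soil)
        bad = ~np.isin(soil["deposit"].to_numpy(),
                       sp.soil_preference["deposit"])
        good_suit = sp.true_suitability(noisefree_climate, REFERENCE,
                                        soil=soil.assign(
                                            deposit=sp.soil_preference[
                                                "deposit"][0],
                                            drainage=sp.soil_preference[
                                                "drainage"][0]))
        assert (suit[bad] <= good_suit[bad] + 1e-12).all()

    def test_determinism(self, small_grid, noisefree_climate):
        a = synthetic.simulate_species(small_grid, noisefree_climate,
                                       {"bird": 3}, seed=9)
        b = synthetic.simulate_species(small_grid, noisefree_climate,
                                       {"bird": 3}, seed=9)
        assert a[1].equals(b[1])


class TestProtectedAreas:
    def test_size_distribution_mostly_below_cap(self, small_grid):
        pa_set = synthetic.simulate_protected_areas(small_grid, 200, seed=4)
        below = sum(1 for a in pa_set.areas if a.area < pa_set.size_cap)
        assert below >= 190

    def test_polygons_inside_extent(self, small_grid):
        pa_set = synthetic.simulate_protected_areas(small_grid, 100, seed=4)
        x0, y0, x1, y1 = small_grid.extent
        for pa in pa_set.areas:
            bx0, by0, bx1, by1 = pa.polygon.bounds
            assert bx0 >= x0 and by0 >= y0 and bx1 <= x1 and by1 <= y1

    def test_same_seed_identical(self, small_grid):
        a = synthetic.simulate_protected_areas(small_grid, 50, seed=8)
        b = synthetic.simulate_protected_areas(small_grid, 50, seed=8)
        assert all(p.polygon.equals(q.polygon) and p.pa_id == q.pa_id
                   for p, q in zip(a.areas, b.areas))

    def test_cap_larger_than_extent_rejected(self):
        tiny = make_grid(2, 2, 1.0)
        with pytest.raises(ValueError, match="cap"):
            synthetic.simulate_protected_areas(tiny, 10, size_cap=100.0,
                                               seed=1)


class TestRegionHierarchy:
    def test_band_partition_counts_and_nesting(self):
        g = make_grid(10, 10, 20.0)
        h = synthetic.simulate_region_hierarchy(g, 2, 2, seed=1)
        assert h.n_provinces == 2
        assert h.n_regions == 4
        # brute force: every cell's region lies in its province
        for cid in range(g.n_cells):
            region = h.region_of[cid]
            members = np.flatnonzero(h.region_of == region)
            assert np.unique(h.province_of[members]).size == 1
            assert h.province_of[members][0] == h.province_of[cid]

    def test_degenerate_single_region(self, small_grid):
        h = synthetic.simulate_region_hierarchy(small_grid, 1, 1, seed=1)
        assert h.n_provinces == 1 and h.n_regions == 1

    def test_more_provinces_than_rows_rejected(self):
        g = make_grid(3, 10, 20.0)
        with pytest.raises(ValueError, match="provinces"):
            synthetic.simulate_region_hierarchy(g, 5, 1, seed=1)

    def test_voronoi_mode_nests(self, small_grid):
        h = synthetic.simulate_region_hierarchy(small_grid, 3, 2, seed=2,
                                                method="voronoi")
        df = h.to_frame()
        assert (df.groupby("region_id")["province_id"].nunique() == 1).all()
        assert set(df["cell_id"]) == set(range(small_grid.n_cells))


class TestGroundTruthParadox:
    def test_northern_richness_does_not_decrease_under_warming(self):
        """With a monotone latitudinal gradient, uniform warming and niches
        fixed in climate space, total true-range richness over the northern
        half is at least its reference value."""
        grid = make_grid(30, 20, 20.0)
        climate = synthetic.simulate_climate(
            grid, synthetic.default_gradients(3.0), seed=21)
        species, _ = synthetic.simulate_species(grid, climate,
                                                seed=22, soil=None,
                                                n_per_taxon={"bird": 15,
                                                             "amphibian": 5,
                                                             "other_plant":
                                                                 15})
        maps = synthetic.true_presence_maps(species, climate)
        north = grid.northern_band(0.5)
        ref = sum(m[REFERENCE][north].sum() for m in maps.values())
        fut = sum(m[FUTURE][north].sum() for m in maps.values())
        assert fut >= ref
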