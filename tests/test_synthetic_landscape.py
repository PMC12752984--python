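"""Synthetic landscape generator: bounds, determinism, geometric oracles."""

import numpy as np
import pytest
from scipy import ndimage

import terravalue as tv
from terravalue.synthetic_landscape import RING_LABELS_5


class TestGridSpec:
    def test_cell_area(self):
        assert tv.GridSpec(10, 10, cell_size=30.0).cell_area_hm2 == pytest.approx(0.09)

    @pytest.mark.parametrize("nrows,ncols,cell", [(0, 5, 30), (5, 0, 30), (5, 5, 0)])
    def test_invalid_grid_rejected(self, nrows, ncols, cell):
        with pytest.raises(ValueError):
            tv.GridSpec(nrows, ncols, cell_size=cell)


class TestGenerateField:
    def test_exact_bounds_slope_range(self):
        grid = tv.GridSpec(50, 50)
        layer = tv.generate_field(grid, 0.0, 28.0476, corr_length=300, seed=1)
        assert layer.values.min() == pytest.approx(0.0, abs=1e-9)
        assert layer.values.max() == pytest.approx(28.0476, abs=1e-9)

    def test_zero_corr_length_is_rescaled_white_noise(self):
        grid = tv.GridSpec(30, 30)
        layer = tv.generate_field(grid, 2.0, 5.0, corr_length=0, seed=3)
        assert layer.values.min() == pytest.approx(2.0)
        assert layer.values.max() == pytest.approx(5.0)
        # white noise: negligible spatial autocorrelation between neighbours
        a, b = layer.values[:, :-1].ravel(), layer.values[:, 1:].ravel()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.15

    def test_deterministic_per_seed(self):
        grid = tv.GridSpec(20, 20)
        a = tv.generate_field(grid, 0, 1, 300, seed=7)
        b = tv.generate_field(grid, 0, 1, 300, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = tv.generate_field(grid, 0, 1, 300, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="lo must be below hi"):
            tv.generate_field(tv.GridSpec(5, 5), 2.0, 2.0, 100, seed=0)


class TestGenerateCategorical:
    def test_legend_respected(self):
        classes = tv.hefei2021.CONCEPTUAL_CATEGORIES["I1"]  # 7 terrain classes
        layer = tv.generate_categorical(tv.GridSpec(40, 40), classes, 300, seed=2)
        assert set(np.unique(layer.class_ids)) <= set(range(1, 8))
        assert layer.legend[1] == "Impact Plains"

    def test_single_class_constant(self):
        layer = tv.generate_categorical(tv.GridSpec(10, 10), ["only"], 300, seed=0)
        assert (layer.class_ids == 1).all()

    def test_seed_contract(self):
        grid = tv.GridSpec(30, 30)
        a = tv.generate_categorical(grid, ["x", "y", "z"], 200, seed=1)
        b = tv.generate_categorical(grid, ["x", "y", "z"], 200, seed=2)
        assert a.legend == b.legend
        assert not np.array_equal(a.class_ids, b.class_ids)

    def test_empty_legend_rejected(self):
        with pytest.raises(ValueError):
            tv.generate_categorical(tv.GridSpec(5, 5), [], 300, seed=0)

    def test_patches_are_contiguous(self):
        layer = tv.generate_categorical(tv.GridSpec(40, 40), ["a", "b", "c"],
                                        400, seed=5)
        # few connected components per class relative to class area
        for cid in np.unique(layer.class_ids):
            _, n = ndimage.label(layer.class_ids == cid)
            assert n <= 6


class TestDistanceTransform:
    def test_adjacent_and_target_cells(self):
        grid = tv.GridSpec(5, 5, cell_size=30.0)
        ids = np.ones(grid.shape, dtype=int)
        ids[2, 2] = 2
        mask = tv.CategoricalLayer(grid, ids, {1: "other", 2: "water"})
        d = tv.distance_transform(mask, 2)
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(30.0)
        assert d.values[1, 2] == pytest.approx(30.0)
        assert d.values[0, 0] == pytest.approx(30.0 * np.hypot(2, 2))

    def test_absent_target_rejected(self):
        grid = tv.GridSpec(4, 4)
        mask = tv.CategoricalLayer(grid, np.ones(grid.shape, dtype=int), {1: "x"})
        with pytest.raises(ValueError, match="does not occur"):
            tv.distance_transform(mask, 99)

    def test_matches_brute_force_all_pairs(self, rng):
        """Independent oracle: minimum centre-to-centre distance over all
        target cells, computed by exhaustive loops."""
        grid = tv.GridSpec(12, 12, cell_size=30.0)
        ids = rng.choice([1, 2], size=grid.shape, p=[0.9, 0.1])
        ids[0, 0] = 2  # ensure presence
        mask = tv.CategoricalLayer(grid, ids, {1: "other", 2: "target"})
        d = tv.distance_transform(mask, 2).values
        targets = np.argwhere(ids == 2)
        for r in range(grid.nrows):
            for c in range(grid.ncols):
                brute = min(
                    np.hypot(r - tr, c - tc) * 30.0 for tr, tc in targets
                )
                assert d[r, c] == pytest.approx(brute, abs=1e-9)


class TestRingClassify:
    def test_boundaries_and_saturation(self):
        grid = tv.GridSpec(1, 4, cell_size=30.0)
        vals = np.array([[0.0, 499.9, 500.0, 10_000.0]])
        layer = tv.IndicatorLayer(grid, "d", vals)
        rings = tv.ring_classify(layer, ring_width=500, n_rings=5)
        assert rings.class_ids.tolist() == [[1, 1, 2, 5]]
        assert rings.legend == dict(enumerate(RING_LABELS_5, start=1))

    def test_negative_distance_rejected(self):
        layer = tv.IndicatorLayer(tv.GridSpec(1, 1), "d", np.array([[-1.0]]))
        with pytest.raises(ValueError):
            tv.ring_classify(layer)


def _layers(grid, landuse, soil, admin):
    mk = lambda a: tv.CategoricalLayer(
        grid, a, {int(i): str(i) for i in np.unique(a)}
    )
    return mk(landuse), mk(soil), mk(admin)


class TestBuildEvaluationUnits:
    def test_constant_layers_single_unit(self):
        grid = tv.GridSpec(6, 6)
        ones = np.ones(grid.shape, dtype=int)
        lu, so, ad = _layers(grid, ones, ones, ones)
        units = tv.build_evaluation_units(lu, so, ad, min_area_hm2=0)
        assert units.n_units == 1
        assert units.total_area_hm2 == pytest.approx(36 * 0.09)

    def test_admin_split_conserves_area(self):
        grid = tv.GridSpec(6, 6)
        ones = np.ones(grid.shape, dtype=int)
        admin = np.ones(grid.shape, dtype=int)
        admin[:, 3:] = 2
        lu, so, ad = _layers(grid, ones, ones, admin)
        units = tv.build_evaluation_units(lu, so, ad, min_area_hm2=0)
        assert units.n_units == 2
        assert units.units["area_hm2"].sum() == pytest.approx(36 * 0.09)
        assert sorted(units.units["region_id"]) == [1, 2]

    def test_matches_flood_fill_oracle(self, rng):
        """Unit count equals connected same-triple components found by an
        independent stack-based flood fill."""
        grid = tv.GridSpec(20, 20)
        lu = rng.integers(1, 3, grid.shape)
        so = rng.integers(1, 3, grid.shape)
        ad = rng.integers(1, 3, grid.shape)
        units = tv.build_evaluation_units(*_layers(grid, lu, so, ad),
                                          min_area_hm2=0)
        triple = lu * 100 + so * 10 + ad
        seen = np.zeros(grid.shape, dtype=bool)
        n_components = 0
        for r0 in range(20):
            for c0 in range(20):
                if seen[r0, c0]:
                    continue
                n_components += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < 20 and 0 <= cc < 20 and not seen[rr, cc]
                                and triple[rr, cc] == triple[r, c]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
        assert units.n_units == n_components

    def test_sliver_merged_into_largest_neighbour(self):
        grid = tv.GridSpec(4, 4)
        ones = np.ones(grid.shape, dtype=int)
        soil = np.ones(grid.shape, dtype=int)
        soil[0, 0] = 2  # single-cell sliver (0.09 hm2 < 0.36)
        lu, so, ad = _layers(grid, ones, soil, ones)
        units = tv.build_evaluation_units(lu, so, ad, min_area_hm2=0.36)
        assert units.n_units == 1
        assert units.total_area_hm2 == pytest.approx(16 * 0.09)

    def test_grid_mismatch_rejected(self):
        a = tv.CategoricalLayer(tv.GridSpec(4, 4), np.ones((4, 4), int), {1: "x"})
        b = tv.CategoricalLayer(tv.GridSpec(5, 5), np.ones((5, 5), int), {1: "x"})
        with pytest.raises(ValueError, match="share"):
            tv.build_evaluation_units(a, b, a)


class TestGenerateLandscape:
    def test_ranges_equal_configured_bounds(self, small_landscape):
        ranges = tv.hefei2021.indicator_value_ranges()
        for iid, (lo, hi) in ranges.items():
            layer = small_landscape.indicators[iid]
            assert layer.values.min() == pytest.approx(lo, abs=1e-9)
            assert layer.values.max() == pytest.approx(hi, abs=1e-9)

    def test_bundle_is_complete(self, small_landscape):
        assert set(small_landscape.indicators) == set(tv.hefei2021.INDICATOR_IDS)
        assert small_landscape.units.n_units >= 5

    def test_unit_area_conservation(self, small_landscape):
        farm_cells = int(
            np.isin(small_landscape.landuse.class_ids, [1]).sum()
        )
        expected = farm_cells * small_landscape.grid.cell_area_hm2
        assert small_landscape.units.total_area_hm2 == pytest.approx(expected)
        # labels restricted to farmland cells
        assert ((small_landscape.units.labels > 0)
                == (small_landscape.landuse.class_ids == 1)).all()

    def test_deterministic_bundle(self):
        cfg = tv.LandscapeConfig(grid=tv.GridSpec(15, 15), patch_scale_m=100.0)
        a = tv.generate_landscape(cfg, seed=5)
        b = tv.generate_landscape(cfg, seed=5)
        for iid in a.indicators:
            la, lb = a.indicators[iid], b.indicators[iid]
            va = getattr(la, "values", None)
            if va is not None:
                np.testing.assert_array_equal(va, lb.values)
            else:
                np.testing.assert_array_equal(la.class_ids, lb.class_ids)
        np.testing.assert_array_equal(a.units.labels, b.units.labels)
        assert a.units.units.equals(b.units.units)

    def test_degenerate_single_cell_grid(self):
        cfg = tv.LandscapeConfig(grid=tv.GridSpec(1, 1))
        scape = tv.generate_landscape(cfg, seed=0)
        assert scape.units.n_units == 1
        for layer in scape.indicators.values():
            assert layer.grid.shape == (1, 1)
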