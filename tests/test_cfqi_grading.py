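"""Quality index, natural breaks and area tabulation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import terravalue as tv
from terravalue import hefei2021


def partition_ssd(groups) -> float:
    return sum(
        float(((np.asarray(g) - np.mean(g)) ** 2).sum()) for g in groups if len(g)
    )


def brute_force_best_ssd(values: np.ndarray, k: int) -> float:
    """Exhaustive search over all contiguous splits of the sorted values."""
    v = np.sort(values)
    n = len(v)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        idx = [0, *cuts, n]
        groups = [v[idx[i]:idx[i + 1]] for i in range(k)]
        best = min(best, partition_ssd(groups))
    return best


def scheme_ssd(values: np.ndarray, scheme: tv.GradeScheme) -> float:
    grades = tv.classify(pd.Series(values), scheme)
    assert not grades.isna().any()
    return partition_ssd([values[grades == g] for g in range(1, scheme.k + 1)])


class TestZonalMean:
    def _unit_map(self):
        grid = tv.GridSpec(2, 2)
        labels = np.array([[1, 1], [2, 2]])
        units = pd.DataFrame(
            {"unit_id": [1, 2], "region_id": 1, "soil_id": 1, "landuse_id": 1,
             "area_hm2": 0.18}
        )
        return grid, tv.UnitMap(grid, labels, units)

    def test_constant_layer(self):
        grid, um = self._unit_map()
        sl = tv.ScoreLayer(grid, "x", np.full(grid.shape, 0.7),
                           np.zeros(grid.shape, bool))
        assert tv.zonal_mean(sl, um).tolist() == pytest.approx([0.7, 0.7])

    def test_two_cell_mean(self):
        grid, um = self._unit_map()
        sl = tv.ScoreLayer(grid, "x", np.array([[0.2, 0.4], [0.6, 0.8]]),
                           np.zeros(grid.shape, bool))
        assert tv.zonal_mean(sl, um).tolist() == pytest.approx([0.3, 0.7])

    def test_all_nodata_unit_flagged_nan(self):
        grid, um = self._unit_map()
        mask = np.array([[True, True], [False, False]])
        sl = tv.ScoreLayer(grid, "x", np.full(grid.shape, 0.5), mask)
        out = tv.zonal_mean(sl, um)
        assert np.isnan(out[1]) and out[2] == 0.5

    def test_matches_naive_per_unit_loop(self, rng):
        """Independent oracle: accumulate each unit's cells in a loop."""
        cfg = tv.LandscapeConfig(grid=tv.GridSpec(20, 20), patch_scale_m=100.0)
        scape = tv.generate_landscape(cfg, seed=11)
        scores = rng.uniform(0, 1, scape.grid.shape)
        sl = tv.ScoreLayer(scape.grid, "x", scores,
                           np.zeros(scape.grid.shape, bool))
        out = tv.zonal_mean(sl, scape.units)
        for uid in scape.units.units["unit_id"]:
            cells = scores[scape.units.labels == uid]
            assert out[uid] == pytest.approx(cells.mean(), abs=1e-12)


class TestComputeIfi:
    def test_half_weights(self):
        scores = pd.DataFrame({"a": [1.0], "b": [0.0]})
        w = pd.Series({"a": 0.5, "b": 0.5})
        assert tv.compute_ifi(scores, w).iloc[0] == pytest.approx(0.5)

    def test_perfect_scores_with_reference_weights(self):
        w = tv.hefei_weights()
        scores = pd.DataFrame(
            np.ones((3, 16)), columns=list(w.index)
        )
        np.testing.assert_allclose(tv.compute_ifi(scores, w), 0.9999)

    def test_zero_scores(self):
        w = tv.hefei_weights()
        scores = pd.DataFrame(np.zeros((2, 16)), columns=list(w.index))
        np.testing.assert_allclose(tv.compute_ifi(scores, w), 0.0)

    def test_missing_indicator_named(self):
        w = pd.Series({"a": 0.5, "I9": 0.5})
        with pytest.raises(KeyError, match="I9"):
            tv.compute_ifi(pd.DataFrame({"a": [1.0]}), w)


class TestJenksBreaks:
    def test_obvious_two_cluster_split(self):
        scheme = tv.jenks_breaks([1, 2, 3, 100, 101, 102], k=2)
        grades = tv.classify(pd.Series([1, 2, 3, 100, 101, 102]), scheme)
        assert grades.tolist() == [2, 2, 2, 1, 1, 1]

    def test_single_class_spans_range(self):
        scheme = tv.jenks_breaks([4.0, 1.0, 2.5], k=1)
        assert scheme.intervals == ((1.0, 4.0),)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tv.jenks_breaks([1.0, 1.0, 2.0], k=3)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(2, 5))
        values = np.round(rng.uniform(0, 10, n), 3)
        if len(np.unique(values)) < k:
            pytest.skip("degenerate draw")
        scheme = tv.jenks_breaks(values, k)
        assert scheme_ssd(values, scheme) == pytest.approx(
            brute_force_best_ssd(values, k), abs=1e-9
        )

    def test_beats_equal_interval_classification(self, rng):
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(8, 1, 40)])
        scheme = tv.jenks_breaks(values, 4)
        edges = np.linspace(values.min(), values.max(), 5)
        eq_groups = [
            values[(values >= lo) & (values <= hi)]
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert scheme_ssd(values, scheme) <= partition_ssd(eq_groups) + 1e-9


class TestClassify:
    SCHEME = tv.hefei_grade_scheme()

    @pytest.mark.parametrize(
        "ifi,grade",
        [(0.70, 1), (0.7499, 1), (0.6477, 1), (0.6476, 2), (0.3962, 5)],
    )
    def test_reference_scheme_boundaries(self, ifi, grade):
        out = tv.classify(pd.Series([ifi]), self.SCHEME)
        assert out.iloc[0] == grade

    def test_out_of_range_flagged_ungraded(self):
        out = tv.classify(pd.Series([0.1, 0.9]), self.SCHEME)
        assert out.isna().all()

    def test_monotone_in_ifi(self, rng):
        x = pd.Series(rng.uniform(0.3962, 0.7499, 300))
        g = tv.classify(x, self.SCHEME)
        order = np.argsort(x.to_numpy())
        assert (np.diff(g.to_numpy()[order]) <= 0).all()

    def test_alternate_scheme_differs(self):
        alt = tv.hefei_grade_scheme(alternate=True)
        assert alt.intervals != self.SCHEME.intervals
        assert tv.classify(pd.Series([0.60]), alt).iloc[0] == 2


class TestTabulateAreas:
    def test_two_unit_example(self):
        grid = tv.GridSpec(1, 2, cell_size=100.0)  # 1 hm2 cells
        labels = np.array([[1, 2]])
        units = tv.UnitMap(
            grid, labels,
            pd.DataFrame({"unit_id": [1, 2], "region_id": 1, "soil_id": 1,
                          "landuse_id": 1, "area_hm2": 1.0}),
        )
        grades = pd.Series([1.0, 5.0], index=pd.Index([1, 2], name="unit_id"))
        table = tv.tabulate_areas(grades, units)
        assert table.loc[1, 1] == 1.0 and table.loc[1, 5] == 1.0
        assert float(table.sum().sum()) == 2.0

    def test_reference_fixture_marginals(self):
        table = hefei2021.grade_area_table()
        np.testing.assert_allclose(
            table.sum(axis=0), hefei2021.PRINTED_GRADE_TOTALS_HM2, atol=0.5
        )
        assert float(table.to_numpy().sum()) == pytest.approx(
            hefei2021.PRINTED_TOTAL_AREA_HM2, abs=0.5
        )

    def test_double_marginal_conservation(self, small_landscape):
        ifi = pd.Series(
            np.linspace(0.3, 0.8, small_landscape.units.n_units),
            index=pd.Index(small_landscape.units.units["unit_id"],
                           name="unit_id"),
        )
        scheme = tv.jenks_breaks(ifi.to_numpy(), 5)
        grades = tv.classify(ifi, scheme)
        table = tv.tabulate_areas(grades, small_landscape.units)
        total = small_landscape.units.total_area_hm2
        assert float(table.sum(axis=0).sum()) == pytest.approx(total, abs=1e-6)
        assert float(table.sum(axis=1).sum()) == pytest.approx(total, abs=1e-6)

    def test_ungraded_units_rejected(self):
        grid = tv.GridSpec(1, 1)
        units = tv.UnitMap(
            grid, np.array([[1]]),
            pd.DataFrame({"unit_id": [1], "region_id": 1, "soil_id": 1,
                          "landuse_id": 1, "area_hm2": 0.09}),
        )
        with pytest.raises(ValueError, match="ungraded"):
            tv.tabulate_areas(pd.Series([np.nan], index=[1]), units)
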