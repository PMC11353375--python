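import numpy as np
import pytest
from hypothesis import given, strategies as st

from cdmifuse.grid import GridSpec, ValidationError
from cdmifuse.maps import ADCMap, SUVMap
from cdmifuse.plausibility import (
    PlausibilityCounts,
    PlausibilityRuleSet,
    VoxelScatter,
    backmap,
    classify,
    default_rules,
    distribution_shift,
    extract_scatter,
    implausible_reduction,
    scatter_plot,
)


def brute_force_cell(adc, suv, rules):
    """Independent per-voxel rule walk (the oracle for the vectorized path)."""
    a1, a2 = rules.adc_edges
    s1, s2 = rules.suv_edges
    if adc < a1:
        i = 0
    elif adc < a2:
        i = 1
    else:
        i = 2
    if suv < s1:
        j = 0
    elif suv < s2:
        j = 1
    else:
        j = 2
    return 3 * i + j


def _scatter(adc, suv):
    n = len(adc)
    idx = np.column_stack([np.arange(n) % 8, (np.arange(n) // 8) % 8, np.zeros(n, int)])
    return VoxelScatter(np.asarray(adc, float), np.asarray(suv, float), idx)


class TestDefaultRules:
    def test_exactly_three_implausible_cells(self):
        rules = default_rules()
        assert rules.n_implausible_cells == 3
        assert set(rules.implausible_cells) == {(0, 2), (2, 2), (1, 0)}

    def test_air_cell_named_and_plausible(self):
        rules = default_rules()
        assert rules.cell_labels[0][0] == "air"
        assert rules.cell_plausible[0][0]

    def test_fluid_cell_named_and_plausible(self):
        rules = default_rules()
        assert rules.cell_labels[2][0] == "fluid"
        assert rules.cell_plausible[2][0]

    def test_edges_must_increase(self):
        with pytest.raises(ValidationError):
            PlausibilityRuleSet(adc_edges=(1600.0, 300.0))


class TestClassify:
    @pytest.mark.parametrize(
        "adc,suv,cell,plausible",
        [
            (250.0, 5.0, (0, 2), False),   # air-like ADC with avid uptake
            (1700.0, 5.0, (2, 2), False),  # fluid-like ADC with avid uptake
            (1000.0, 0.5, (1, 0), False),  # tissue ADC without uptake
            (1000.0, 5.0, (1, 2), True),   # tumor core
            (100.0, 0.2, (0, 0), True),    # air
            (2000.0, 0.2, (2, 0), True),   # fluid
        ],
    )
    def test_printed_rule_examples(self, adc, suv, cell, plausible):
        rules = default_rules()
        assert rules.bin_pair(adc, suv) == cell
        cells, counts = classify(_scatter([adc], [suv]), rules)
        assert cells[0] == rules.cell_id(*cell)
        assert counts.n_implausible == (0 if plausible else 1)

    def test_vectorized_equals_brute_force_oracle(self, rng):
        rules = default_rules()
        n = 10_000
        adc = rng.uniform(0, 2500, n)
        suv = rng.uniform(0, 8, n)
        # include exact threshold values: lower-edge-inclusive bins
        adc[:4] = [300.0, 1600.0, 300.0, 1600.0]
        suv[:4] = [1.0, 4.0, 4.0, 1.0]
        cells, counts = classify(_scatter(adc, suv), rules)
        expected = np.array([brute_force_cell(a, s, rules) for a, s in zip(adc, suv)])
        assert np.array_equal(cells, expected)
        assert counts.per_cell.sum() == n

    @given(
        adc=st.lists(st.floats(0, 5000, allow_nan=False), min_size=1, max_size=200),
    )
    def test_classification_is_total_partition(self, adc):
        rules = default_rules()
        n = len(adc)
        suv = (np.arange(n) * 0.37) % 9
        cells, counts = classify(_scatter(adc, suv), rules)
        assert counts.n_total == n
        assert counts.per_cell.sum() == n
        assert ((cells >= 0) & (cells <= 8)).all()

    def test_non_finite_pairs_excluded_not_classified(self):
        rules = default_rules()
        cells, counts = classify(_scatter([100.0, np.nan, 500.0], [1.0, 2.0, np.inf]), rules)
        assert counts.n_total == 1
        assert cells[1] == -1 and cells[2] == -1


class TestImplausibleReduction:
    def test_published_headline_counts_give_25_percent(self):
        assert round(implausible_reduction(7390, 5537)) == 25

    def test_no_change_is_zero(self):
        assert implausible_reduction(100, 100) == 0.0

    def test_halving_is_fifty_percent(self):
        assert implausible_reduction(100, 50) == 50.0

    def test_zero_before_is_not_applicable(self):
        assert np.isnan(implausible_reduction(0, 0))

    def test_accepts_counts_objects(self):
        pc = np.zeros((3, 3), int)
        pc[0, 2] = 10
        before = PlausibilityCounts(pc, 10, 10, "original")
        pc2 = np.zeros((3, 3), int)
        pc2[0, 2] = 5
        pc2[1, 1] = 5
        after = PlausibilityCounts(pc2, 10, 5, "registered")
        assert implausible_reduction(before, after) == 50.0


class TestDistributionShift:
    def test_identical_scatters_have_zero_change(self, rng):
        s = _scatter(rng.uniform(0, 2000, 50), rng.uniform(0, 6, 50))
        rep = distribution_shift(s, s)
        assert np.allclose(rep["pct_change"].dropna(), 0.0)

    def test_scaling_adc_changes_mean_by_ten_percent(self, rng):
        adc = rng.uniform(500, 1500, 50)
        suv = rng.uniform(0, 6, 50)
        rep = distribution_shift(_scatter(adc, suv), _scatter(adc * 1.1, suv))
        row = rep[(rep["parameter"] == "adc") & (rep["moment"] == "mean")]
        assert row["pct_change"].iloc[0] == pytest.approx(10.0)

    def test_tiny_samples_omit_higher_moments(self):
        rep = distribution_shift(_scatter([1.0, 2.0], [1.0, 2.0]), _scatter([1.0], [1.0]))
        skew = rep[rep["moment"] == "skewness"]["pct_change"]
        assert skew.isna().all()


class TestBackmap:
    def test_empty_voi_gives_all_zero_map(self, small_grid):
        m = backmap(np.empty(0, int), np.empty((0, 3), int), small_grid,
                    np.zeros(tuple(small_grid.shape), bool))
        assert not m.labels.any()

    def test_single_air_voxel(self, small_grid):
        voi = np.zeros(tuple(small_grid.shape), bool)
        voi[5, 6, 7] = True
        rules = default_rules()
        m = backmap(np.array([rules.cell_id(0, 0)]), np.array([[5, 6, 7]]), small_grid, voi)
        assert m.labels[5, 6, 7] == 1
        assert (m.labels != 0).sum() == 1
        assert m.legend[1]["name"] == "air"

    def test_round_trip_reproduces_direct_classification(self, small_grid, rng):
        rules = default_rules()
        shape = tuple(small_grid.shape)
        adc_vol = rng.uniform(0, 2500, shape)
        suv_vol = rng.uniform(0, 8, shape)
        voi = rng.random(shape) < 0.1
        amap = ADCMap(adc_vol, np.ones(shape, bool), small_grid)
        smap = SUVMap(suv_vol, small_grid)
        scatter = extract_scatter(amap, smap, voi)
        cells, _ = classify(scatter, rules)
        m = backmap(cells, scatter.voxel_index, small_grid, voi, rules)
        # per-voxel lookup equals direct classification
        for k in range(len(scatter)):
            i, j, l = scatter.voxel_index[k]
            assert m.labels[i, j, l] == cells[k] + 1

    def test_voxel_outside_grid_rejected(self, small_grid):
        voi = np.ones(tuple(small_grid.shape), bool)
        with pytest.raises(ValidationError):
            backmap(np.array([0]), np.array([[99, 0, 0]]), small_grid, voi)


class TestScatterPlot:
    def test_writes_nonempty_file_with_threshold_gridlines(self, tmp_path, rng):
        s = _scatter(rng.uniform(0, 2000, 64), rng.uniform(0, 6, 64))
        out = tmp_path / "scatter.png"
        fig = scatter_plot(s, out_path=out)
        assert out.exists() and out.stat().st_size > 0
        ax = fig.axes[0]
        vlines = {l.get_xdata()[0] for l in ax.lines if len(set(l.get_xdata())) == 1}
        hlines = {l.get_ydata()[0] for l in ax.lines if len(set(l.get_ydata())) == 1}
        assert {300.0, 1600.0} <= vlines
        assert {1.0, 4.0} <= hlines

    def test_overlay_mode_draws_both_datasets(self, rng):
        a = _scatter(rng.uniform(0, 2000, 32), rng.uniform(0, 6, 32))
        b = _scatter(rng.uniform(0, 2000, 32), rng.uniform(0, 6, 32))
        fig = scatter_plot(a, overlay=b)
        assert len(fig.axes[0].collections) == 2
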