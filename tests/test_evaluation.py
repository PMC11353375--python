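import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdmifuse.evaluation import (
    compare_to_expected,
    lesion_size_sweep,
    load_reference_sector_table,
    rm_anova,
    sector_statistics,
    voi_mean_shift,
)
from cdmifuse.grid import GridSpec, ValidationError
from cdmifuse.maps import ADCMap


@pytest.fixture(scope="module")
def reference_table():
    return load_reference_sector_table()


class TestRMAnova:
    def test_reference_bench_measurements_give_F_1p12(self, reference_table):
        m = reference_table[["adc_expected", "adc_unregistered", "adc_registered"]].to_numpy()
        res = rm_anova(m)
        assert round(res.F, 2) == 1.12
        assert (res.df_num, res.df_den) == (2, 10)

    def test_sum_of_squares_identity(self, rng):
        m = rng.normal(size=(7, 4)) * 100
        res = rm_anova(m)
        t = res.table.set_index("source")["SS"]
        assert t["total"] == pytest.approx(
            t["conditions"] + t["subjects"] + t["error"], rel=1e-9
        )

    def test_identical_conditions_give_zero_F(self, rng):
        col = rng.normal(size=6)
        res = rm_anova(np.column_stack([col, col, col]))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_conditions_F_equals_paired_t_squared(self, rng):
        m = rng.normal(size=(3, 2)) * 10 + 100
        res = rm_anova(m)
        t = stats.ttest_rel(m[:, 0], m[:, 1]).statistic
        assert res.F == pytest.approx(t**2, rel=1e-9)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(size=(8, 3)) * 50 + 1000
        res = rm_anova(m)
        df = pd.DataFrame(
            {
                "y": m.ravel(),
                "subject": np.repeat(np.arange(8), 3),
                "cond": np.tile(np.arange(3), 8),
            }
        )
        ora = pingouin.rm_anova(data=df, dv="y", within="cond", subject="subject")
        assert res.F == pytest.approx(float(ora["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(ora["p_unc"].iloc[0]), rel=1e-6)

    def test_incomplete_matrix_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValidationError):
            rm_anova(m)


class TestSectorStatistics:
    def test_exact_area_for_axis_aligned_rectangle(self):
        grid = GridSpec((40, 40, 10), (1.0, 1.0, 5.0))
        shape = tuple(grid.shape)
        wedges = np.zeros(shape, np.int16)
        wedges[5:25, 10:40, 2:8] = 1  # 20 x 30 mm rectangle over 6 slices
        adc = ADCMap(np.where(wedges > 0, 1000.0, 0.0), np.ones(shape, bool), grid)
        stats_ = sector_statistics(adc, wedges)
        assert stats_[0].area_mean == pytest.approx(20 * 30 / 100.0)
        assert stats_[0].area_sd == 0.0
        assert stats_[0].adc_mean == 1000.0

    def test_eighth_disc_wedge_within_two_percent(self):
        from cdmifuse.phantoms import SectorPhantomSpec, build_sector_phantom, sector_wedge_labels

        grid = GridSpec.centered((144, 144, 12), (1.0, 1.0, 4.0))
        spec = SectorPhantomSpec(height=20.0)
        scene = build_sector_phantom(spec, grid)
        wedges = sector_wedge_labels(grid, spec)
        shape = tuple(grid.shape)
        adc = ADCMap(scene.true_adc, np.ones(shape, bool), grid)
        stats_ = sector_statistics(adc, wedges, support=scene.labels > 0)
        for s in stats_:
            assert s.area_mean == pytest.approx(16.2, rel=0.02)

    def test_all_zero_map_reports_zero_areas(self, small_grid):
        shape = tuple(small_grid.shape)
        wedges = np.ones(shape, np.int16)
        adc = ADCMap(np.zeros(shape), np.ones(shape, bool), small_grid)
        stats_ = sector_statistics(adc, wedges)
        assert stats_[0].area_mean == 0.0


class TestCompareToExpected:
    def test_reference_areas_show_five_of_six_improving(self, reference_table):
        from cdmifuse.evaluation import SectorStats

        unreg = [
            SectorStats(int(r.sector), r.area_unregistered_cm2, 0, 0, 0, "unregistered")
            for r in reference_table.itertuples()
        ]
        reg = [
            SectorStats(int(r.sector), r.area_registered_cm2, 0, 0, 0, "registered")
            for r in reference_table.itertuples()
        ]
        df = compare_to_expected(unreg, reg, 16.2)
        assert df.attrs["n_improved"] == 5
        assert not df.loc[df["sector"] == 1, "improved"].iloc[0]  # sector 1 worsens

    def test_identical_conditions_are_ties(self):
        from cdmifuse.evaluation import SectorStats

        s = [SectorStats(i, 15.0, 0, 0, 0) for i in range(1, 4)]
        df = compare_to_expected(s, [SectorStats(i, 15.0, 0, 0, 0) for i in range(1, 4)], 16.2)
        assert df.attrs["n_improved"] == 0
        assert df.attrs["n_worsened"] == 0

    def test_exact_registration_improves_all_inexact_sectors(self):
        from cdmifuse.evaluation import SectorStats

        unreg = [SectorStats(i, 14.0, 0, 0, 0) for i in range(1, 4)]
        reg = [SectorStats(i, 16.2, 0, 0, 0) for i in range(1, 4)]
        df = compare_to_expected(unreg, reg, 16.2)
        assert df.attrs["n_improved"] == 3


class TestVoiMeanShift:
    def test_identical_maps_shift_zero(self, rng):
        vol = rng.uniform(1, 2, (8, 8, 8))
        voi = np.ones((8, 8, 8), bool)
        assert voi_mean_shift(vol, vol, voi) == 0.0

    def test_ten_percent_scaling(self, rng):
        vol = rng.uniform(1, 2, (8, 8, 8))
        voi = np.ones((8, 8, 8), bool)
        assert voi_mean_shift(vol, 1.1 * vol, voi) == pytest.approx(10.0)

    def test_zero_before_mean_is_nan(self):
        voi = np.ones((8, 8, 8), bool)
        assert np.isnan(voi_mean_shift(np.zeros((8, 8, 8)), np.ones((8, 8, 8)), voi))

    def test_empty_voi_rejected(self):
        with pytest.raises(ValidationError):
            voi_mean_shift(np.ones((8, 8, 8)), np.ones((8, 8, 8)), np.zeros((8, 8, 8), bool))


def test_lesion_sweep_requires_diameters_above_slice_thickness():
    with pytest.raises(ValidationError):
        lesion_size_sweep([4.0, 20.0], slice_thickness=5.0)
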