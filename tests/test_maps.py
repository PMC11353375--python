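import numpy as np
import pytest
from hypothesis import given, strategies as st

from cdmifuse.acquisition import DWISeries, simulate_dwi
from cdmifuse.grid import GridSpec, ValidationError, Volume
from cdmifuse.maps import TracerDose, compute_adc, compute_suv
from cdmifuse.phantoms import build_sphere_phantom


def _series(grid, b_values, volumes):
    return DWISeries(tuple(b_values), list(volumes), grid)


class TestComputeADC:
    def test_equal_signals_give_zero_adc_everywhere(self, small_grid):
        shape = tuple(small_grid.shape)
        s = np.full(shape, 500.0)
        amap = compute_adc(_series(small_grid, (50, 800), (s, s.copy())))
        assert not amap.values.any()
        assert amap.valid_mask.all()

    def test_analytic_two_point_inversion(self, small_grid):
        # S50 = 1000, S800 = 1000 e^-0.75 -> ADC = 1000 (1e-6 mm^2/s)
        shape = tuple(small_grid.shape)
        s50 = np.full(shape, 1000.0)
        s800 = s50 * np.exp(-0.75)
        amap = compute_adc(_series(small_grid, (50, 800), (s50, s800)))
        assert np.allclose(amap.values, 1000.0)

    def test_zero_signal_voxel_invalid_without_exception(self, small_grid):
        shape = tuple(small_grid.shape)
        s50 = np.full(shape, 1000.0)
        s800 = np.full(shape, 400.0)
        s800[3, 4, 5] = 0.0
        amap = compute_adc(_series(small_grid, (50, 800), (s50, s800)))
        assert not amap.valid_mask[3, 4, 5]
        assert amap.values[3, 4, 5] == 0.0
        assert amap.valid_mask.sum() == np.prod(shape) - 1

    def test_negative_estimates_clipped_but_valid(self, small_grid):
        shape = tuple(small_grid.shape)
        s50 = np.full(shape, 400.0)
        s800 = np.full(shape, 500.0)  # signal rose: noise-like, ADC < 0
        amap = compute_adc(_series(small_grid, (50, 800), (s50, s800)))
        assert (amap.values == 0).all()
        assert amap.valid_mask.all()

    @given(scale=st.floats(0.1, 100.0))
    def test_scale_equivariance(self, scale):
        grid = GridSpec((8, 8, 8), (2, 2, 2))
        rng = np.random.default_rng(0)
        s50 = rng.uniform(500, 1500, (8, 8, 8))
        s800 = s50 * rng.uniform(0.3, 0.9, (8, 8, 8))
        a1 = compute_adc(_series(grid, (50, 800), (s50, s800)))
        a2 = compute_adc(_series(grid, (50, 800), (s50 * scale, s800 * scale)))
        assert np.allclose(a1.values, a2.values, rtol=1e-9, atol=1e-9)

    def test_multi_b_least_squares_matches_polyfit_oracle(self, small_grid):
        shape = tuple(small_grid.shape)
        rng = np.random.default_rng(3)
        b = np.array([50.0, 400.0, 800.0])
        true_adc = rng.uniform(300, 1500, shape) * 1e-6
        s0 = rng.uniform(800, 1200, shape)
        vols = [s0 * np.exp(-bb * true_adc) for bb in b]
        amap = compute_adc(_series(small_grid, b, vols))
        # independent oracle: voxel-wise polyfit slope
        flat = np.stack([np.log(v).ravel() for v in vols])
        slope = np.polyfit(b, flat, 1)[0]
        assert np.allclose(amap.values.ravel(), -slope * 1e6, atol=1e-6)

    def test_parameter_recovery_on_noiseless_simulation(self):
        grid = GridSpec.centered((32, 32, 32), (2.0, 2.0, 2.0))
        scene = build_sphere_phantom(40.0, 1110.0, 0.0, grid)
        dwi = simulate_dwi(scene, None, (50.0, 800.0), 0.0, grid, slice_thickness=1e-9)
        amap = compute_adc(dwi)
        inside = scene.tissue_mask
        assert np.abs(amap.values[inside] - 1110.0).max() < 1.0

    def test_noisy_recovery_of_compartment_mean(self):
        grid = GridSpec.centered((32, 32, 32), (2.0, 2.0, 2.0))
        scene = build_sphere_phantom(40.0, 1110.0, 0.0, grid)
        dwi = simulate_dwi(scene, None, (50.0, 800.0), 0.02, grid, seed=5,
                           slice_thickness=1e-9)
        amap = compute_adc(dwi)
        import scipy.ndimage as ndi

        deep = ndi.binary_erosion(scene.tissue_mask, iterations=2)
        assert amap.values[deep & amap.valid_mask].mean() == pytest.approx(1110.0, rel=0.05)


class TestComputeSUV:
    def test_uniform_dose_distribution_gives_suv_one(self, small_grid):
        dose = TracerDose(330.0, 70.0, 3600.0)
        c = dose.decayed_activity_kbq / (70.0 * 1000.0)  # kBq per mL at 1 g/mL
        suv = compute_suv(Volume(np.full(tuple(small_grid.shape), c), small_grid), dose)
        assert np.allclose(suv.values, 1.0)

    def test_zero_activity_gives_zero_suv(self, small_grid):
        dose = TracerDose(330.0, 70.0, 3600.0)
        suv = compute_suv(Volume(np.zeros(tuple(small_grid.shape)), small_grid), dose)
        assert not suv.values.any()

    def test_hand_computed_value(self, small_grid):
        # 5 kBq/mL, 330 MBq, 70 kg, 1 h uptake of 18F -> SUV ~ 1.549
        dose = TracerDose(330.0, 70.0, 3600.0)
        suv = compute_suv(Volume(np.full(tuple(small_grid.shape), 5.0), small_grid), dose)
        expected = 5.0 * 70000.0 / (330000.0 * 2 ** (-3600.0 / 6586.0))
        assert np.allclose(suv.values, expected)
        assert expected == pytest.approx(1.55, abs=0.01)

    @pytest.mark.parametrize("field", ["injected_activity", "body_weight", "uptake_interval"])
    def test_nonpositive_dose_fields_rejected(self, field):
        kwargs = dict(injected_activity=330.0, body_weight=70.0, uptake_interval=3600.0)
        kwargs[field] = 0.0
        with pytest.raises(ValidationError):
            TracerDose(**kwargs)
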