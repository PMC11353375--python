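import numpy as np
import pytest
from scipy import ndimage

from cdmifuse.acquisition import simulate_reference
from cdmifuse.distortion import DistortionModel, make_susceptibility_field
from cdmifuse.fields import apply_field, invert_field, jacobian_determinant
from cdmifuse.grid import GridSpec, ValidationError, Volume
from cdmifuse.registration import (
    RegistrationParams,
    RigidTransform,
    elastic_register,
    resample_through_rigid,
    resample_to_static,
    rigid_register,
)

FAST = RegistrationParams(iterations_per_level=(30, 20, 10))


@pytest.fixture(scope="module")
def ref(tumor_scene):
    return simulate_reference(tumor_scene)


class TestResampleToStatic:
    def test_identity_grid_returns_input_bitwise(self, ref):
        out = resample_to_static(ref, ref.grid)
        assert np.array_equal(out.data, ref.data)

    def test_constant_volume_stays_constant_in_interior(self, small_grid):
        fine = GridSpec.centered((32, 32, 32), (1.0, 1.0, 1.0))
        vol = Volume(np.full((32, 32, 32), 7.0), fine)
        out = resample_to_static(vol, small_grid, return_mask=True)
        data, inside = out
        assert np.allclose(data.data[inside], 7.0)

    def test_linear_ramp_interpolates_exactly(self):
        fine = GridSpec.centered((64, 64, 16), (1.0, 1.0, 4.0))
        coarse = GridSpec.centered((32, 32, 16), (2.0, 2.0, 4.0))
        x = fine.world_mesh()[0]
        ramp = Volume(np.broadcast_to(x, tuple(fine.shape)).copy(), fine)
        out, inside = resample_to_static(ramp, coarse, return_mask=True)
        expected = np.broadcast_to(coarse.world_mesh()[0], tuple(coarse.shape))
        err = np.abs(out.data - expected)[inside]
        assert err.max() < 1e-6 * (x.max() - x.min())


class TestRigid:
    def test_self_registration_is_identity(self, ref):
        t = rigid_register(ref, ref)
        assert np.linalg.norm(t.translation) < 0.1
        assert np.abs(np.array(t.rotation)).max() < 0.005

    def test_translation_recovery(self, ref):
        shifted_grid = GridSpec(
            ref.grid.shape, ref.grid.spacing,
            tuple(np.asarray(ref.grid.origin) + np.array([4.0, -2.0, 3.0])),
        )
        moving = Volume(ref.data, shifted_grid)
        t = rigid_register(ref, moving)
        assert np.allclose(t.translation, (4.0, -2.0, 3.0), atol=0.5)

    def test_rotation_recovery(self):
        # rotation needs an angularly structured image: off-center blobs
        grid = GridSpec.centered((48, 48, 48), (1.5, 1.5, 1.5))
        x, y, z = grid.world_mesh()
        img = (
            np.exp(-((x - 15) ** 2 + y**2 + z**2) / 50.0)
            + 0.7 * np.exp(-(x**2 + (y - 18) ** 2 + z**2) / 80.0)
            + 0.5 * np.exp(-((x + 12) ** 2 + (y + 10) ** 2 + (z - 8) ** 2) / 60.0)
        )
        static = Volume(np.broadcast_to(img, tuple(grid.shape)).copy(), grid)
        angle = np.deg2rad(5.0)
        # build the moving image by backward-sampling with -angle, so the
        # fixed-to-moving correction the registration must find is +angle
        synth = RigidTransform(rotation=(0.0, 0.0, -angle), center=tuple(grid.center))
        moving = resample_through_rigid(static, grid, synth)
        t = rigid_register(static, moving)
        assert t.rotation[2] == pytest.approx(angle, abs=np.deg2rad(0.5))

    def test_degenerate_image_warns_and_returns_identity(self, small_grid):
        const = Volume(np.zeros(tuple(small_grid.shape)), small_grid)
        with pytest.warns(UserWarning, match="degenerate"):
            t = rigid_register(const, const)
        assert t.is_identity


class TestElastic:
    def test_self_registration_displacement_below_quarter_voxel(self, ref):
        res = elastic_register(ref, ref, FAST)
        max_disp = res.field.magnitude.max()
        assert max_disp < 0.25 * min(ref.grid.spacing)

    def test_known_warp_recovery_within_one_voxel(self, tumor_scene, ref):
        truth = make_susceptibility_field(
            tumor_scene, DistortionModel(amplitude=3.0, smoothing_sigma=6.0)
        )
        moving = Volume(apply_field(truth, ref.data), ref.grid)
        res = elastic_register(ref, moving, RegistrationParams())
        truth_inv = invert_field(truth)
        resid = np.linalg.norm(
            res.field.displacement - truth_inv.displacement, axis=-1
        )
        tissue = tumor_scene.tissue_mask
        assert resid[tissue].mean() < min(ref.grid.spacing)

    def test_volume_preserving_constraint_limits_mask_volume_change(self, tumor_scene, ref):
        truth = make_susceptibility_field(
            tumor_scene, DistortionModel(amplitude=3.0, smoothing_sigma=6.0)
        )
        moving = Volume(apply_field(truth, ref.data), ref.grid)
        res = elastic_register(ref, moving, RegistrationParams())
        mask = tumor_scene.tissue_mask.astype(float)
        warped = apply_field(res.field, mask)
        change = abs(warped.sum() - mask.sum()) / mask.sum()
        assert change < 0.02
        jd = jacobian_determinant(res.field)[1:-1, 1:-1, 1:-1]
        assert 0.98 < jd.mean() < 1.02
        assert jd.min() > 0

    def test_deterministic_given_identical_inputs(self, tumor_scene, ref):
        truth = make_susceptibility_field(
            tumor_scene, DistortionModel(amplitude=2.0, smoothing_sigma=6.0)
        )
        moving = Volume(apply_field(truth, ref.data), ref.grid)
        r1 = elastic_register(ref, moving, FAST)
        r2 = elastic_register(ref, moving, FAST)
        assert np.array_equal(r1.field.displacement, r2.field.displacement)
        assert r1.metric_trace == r2.metric_trace

    def test_metric_improves_within_each_pyramid_level(self, tumor_scene, ref):
        truth = make_susceptibility_field(
            tumor_scene, DistortionModel(amplitude=2.0, smoothing_sigma=6.0)
        )
        moving = Volume(apply_field(truth, ref.data), ref.grid)
        res = elastic_register(ref, moving, FAST)
        assert len(res.metric_trace) == FAST.pyramid_levels
        for level in res.metric_trace:
            # dissimilarity may chatter, but the best value per level never
            # exceeds its starting value (the best field is what is kept)
            assert min(level) <= level[0] + 1e-9

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            RegistrationParams(pyramid_levels=0)
        with pytest.raises(ValidationError):
            RegistrationParams(iterations_per_level=(10, 10))  # mismatched levels
        with pytest.raises(ValidationError):
            RegistrationParams(convergence_tol=0.0)
        with pytest.raises(ValidationError):
            RegistrationParams(metric="ssd")
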