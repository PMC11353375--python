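import numpy as np
import pytest
from scipy import ndimage

from cdmifuse.fields import (
    DeformationField,
    apply_field,
    compose_fields,
    divergence,
    divergence_free_project,
    invert_field,
    jacobian_determinant,
    resample_field,
    zero_field,
)
from cdmifuse.grid import GridSpec, ValidationError


@pytest.fixture(scope="module")
def grid():
    return GridSpec.centered((32, 32, 32), (1.5, 1.5, 1.5))


def _coords(grid):
    x, y, z = grid.world_mesh()
    shape = tuple(grid.shape)
    return (np.broadcast_to(x, shape), np.broadcast_to(y, shape), np.broadcast_to(z, shape))


class TestDivergenceFreeProjection:
    def test_constant_field_is_fixed_point(self, grid):
        u = np.zeros(tuple(grid.shape) + (3,))
        u[..., 0] = 2.5
        p = divergence_free_project(DeformationField(u, grid))
        assert np.allclose(p.displacement, u)

    def test_pure_expansion_is_removed(self, grid):
        X, Y, Z = _coords(grid)
        u = np.stack([0.05 * X, 0.05 * Y, 0.05 * Z], axis=-1)
        p = divergence_free_project(DeformationField(u, grid))
        assert np.linalg.norm(p.displacement) < 0.01 * np.linalg.norm(u)

    def test_rotation_is_fixed_point(self, grid):
        X, Y, Z = _coords(grid)
        u = np.stack([-0.05 * Y, 0.05 * X, np.zeros_like(X)], axis=-1)
        p = divergence_free_project(DeformationField(u, grid))
        assert np.linalg.norm(p.displacement - u) < 0.01 * np.linalg.norm(u)

    def test_interior_divergence_vanishes_for_smooth_random_field(self, grid, rng):
        u = ndimage.gaussian_filter(rng.normal(size=tuple(grid.shape) + (3,)), (3, 3, 3, 0)) * 5
        f = DeformationField(u, grid)
        p = divergence_free_project(f)
        d0 = divergence(f)[1:-1, 1:-1, 1:-1]
        d1 = divergence(p)[1:-1, 1:-1, 1:-1]
        assert np.linalg.norm(d1) <= 1e-3 * np.linalg.norm(d0)

    def test_projection_is_idempotent(self, grid, rng):
        u = ndimage.gaussian_filter(rng.normal(size=tuple(grid.shape) + (3,)), (3, 3, 3, 0)) * 5
        p1 = divergence_free_project(DeformationField(u, grid))
        p2 = divergence_free_project(p1)
        assert np.allclose(p1.displacement, p2.displacement, atol=1e-10)


class TestJacobian:
    def test_zero_field_has_unit_jacobian(self, grid):
        assert np.allclose(jacobian_determinant(zero_field(grid)), 1.0)

    def test_uniform_scaling_jacobian(self, grid):
        X, Y, Z = _coords(grid)
        u = np.stack([0.01 * X, 0.01 * Y, 0.01 * Z], axis=-1)
        jd = jacobian_determinant(DeformationField(u, grid))
        assert jd[16, 16, 16] == pytest.approx(1.01**3, rel=1e-9)

    def test_projected_field_preserves_mean_volume(self, grid, rng):
        u = ndimage.gaussian_filter(rng.normal(size=tuple(grid.shape) + (3,)), (3, 3, 3, 0)) * 3
        p = divergence_free_project(DeformationField(u, grid))
        jd = jacobian_determinant(p)[1:-1, 1:-1, 1:-1]
        assert 0.99 < jd.mean() < 1.01


class TestApplyField:
    def test_zero_field_is_identity(self, grid, rng):
        vol = rng.normal(size=tuple(grid.shape))
        assert np.allclose(apply_field(zero_field(grid), vol), vol)

    def test_constant_shift_on_linear_ramp(self, grid):
        X, Y, Z = _coords(grid)
        ramp = Y.astype(float).copy()
        u = np.zeros(tuple(grid.shape) + (3,))
        u[..., 1] = 5.0
        out = apply_field(DeformationField(u, grid), ramp)
        interior = np.s_[:, 4:-4, :]
        assert np.allclose(out[interior], (Y + 5.0)[interior], atol=1e-9)

    def test_nearest_warp_preserves_label_set(self, grid, rng):
        labels = (rng.random(tuple(grid.shape)) * 4).astype(int).astype(float)
        u = ndimage.gaussian_filter(rng.normal(size=tuple(grid.shape) + (3,)), (3, 3, 3, 0)) * 2
        out = apply_field(DeformationField(u, grid), labels, interpolation="nearest")
        assert set(np.unique(out)) <= set(np.unique(labels))

    def test_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValidationError):
            apply_field(zero_field(grid), np.zeros((8, 8, 8)))


class TestComposeInvert:
    def test_inverse_composes_to_near_identity(self, grid):
        X, Y, Z = _coords(grid)
        u = np.zeros(tuple(grid.shape) + (3,))
        u[..., 1] = 2.0 * np.exp(-(X**2 + Y**2 + Z**2) / (2 * 100.0))
        f = DeformationField(u, grid)
        finv = invert_field(f)
        comp = compose_fields(f, finv)
        interior = comp.displacement[4:-4, 4:-4, 4:-4]
        assert np.abs(interior).max() < 0.1  # mm

    def test_resample_field_round_trip(self, grid):
        X, Y, Z = _coords(grid)
        u = np.zeros(tuple(grid.shape) + (3,))
        u[..., 1] = np.broadcast_to(np.linspace(0, 1, 32)[None, :, None], tuple(grid.shape))
        f = DeformationField(u, grid)
        coarse = GridSpec.centered((16, 16, 16), (3.0, 3.0, 3.0))
        back = resample_field(resample_field(f, coarse), grid)
        interior = np.s_[2:-2, 2:-2, 2:-2]
        assert np.allclose(
            back.displacement[interior], f.displacement[interior], atol=0.05
        )
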