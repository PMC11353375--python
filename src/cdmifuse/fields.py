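"""Dense deformation fields and operations on them.

A :class:`DeformationField` stores per-voxel displacement vectors in world
millimetres on a static grid, following the backward-warping convention: a
warped image is ``out(x) = img(x + u(x))``.  The same field object is used
both by the distortion simulator (as ground truth) and by the elastic
registration (as the recovered correction), so that the two can be compared
directly.

The volume-preserving constraint of the registration is implemented here as a
discrete Helmholtz (Leray) projection: the curl-free part of a displacement
increment is removed by solving a Poisson problem spectrally, using the
symbol of the central-difference derivative so that the *discrete* divergence
of the projected field vanishes at interior voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .grid import GridSpec, ValidationError, Volume

__all__ = [
    "DeformationField",
    "apply_field",
    "jacobian_determinant",
    "divergence",
    "divergence_free_project",
    "compose_fields",
    "invert_field",
    "resample_field",
    "zero_field",
]


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on a static grid.

    ``displacement`` has shape ``grid.shape + (3,)``; component ``a`` is the
    world-mm displacement along axis ``a``.
    """

    displacement: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        expected = tuple(self.grid.shape) + (3,)
        if self.displacement.shape != expected:
            raise ValidationError(
                f"displacement shape {self.displacement.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValidationError("displacement field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)

    def copy(self) -> "DeformationField":
        return DeformationField(self.displacement.copy(), self.grid)


def zero_field(grid: GridSpec) -> DeformationField:
    return DeformationField(np.zeros(tuple(grid.shape) + (3,)), grid)


# --------------------------------------------------------------------------- #
# warping
# --------------------------------------------------------------------------- #

def _sample_coords(field: DeformationField) -> list[np.ndarray]:
    """Fractional voxel coordinates x + u(x)/h for map_coordinates."""
    g = field.grid
    coords = []
    for a in range(3):
        idx = np.arange(g.shape[a], dtype=float).reshape(
            [-1 if i == a else 1 for i in range(3)]
        )
        coords.append(idx + field.displacement[..., a] / g.spacing[a])
    return coords


def apply_field(
    field: DeformationField,
    volume: np.ndarray | Volume,
    interpolation: str = "linear",
    cval: float = 0.0,
) -> np.ndarray:
    """Backward-warp ``volume`` by ``field``: ``out(x) = volume(x + u(x))``.

    The volume must live on the field's (static) grid; resample it there
    first if it does not.  ``interpolation`` is ``"linear"`` for intensities
    or ``"nearest"`` for label volumes.
    """
    if isinstance(volume, Volume):
        if not volume.grid.compatible_with(field.grid):
            raise ValidationError("volume grid does not match field grid; resample first")
        data = volume.data
    else:
        data = np.asarray(volume)
        if data.shape != tuple(field.grid.shape):
            raise ValidationError(
                f"volume shape {data.shape} does not match field grid {field.grid.shape}"
            )
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    coords = _sample_coords(field)
    return ndimage.map_coordinates(
        data.astype(float, copy=False), coords, order=order, mode="constant", cval=cval
    )


# --------------------------------------------------------------------------- #
# differential operators
# --------------------------------------------------------------------------- #

def _gradient(comp: np.ndarray, spacing) -> list[np.ndarray]:
    return list(np.gradient(comp, *spacing))


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """det(I + grad u) by central differences (one-sided at the edges).

    A value of 1 means local volume is preserved; the interior voxels are the
    meaningful ones, edge values use one-sided differences.
    """
    u = field.displacement
    h = field.grid.spacing
    J = np.empty(u.shape[:3] + (3, 3))
    for a in range(3):
        grads = np.gradient(u[..., a], *h)
        for b in range(3):
            J[..., a, b] = grads[b]
        J[..., a, a] += 1.0
    return np.linalg.det(J)


def divergence(field: DeformationField) -> np.ndarray:
    """Discrete divergence of the displacement (central differences)."""
    u = field.displacement
    h = field.grid.spacing
    out = np.zeros(u.shape[:3])
    for a in range(3):
        out += np.gradient(u[..., a], h[a], axis=a)
    return out


# --------------------------------------------------------------------------- #
# Helmholtz / Leray projection
# --------------------------------------------------------------------------- #

def divergence_free_project(field: DeformationField) -> DeformationField:
    """Remove the curl-free (volume-changing) part of a displacement field.

    Returns ``u - grad(phi)`` where ``phi`` solves the Poisson equation
    ``laplacian(phi) = div(u)``.  The solve is spectral, with derivative
    symbols matching the central-difference operator, so the projected
    field's central-difference divergence is zero at every interior voxel.
    The mean (k = 0) component of the field is kept: rigid shifts are
    divergence-free and pass through unchanged.
    """
    u = field.displacement
    if not np.all(np.isfinite(u)):
        raise ValidationError("cannot project a non-finite field")
    shape = u.shape[:3]
    h = field.grid.spacing

    # central-difference derivative symbol i*kappa_a with
    # kappa_a = sin(2 pi k / N) / h
    freqs = [np.fft.fftfreq(shape[0]), np.fft.fftfreq(shape[1]), sfft.rfftfreq(shape[2])]
    kap = []
    for a in range(3):
        k = np.sin(2 * np.pi * freqs[a]) / h[a]
        kap.append(k.reshape([-1 if i == a else 1 for i in range(3)]))

    U = [sfft.rfftn(u[..., a]) for a in range(3)]
    k2 = kap[0] ** 2 + kap[1] ** 2 + kap[2] ** 2
    # longitudinal (curl-free) component amplitude; modes with kappa == 0
    # (mean and pure-Nyquist) are left untouched
    with np.errstate(invalid="ignore", divide="ignore"):
        dot = (kap[0] * U[0] + kap[1] * U[1] + kap[2] * U[2]) / k2
    dot = np.where(k2 > 0, dot, 0.0)

    out = np.empty_like(u)
    for a in range(3):
        out[..., a] = sfft.irfftn(U[a] - kap[a] * dot, s=shape)
    return DeformationField(out, field.grid)


# --------------------------------------------------------------------------- #
# composition / inversion / resampling
# --------------------------------------------------------------------------- #

def compose_fields(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Field of the composed warp ``x -> x + inner(x) + outer(x + inner(x))``.

    Warping an image by the returned field equals warping it first by
    ``outer`` and then warping the result by ``inner``.
    """
    if not outer.grid.compatible_with(inner.grid):
        raise ValidationError("fields must share a grid to compose")
    coords = _sample_coords(inner)
    comp = np.empty_like(inner.displacement)
    for a in range(3):
        warped_outer = ndimage.map_coordinates(
            outer.displacement[..., a], coords, order=1, mode="nearest"
        )
        comp[..., a] = inner.displacement[..., a] + warped_outer
    return DeformationField(comp, inner.grid)


def invert_field(field: DeformationField, n_iter: int = 20, tol: float = 1e-3) -> DeformationField:
    """Fixed-point inverse: find v with v(x) = -u(x + v(x)).

    Converges for smooth fields inside the invertibility regime (positive
    Jacobian); used to compare a recovered correction field against the
    simulated forward distortion.
    """
    v = DeformationField(-field.displacement.copy(), field.grid)
    for _ in range(n_iter):
        coords = _sample_coords(v)
        new = np.empty_like(v.displacement)
        for a in range(3):
            new[..., a] = -ndimage.map_coordinates(
                field.displacement[..., a], coords, order=1, mode="nearest"
            )
        delta = np.max(np.abs(new - v.displacement))
        v = DeformationField(new, field.grid)
        if delta < tol:
            break
    return v


def resample_field(field: DeformationField, grid_out: GridSpec) -> DeformationField:
    """Linearly resample the displacement vectors onto another grid.

    Displacement values are world-mm and are interpolated componentwise;
    out-of-field locations take the edge value.
    """
    g = field.grid
    mesh = np.meshgrid(
        *(((grid_out.axis_coords(a) - g.origin[a]) / g.spacing[a]) for a in range(3)),
        indexing="ij",
    )
    out = np.empty(tuple(grid_out.shape) + (3,))
    for a in range(3):
        out[..., a] = ndimage.map_coordinates(
            field.displacement[..., a], mesh, order=1, mode="nearest"
        )
    return DeformationField(out, grid_out)
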