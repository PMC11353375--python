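"""Rigid pre-alignment and volume-preserving elastic 3D registration.

The elastic stage is a multiresolution demons-style loop driven by a local
normalized cross-correlation (LNCC) similarity force: at every iteration the
similarity gradient is computed, smoothed with a fluid-like Gaussian
(``update_sigma``), optionally projected onto the divergence-free subspace
(the volume-preserving constraint), composed with the accumulated field, and
the result smoothed with an elastic Gaussian (``field_sigma``).  The
divergence-free projection of every increment keeps the Jacobian determinant
of the accumulated field close to 1, so warped quantitative maps (ADC, SUV)
are neither inflated nor compressed regionally.

Rigid pre-alignment wraps SimpleITK's multiresolution Euler3D registration;
the elastic stage is implemented here because its volume-preserving contract
(Jacobian ~ 1, testable) is the property the workflow depends on.

The deformation is estimated once, from the low-b diffusion image against
the anatomical reference, and the same transform chain is then reused for
the ADC map, the remaining b-value images, and PET.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .fields import (
    DeformationField,
    compose_fields,
    divergence_free_project,
    jacobian_determinant,
)
from .grid import GridSpec, ValidationError, Volume
from .resample import resample_volume

__all__ = [
    "RegistrationParams",
    "RigidTransform",
    "RegistrationResult",
    "RegistrationFailure",
    "resample_to_static",
    "rigid_register",
    "elastic_register",
    "resample_through_rigid",
    "Alignment",
    "align_to_reference",
]


class RegistrationFailure(RuntimeError):
    """Raised when the elastic loop cannot maintain an invertible field."""


@dataclass(frozen=True)
class RegistrationParams:
    """Tunable knobs of the rigid + elastic registration.

    All lengths are world millimetres.  ``iterations_per_level`` is ordered
    coarse to fine and must have ``pyramid_levels`` entries (an int is
    broadcast).  ``step_length`` caps the largest displacement increment
    per iteration; ``update_sigma`` / ``field_sigma`` are the fluid and
    elastic regularization scales.  ``volume_preserving`` toggles the
    divergence-free projection of each increment.
    """

    pyramid_levels: int = 3
    iterations_per_level: tuple[int, ...] | int = (80, 50, 25)
    update_sigma: float = 2.0
    field_sigma: float = 3.0
    metric: str = "lncc"  # "lncc" | "mi" (mi applies to the rigid stage)
    lncc_window: int = 5
    mi_bins: int = 32
    volume_preserving: bool = True
    step_length: float = 1.0
    field_decay: float = 0.05
    convergence_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")
        its = self.iterations_per_level
        if isinstance(its, int):
            its = (its,) * self.pyramid_levels
        else:
            its = tuple(int(i) for i in its)
        if len(its) != self.pyramid_levels:
            raise ValidationError("iterations_per_level must match pyramid_levels")
        object.__setattr__(self, "iterations_per_level", its)
        if self.update_sigma < 0 or self.field_sigma < 0:
            raise ValidationError("sigmas must be >= 0")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be > 0")
        if not 0 <= self.field_decay < 1:
            raise ValidationError("field_decay must be in [0, 1)")
        if self.metric not in ("lncc", "mi"):
            raise ValidationError("metric must be 'lncc' or 'mi'")


@dataclass(frozen=True)
class RigidTransform:
    """Euler rigid transform: p -> R(p - c) + c + t (fixed to moving space).

    ``rotation`` holds (rx, ry, rz) in radians composed as Rz @ Rx @ Ry,
    matching the SimpleITK/ITK Euler3D convention, so parameters returned
    by the rigid registration describe the same physical mapping here.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Rx @ Ry

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        return (pts - c) @ self.matrix.T + c + np.asarray(self.translation)

    @property
    def is_identity(self) -> bool:
        return (
            float(np.max(np.abs(self.rotation))) < 1e-12
            and float(np.max(np.abs(self.translation))) < 1e-12
        )


@dataclass
class RegistrationResult:
    """Outcome of the elastic stage.

    ``metric_trace`` holds one list of per-iteration dissimilarity values
    (1 - mean local correlation) per pyramid level; values are comparable
    within a level but not across levels, whose active-window sets differ.
    """

    rigid: RigidTransform
    field: DeformationField
    metric_trace: list[list[float]]
    converged: bool


# --------------------------------------------------------------------------- #
# resampling helpers
# --------------------------------------------------------------------------- #

def resample_to_static(
    moving: Volume,
    static_grid: GridSpec,
    interpolation: str = "linear",
    fill: float = 0.0,
    return_mask: bool = False,
):
    """Resample a moving volume onto the static grid (world frames shared)."""
    return resample_volume(moving, static_grid, interpolation, fill, return_mask)


def resample_through_rigid(
    moving: Volume,
    static_grid: GridSpec,
    rigid: RigidTransform,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> Volume:
    """Resample ``moving`` onto the static grid through a rigid transform."""
    order = {"linear": 1, "nearest": 0}[interpolation]
    mesh = np.meshgrid(*(static_grid.axis_coords(a) for a in range(3)), indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    q = rigid.apply_points(pts)
    idx = moving.grid.world_to_voxel(q).T.reshape((3,) + tuple(static_grid.shape))
    data = ndimage.map_coordinates(
        moving.data.astype(float, copy=False), idx, order=order, mode="constant", cval=fill
    )
    return Volume(data, static_grid)


# --------------------------------------------------------------------------- #
# rigid registration (SimpleITK)
# --------------------------------------------------------------------------- #

def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0).astype(np.float64)))
    img.SetSpacing(tuple(float(s) for s in vol.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin))
    return img


def rigid_register(static: Volume, moving: Volume, params: RegistrationParams | None = None) -> RigidTransform:
    """Multiresolution rigid (Euler3D) registration of moving to static.

    Uses dense (all-voxel) metric sampling, so the result is deterministic.
    Degenerate (constant) images yield the identity with a warning.
    """
    params = params or RegistrationParams()
    if float(np.std(static.data)) == 0.0 or float(np.std(moving.data)) == 0.0:
        warnings.warn("degenerate (constant) image: rigid registration skipped")
        return RigidTransform(center=tuple(static.grid.center))

    fixed, mov = _to_sitk(static), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if params.metric == "mi":
        reg.SetMetricAsMattesMutualInformation(params.mi_bins)
    else:
        reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    init = sitk.CenteredTransformInitializer(
        fixed, mov, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg.SetInitialTransform(init, inPlace=True)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    levels = min(3, params.pyramid_levels) if params.pyramid_levels else 3
    shrink = [2**l for l in range(levels - 1, -1, -1)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s // 2, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    out = sitk.Euler3DTransform(reg.Execute(fixed, mov))
    return RigidTransform(
        rotation=tuple(out.GetParameters()[:3]),
        translation=tuple(out.GetParameters()[3:6]),
        center=tuple(out.GetCenter()),
    )


# --------------------------------------------------------------------------- #
# elastic (demons-style) registration
# --------------------------------------------------------------------------- #

def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, [1, 99])
    scale = hi - lo
    if scale <= 0:
        scale = img.max() - img.min() or 1.0
    return (img - lo) / scale


def _lncc_force(I: np.ndarray, J: np.ndarray, spacing, window: int):
    """LNCC similarity value and its ascent direction w.r.t. displacement.

    Local means/covariances over a ``window``-voxel box; the returned force
    is ``dCC/dJ * grad(J)`` with the classic windowed cross-correlation
    derivative.  Windows with negligible variance in either image
    contribute no force.
    """
    uf = lambda x: ndimage.uniform_filter(x, window, mode="nearest")
    a = I - uf(I)
    b = J - uf(J)
    A = uf(a * b)
    B = uf(a * a)
    C = uf(b * b)
    floor = 1e-6 * max(float(I.var()), 1e-12)
    active = (B > floor) & (C > floor)
    BC = np.where(active, B * C, 1.0)
    cc = np.where(active, A * A / BC, 0.0)
    coef = np.where(active, 2.0 * A / BC, 0.0)
    term = a - np.where(active, A / np.where(active, C, 1.0), 0.0) * b
    gJ = np.gradient(J, *spacing)
    force = np.stack([coef * term * g for g in gJ], axis=-1)
    n_active = int(active.sum())
    metric = float(cc.sum() / n_active) if n_active else 0.0
    return force, metric


def _boundary_taper(shape, taper_vox: int = 2) -> np.ndarray:
    w = np.ones(shape)
    for a, n in enumerate(shape):
        idx = np.arange(n, dtype=float)
        ramp = np.minimum(1.0, np.minimum(idx, n - 1 - idx) / max(taper_vox, 1))
        w *= ramp.reshape([-1 if i == a else 1 for i in range(3)])
    return w


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, factor / 2.0, mode="nearest")
    new_shape = tuple(max(int(np.ceil(n / factor)), 8) for n in img.shape)
    return ndimage.zoom(sm, np.array(new_shape) / np.array(img.shape), order=1, prefilter=False)


def _upsample_field(u: np.ndarray, new_shape) -> np.ndarray:
    out = np.empty(tuple(new_shape) + (3,))
    zf = np.array(new_shape) / np.array(u.shape[:3])
    for a in range(3):
        out[..., a] = ndimage.zoom(u[..., a], zf, order=1, prefilter=False)
    return out


def elastic_register(
    static: Volume,
    moving: Volume,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Volume-preserving demons-style registration of moving to static.

    The moving volume is resampled to the static grid first if needed.  The
    returned field is defined on the static grid and satisfies a positive
    Jacobian everywhere; with ``volume_preserving`` the spatial mean
    Jacobian stays within a few percent of 1.  Identical inputs and
    parameters give identical fields (the loop is deterministic).
    """
    params = params or RegistrationParams()
    grid = static.grid
    if not moving.grid.compatible_with(grid):
        moving = resample_to_static(moving, grid)

    I_full = _normalize(static.data)
    J_full = _normalize(moving.data)

    factors = [2**l for l in range(params.pyramid_levels - 1, -1, -1)]
    u = None
    trace: list[list[float]] = []
    converged = False

    for level, f in enumerate(factors):
        Il = _downsample(I_full, f)
        Jl = _downsample(J_full, f)
        shape_l = Il.shape
        spacing_l = tuple(h * n_full / n_l for h, n_full, n_l in
                          zip(grid.spacing, I_full.shape, shape_l))
        grid_l = GridSpec(shape_l, spacing_l,
                          phase_encode_axis=grid.phase_encode_axis,
                          slice_axis=grid.slice_axis)
        if u is None:
            u = np.zeros(tuple(shape_l) + (3,))
        else:
            u = _upsample_field(u, shape_l)
        taper = _boundary_taper(shape_l)
        upd_sig = [params.update_sigma / h for h in spacing_l]
        fld_sig = [params.field_sigma / h for h in spacing_l]
        level_trace: list[float] = []
        gain = None
        best_u, best_metric, since_best = u.copy(), np.inf, 0

        for it in range(params.iterations_per_level[level]):
            fld = DeformationField(u, grid_l)
            warped = _warp(Jl, fld)
            force, metric = _lncc_force(Il, warped, spacing_l, params.lncc_window)
            dissim = 1.0 - metric
            level_trace.append(dissim)
            if dissim < best_metric - params.convergence_tol:
                best_metric, best_u, since_best = dissim, u.copy(), 0
            else:
                since_best += 1
                if since_best >= 5:  # no improvement: stop and keep the best field
                    converged = True
                    break

            fmax = float(np.max(np.linalg.norm(force, axis=-1)))
            if fmax <= 0:
                converged = True
                break
            # steps scale with the pyramid level (coarse levels take longer
            # strides); a robust normalization keeps the strongest edges
            # from starving weaker ones
            step = params.step_length * f
            fnorm = np.linalg.norm(force, axis=-1)
            scale = step / max(float(np.percentile(fnorm[fnorm > 0], 95)), 1e-12)
            delta = force * scale
            dnorm = np.linalg.norm(delta, axis=-1)
            dmax = float(dnorm.max())
            if dmax > 2 * step:
                delta *= 2 * step / dmax
            if params.update_sigma > 0:
                for a in range(3):
                    delta[..., a] = ndimage.gaussian_filter(delta[..., a], upd_sig, mode="nearest")
            delta *= taper[..., None]
            if params.volume_preserving:
                delta = divergence_free_project(DeformationField(delta, grid_l)).displacement
                delta *= taper[..., None]

            u_try, ok = None, False
            for attempt in range(5):
                cand = compose_fields(
                    DeformationField(u, grid_l), DeformationField(delta, grid_l)
                ).displacement
                if params.field_sigma > 0:
                    for a in range(3):
                        cand[..., a] = ndimage.gaussian_filter(cand[..., a], fld_sig, mode="nearest")
                if params.field_decay > 0:
                    # weak restoring force toward zero displacement: regions
                    # without image evidence relax instead of inheriting
                    # diffused boundary displacement
                    cand *= 1.0 - params.field_decay
                jmin = jacobian_determinant(DeformationField(cand, grid_l))[1:-1, 1:-1, 1:-1].min()
                if jmin > 0:
                    u_try, ok = cand, True
                    break
                delta = delta / 2.0
            if not ok:
                raise RegistrationFailure(
                    "update repeatedly produced a non-positive Jacobian; "
                    "the images may be too discordant for the chosen step length"
                )
            u = u_try
        else:
            # ran out of iterations: keep the best field seen at this level
            pass
        u = best_u if best_metric < np.inf else u
        trace.append(level_trace)

    field = DeformationField(_upsample_field(u, I_full.shape) if u.shape[:3] != I_full.shape else u, grid)
    return RegistrationResult(
        rigid=RigidTransform(center=tuple(grid.center)),
        field=field,
        metric_trace=trace,
        converged=converged,
    )


def _warp(img: np.ndarray, field: DeformationField) -> np.ndarray:
    from .fields import apply_field

    return apply_field(field, img)


# --------------------------------------------------------------------------- #
# combined transform chain
# --------------------------------------------------------------------------- #

@dataclass
class Alignment:
    """Rigid + elastic transform chain estimated once and reused.

    ``apply`` maps any volume sharing the moving image's world frame onto
    the static grid: rigid resampling first, then the elastic warp.  This
    is how the field estimated from the low-b DWI is propagated to the ADC
    map, the other b-value images and PET.
    """

    static_grid: GridSpec
    field: DeformationField
    rigid: RigidTransform | None = None

    def apply(self, vol: Volume, interpolation: str = "linear") -> Volume:
        if self.rigid is not None and not self.rigid.is_identity:
            v = resample_through_rigid(vol, self.static_grid, self.rigid, interpolation)
        else:
            v = resample_volume(vol, self.static_grid, interpolation)
        from .fields import apply_field

        return Volume(apply_field(self.field, v.data, interpolation), self.static_grid)


def align_to_reference(
    reference: Volume,
    moving_low_b: Volume,
    params: RegistrationParams | None = None,
    do_rigid: bool = True,
) -> tuple[Alignment, RegistrationResult]:
    """Estimate the full transform chain from the low-b DWI to the reference."""
    params = params or RegistrationParams()
    rigid = rigid_register(reference, moving_low_b, params) if do_rigid else None
    if rigid is not None and not rigid.is_identity:
        pre = resample_through_rigid(moving_low_b, reference.grid, rigid)
    else:
        pre = resample_volume(moving_low_b, reference.grid)
    result = elastic_register(reference, pre, params)
    result.rigid = rigid or result.rigid
    return Alignment(reference.grid, result.field, rigid), result
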