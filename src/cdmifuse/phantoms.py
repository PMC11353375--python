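"""Digital twins of the 3D-printed validation phantoms.

Three phantom families are provided, mirroring the physical objects used to
validate DWI/PET fusion:

* an eight-sector cylinder whose sectors hold agar-sucrose gels of known
  diffusivity (six filled, two left as air, FDG in two of the gels),
* single spheres of varying diameter for the lesion-size feasibility sweep,
* a concentric-sphere "tumor" with FDG only in the core.

Each builder returns a :class:`PhantomScene` holding ground-truth ADC
(in 1e-6 mm^2/s), proton density, tracer activity (kBq/mL) and an integer
label volume on a common grid.  These scenes are the inputs of the
acquisition simulators in :mod:`cdmifuse.acquisition` and the ground truth
for every downstream evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .grid import GeometryError, GridSpec, ValidationError

__all__ = [
    "PhantomScene",
    "SectorPhantomSpec",
    "TumorPhantomSpec",
    "build_sector_phantom",
    "build_sphere_phantom",
    "build_tumor_phantom",
    "sector_wedge_labels",
    "TABLE_SECTOR_ADC",
]

# Nominal gel diffusivities of the six filled sectors (1e-6 mm^2/s),
# in sector order 1..6.
TABLE_SECTOR_ADC: tuple[float, ...] = (800.0, 1400.0, 1110.0, 800.0, 1400.0, 1110.0)

# Sector radius (mm) back-derived from the nominal 16.2 cm^2 per-sector
# cross-section of an equal-eighths disc: r = sqrt(8 * A / pi).
DEFAULT_SECTOR_RADIUS_MM: float = float(np.sqrt(8 * 16.2 / np.pi) * 10.0)


@dataclass
class PhantomScene:
    """Ground-truth volumes of a digital phantom on a common grid.

    ``labels`` uses 0 for air/background and contiguous integers >= 1 for
    the material compartments.  ``true_adc`` is zero wherever ``labels`` is
    zero (air carries no diffusion signal).
    """

    true_adc: np.ndarray
    proton_density: np.ndarray
    activity: np.ndarray
    labels: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        shape = tuple(self.grid.shape)
        for name in ("true_adc", "proton_density", "activity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValidationError(f"{name} shape {arr.shape} != grid shape {shape}")
            setattr(self, name, arr)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != shape:
            raise ValidationError("labels shape does not match grid shape")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integer-valued")
        if np.any(self.true_adc < 0) or np.any(self.activity < 0):
            raise ValidationError("true_adc and activity must be non-negative")
        if np.any(self.true_adc[self.labels == 0] != 0):
            raise ValidationError("true_adc must be zero in air (label 0)")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(present.size)):
            raise ValidationError(f"label set must be contiguous from 0, got {present}")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_compartments(self) -> int:
        return int(self.labels.max())


# --------------------------------------------------------------------------- #
# sector phantom
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SectorPhantomSpec:
    """Geometry and fill plan of the sectored cylinder.

    ``sector_adc`` lists the gel ADC of each *filled* wedge in increasing
    wedge order; ``empty_sectors`` are wedge indices (0-based, of
    ``n_sectors``) left as air; ``fdg_sectors`` are wedge indices whose gel
    carries tracer activity.
    """

    radius: float = DEFAULT_SECTOR_RADIUS_MM
    height: float = 60.0
    n_sectors: int = 8
    sector_adc: tuple[float, ...] = TABLE_SECTOR_ADC
    fdg_sectors: tuple[int, ...] = (2, 5)
    empty_sectors: tuple[int, ...] = (6, 7)
    fdg_activity: float = 8.0  # kBq/mL in the FDG-bearing gels
    proton_density: tuple[float, ...] | None = None  # per filled sector; default graded

    def __post_init__(self):
        if self.n_sectors < 2:
            raise ValidationError("n_sectors must be >= 2")
        if self.radius <= 0 or self.height <= 0:
            raise ValidationError("radius and height must be positive")
        empty = set(self.empty_sectors)
        if not empty <= set(range(self.n_sectors)):
            raise ValidationError("empty_sectors outside wedge range")
        n_filled = self.n_sectors - len(empty)
        if len(self.sector_adc) != n_filled:
            raise ValidationError(
                f"need {n_filled} sector_adc entries for {self.n_sectors} sectors "
                f"with {len(empty)} empty, got {len(self.sector_adc)}"
            )
        filled = set(range(self.n_sectors)) - empty
        if not set(self.fdg_sectors) <= filled:
            raise ValidationError("fdg_sectors must be filled sectors")
        if any(a <= 0 for a in self.sector_adc):
            raise ValidationError("sector ADC values must be positive")
        if self.proton_density is not None and len(self.proton_density) != n_filled:
            raise ValidationError("proton_density must have one entry per filled sector")


def _check_margin(grid: GridSpec, half_extent_xy: float, half_extent_z: float):
    cx = grid.center
    for a, half in ((0, half_extent_xy), (1, half_extent_xy), (2, half_extent_z)):
        lo = grid.origin[a]
        hi = grid.origin[a] + (grid.shape[a] - 1) * grid.spacing[a]
        margin = 2 * grid.spacing[a]
        if cx[a] - half < lo + margin or cx[a] + half > hi - margin:
            raise GeometryError(
                f"phantom (half-extent {half:.1f} mm along axis {a}) does not fit "
                f"grid with a 2-voxel air margin"
            )


def sector_wedge_labels(
    grid: GridSpec,
    spec: SectorPhantomSpec,
    z_margin: float = 0.0,
    center=None,
) -> np.ndarray:
    """Full-plane angular wedge labels matching the sector numbering.

    Unlike the phantom labels, wedges extend to the grid edge in-plane, so
    signal displaced radially outward by distortion is still attributed to
    its sector.  Air wedges map to 0.  ``z_margin`` (mm) trims slices near
    the cylinder ends to avoid through-plane partial-volume slices.
    """
    x, y, z = grid.world_mesh()
    c = grid.center if center is None else np.asarray(center, float)
    theta = np.mod(np.arctan2(y - c[1], x - c[0]), 2 * np.pi)
    wedge = np.minimum((theta / (2 * np.pi / spec.n_sectors)).astype(int), spec.n_sectors - 1)
    labels = np.zeros(tuple(grid.shape), dtype=np.int16)
    label_of_wedge = _wedge_label_map(spec)
    for w, lab in label_of_wedge.items():
        labels[np.broadcast_to(wedge == w, labels.shape)] = lab
    in_z = np.abs(z - c[2]) <= (spec.height / 2 - z_margin)
    labels *= np.broadcast_to(in_z, labels.shape)
    return labels


def _wedge_label_map(spec: SectorPhantomSpec) -> dict[int, int]:
    """Wedge index -> compartment label (1..n_filled) in wedge order."""
    mapping, lab = {}, 0
    for w in range(spec.n_sectors):
        if w in spec.empty_sectors:
            continue
        lab += 1
        mapping[w] = lab
    return mapping


def build_sector_phantom(spec: SectorPhantomSpec, grid: GridSpec) -> PhantomScene:
    """Voxelize the sectored cylinder onto ``grid`` (centred in the FOV)."""
    _check_margin(grid, spec.radius, spec.height / 2)
    x, y, z = grid.world_mesh()
    c = grid.center
    r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2
    inside = (r2 <= spec.radius**2) & (np.abs(z - c[2]) <= spec.height / 2)
    inside = np.broadcast_to(inside, tuple(grid.shape))

    theta = np.mod(np.arctan2(y - c[1], x - c[0]), 2 * np.pi)
    wedge = np.minimum((theta / (2 * np.pi / spec.n_sectors)).astype(int), spec.n_sectors - 1)
    wedge = np.broadcast_to(wedge, tuple(grid.shape))

    labels = np.zeros(tuple(grid.shape), dtype=np.int16)
    adc = np.zeros(tuple(grid.shape))
    pd = np.zeros(tuple(grid.shape))
    act = np.zeros(tuple(grid.shape))
    label_of_wedge = _wedge_label_map(spec)
    for w, lab in label_of_wedge.items():
        m = inside & (wedge == w)
        labels[m] = lab
        adc[m] = spec.sector_adc[lab - 1]
        if spec.proton_density is not None:
            pd[m] = spec.proton_density[lab - 1]
        else:
            # mild per-gel contrast so the reference image shows sector edges
            pd[m] = 1000.0 + 25.0 * lab
        if w in spec.fdg_sectors:
            act[m] = spec.fdg_activity
    return PhantomScene(adc, pd, act, labels, grid)


# --------------------------------------------------------------------------- #
# sphere phantoms
# --------------------------------------------------------------------------- #

def build_sphere_phantom(
    diameter: float,
    adc: float,
    activity: float,
    grid: GridSpec,
    proton_density: float = 1000.0,
) -> PhantomScene:
    """A single homogeneous gel sphere centred in the field of view."""
    if diameter <= 0:
        raise ValidationError("sphere diameter must be positive")
    if adc <= 0:
        raise ValidationError("sphere ADC must be positive")
    if diameter < 2 * max(grid.spacing):
        raise ValidationError(
            f"diameter {diameter} mm is sub-voxel on spacing {grid.spacing}"
        )
    _check_margin(grid, diameter / 2, diameter / 2)
    x, y, z = grid.world_mesh()
    c = grid.center
    inside = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= (diameter / 2) ** 2
    inside = np.broadcast_to(inside, tuple(grid.shape))
    labels = inside.astype(np.int16)
    return PhantomScene(
        adc * inside, proton_density * inside, activity * inside.astype(float), labels, grid
    )


@dataclass(frozen=True)
class TumorPhantomSpec:
    """Concentric spheres: an FDG-avid core inside a gel shell."""

    inner_diameter: float = 30.0
    outer_diameter: float = 60.0
    inner_adc: float = 1000.0
    outer_adc: float = 1800.0
    inner_activity: float = 25.0  # kBq/mL; ~SUV 8 core at a typical clinical dose
    inner_pd: float = 1050.0
    outer_pd: float = 950.0

    def __post_init__(self):
        if not (0 < self.inner_diameter < self.outer_diameter):
            raise ValidationError("need 0 < inner_diameter < outer_diameter")
        if self.inner_adc <= 0 or self.outer_adc <= 0:
            raise ValidationError("ADC values must be positive")
        if self.inner_activity < 0:
            raise ValidationError("inner_activity must be non-negative")


def build_tumor_phantom(spec: TumorPhantomSpec, grid: GridSpec) -> PhantomScene:
    """Voxelize the two-sphere tumor phantom (labels: 1 shell, 2 core)."""
    _check_margin(grid, spec.outer_diameter / 2, spec.outer_diameter / 2)
    x, y, z = grid.world_mesh()
    c = grid.center
    r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    core = np.broadcast_to(r2 <= (spec.inner_diameter / 2) ** 2, tuple(grid.shape))
    outer = np.broadcast_to(r2 <= (spec.outer_diameter / 2) ** 2, tuple(grid.shape))
    shell = outer & ~core
    labels = np.zeros(tuple(grid.shape), dtype=np.int16)
    labels[shell] = 1
    labels[core] = 2
    adc = np.where(core, spec.inner_adc, np.where(shell, spec.outer_adc, 0.0))
    pd = np.where(core, spec.inner_pd, np.where(shell, spec.outer_pd, 0.0))
    act = np.where(core, spec.inner_activity, 0.0)
    return PhantomScene(adc, pd, act, labels, grid)
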