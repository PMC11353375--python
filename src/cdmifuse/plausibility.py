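"""Voxel-wise ADC-SUV plausibility classification and cDMI back-mapping.

Joint (ADC, SUVbw) voxel values inside a tumor VOI are classified on a 3x3
threshold grid.  Some cells correspond to biologically implausible
combinations — e.g. air-like diffusivity together with avid tracer uptake —
which in a perfectly fused dataset should be rare; counting those voxels
before and after registration quantifies the spatial accuracy of the
fusion.  Mapping each voxel's class back to its anatomical location yields
the color-coded combined diffusivity-metabolic index (cDMI) map.

Default thresholds are ADC 300 / 1600 (1e-6 mm^2/s) and SUV 1 / 4; the
three implausible cells are (low ADC, high SUV), (high ADC, high SUV) and
(mid ADC, low SUV).  Bins are half-open and lower-edge inclusive, so every
non-negative (ADC, SUV) pair falls in exactly one cell.  Thresholds are
disease-dependent and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec, ValidationError
from .maps import ADCMap, SUVMap

__all__ = [
    "PlausibilityRuleSet",
    "VoxelScatter",
    "PlausibilityCounts",
    "CDMIClassMap",
    "default_rules",
    "extract_scatter",
    "classify",
    "implausible_reduction",
    "distribution_shift",
    "backmap",
    "scatter_plot",
]

_DEFAULT_LABELS = (
    ("air", "low-ADC tissue", "implausible: air-like ADC, high uptake"),
    ("implausible: tissue ADC, no uptake", "tissue", "tumor core"),
    ("fluid", "fluid, moderate uptake", "implausible: fluid-like ADC, high uptake"),
)
_DEFAULT_PLAUSIBLE = (
    (True, True, False),
    (False, True, True),
    (True, True, False),
)
# Fig-style display colors, row = ADC bin (low/mid/high), col = SUV bin
_DEFAULT_COLORS = (
    ("#00008b", "#e07000", "#00a000"),
    ("#00b000", "#f2c200", "#b00000"),
    ("#77ccee", "#ffa54c", "#20c020"),
)


@dataclass(frozen=True)
class PlausibilityRuleSet:
    """3x3 ADC x SUV classification grid.

    ``adc_edges`` / ``suv_edges`` are the two strictly increasing interior
    thresholds per axis; with lower-edge-inclusive half-open bins
    ([0, e1), [e1, e2), [e2, inf)) the nine cells partition the quarter
    plane.  ``cell_labels`` / ``cell_plausible`` / ``cell_colors`` are
    indexed ``[adc_bin][suv_bin]``.
    """

    adc_edges: tuple[float, float] = (300.0, 1600.0)
    suv_edges: tuple[float, float] = (1.0, 4.0)
    cell_labels: tuple = _DEFAULT_LABELS
    cell_plausible: tuple = _DEFAULT_PLAUSIBLE
    cell_colors: tuple = _DEFAULT_COLORS

    def __post_init__(self):
        for name in ("adc_edges", "suv_edges"):
            e = getattr(self, name)
            if len(e) != 2 or not e[0] < e[1]:
                raise ValidationError(f"{name} must be two strictly increasing values")
        for name in ("cell_labels", "cell_plausible"):
            g = getattr(self, name)
            if len(g) != 3 or any(len(row) != 3 for row in g):
                raise ValidationError(f"{name} must be a 3x3 table")

    def bin_pair(self, adc: float, suv: float) -> tuple[int, int]:
        """Cell of a single (ADC, SUV) pair; the scalar reference rule."""
        i = 0 if adc < self.adc_edges[0] else (1 if adc < self.adc_edges[1] else 2)
        j = 0 if suv < self.suv_edges[0] else (1 if suv < self.suv_edges[1] else 2)
        return i, j

    def cell_id(self, i: int, j: int) -> int:
        """Flat cell index in 0..8 (row-major over [adc_bin, suv_bin])."""
        return 3 * i + j

    @property
    def implausible_cells(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(3) for j in range(3) if not self.cell_plausible[i][j]]

    @property
    def n_implausible_cells(self) -> int:
        return len(self.implausible_cells)


def default_rules() -> PlausibilityRuleSet:
    """The published thoracic default thresholds (ADC 300/1600, SUV 1/4)."""
    return PlausibilityRuleSet()


@dataclass
class VoxelScatter:
    """Paired (ADC, SUV) samples with their grid locations inside a VOI."""

    adc: np.ndarray
    suv: np.ndarray
    voxel_index: np.ndarray  # (n, 3) integer grid coordinates
    voi_id: int = 1

    def __post_init__(self):
        self.adc = np.asarray(self.adc, float).ravel()
        self.suv = np.asarray(self.suv, float).ravel()
        self.voxel_index = np.asarray(self.voxel_index, int).reshape(-1, 3)
        n = self.adc.size
        if self.suv.size != n or self.voxel_index.shape[0] != n:
            raise ValidationError("scatter arrays must have equal length")

    def __len__(self) -> int:
        return int(self.adc.size)


@dataclass
class PlausibilityCounts:
    """Per-cell voxel tallies for one dataset (e.g. before/after fusion)."""

    per_cell: np.ndarray  # 3x3 int, [adc_bin, suv_bin]
    n_total: int
    n_implausible: int
    dataset_tag: str = ""

    def __post_init__(self):
        self.per_cell = np.asarray(self.per_cell, int)
        if self.per_cell.shape != (3, 3):
            raise ValidationError("per_cell must be 3x3")
        if int(self.per_cell.sum()) != self.n_total:
            raise ValidationError("per_cell must sum to n_total")

    def as_frame(self, rules: PlausibilityRuleSet) -> pd.DataFrame:
        rows = []
        for i in range(3):
            for j in range(3):
                rows.append(
                    {
                        "dataset": self.dataset_tag,
                        "adc_bin": i,
                        "suv_bin": j,
                        "label": rules.cell_labels[i][j],
                        "plausible": bool(rules.cell_plausible[i][j]),
                        "count": int(self.per_cell[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CDMIClassMap:
    """Integer cDMI class volume on the anatomical grid (0 = outside VOI).

    Stored values are ``cell_id + 1``; ``legend`` maps each stored value to
    the cell's name and display color.
    """

    labels: np.ndarray
    legend: dict[int, dict]
    grid: GridSpec

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValidationError("cDMI label volume must match the grid")
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(self.legend):
            raise ValidationError("cDMI map contains labels missing from the legend")


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #

def extract_scatter(
    adc: ADCMap, suv: SUVMap, voi_mask: np.ndarray, voi_id: int = 1
) -> VoxelScatter:
    """Collect paired ADC/SUV values of valid, finite voxels inside a VOI.

    Both maps must live on the same (anatomical) grid, i.e. after the
    deformation field has been applied.
    """
    if not adc.grid.compatible_with(suv.grid):
        raise ValidationError("ADC and SUV maps must share a grid")
    voi_mask = np.asarray(voi_mask, bool)
    if voi_mask.shape != tuple(adc.grid.shape):
        raise ValidationError("VOI mask must match the map grid")
    m = voi_mask & adc.valid_mask & np.isfinite(suv.values)
    idx = np.argwhere(m)
    return VoxelScatter(adc.values[m], suv.values[m], idx, voi_id)


def classify(
    scatter: VoxelScatter,
    rules: PlausibilityRuleSet | None = None,
    dataset_tag: str = "",
) -> tuple[np.ndarray, PlausibilityCounts]:
    """Assign every scatter voxel to exactly one cell and tally the counts.

    Returns the flat per-voxel cell ids (0..8, row-major over
    [adc_bin, suv_bin]; -1 for non-finite pairs, which are excluded from
    the counts rather than classified) and the per-cell tallies.
    """
    rules = rules or default_rules()
    adc, suv = scatter.adc, scatter.suv
    finite = np.isfinite(adc) & np.isfinite(suv)
    i = np.digitize(adc, rules.adc_edges)  # lower-edge inclusive bins
    j = np.digitize(suv, rules.suv_edges)
    cells = np.where(finite, 3 * i + j, -1)
    per_cell = np.zeros((3, 3), dtype=int)
    flat = np.bincount(cells[finite], minlength=9)
    per_cell[:] = flat.reshape(3, 3)
    plaus = np.asarray(rules.cell_plausible, bool)
    n_impl = int(per_cell[~plaus].sum())
    counts = PlausibilityCounts(per_cell, int(finite.sum()), n_impl, dataset_tag)
    return cells, counts


def implausible_reduction(before, after) -> float:
    """Percent reduction of implausible voxels achieved by registration.

    ``100 * (n_before - n_after) / n_before``; positive values mean the
    fusion improved.  Accepts :class:`PlausibilityCounts` or raw counts.
    Undefined (NaN) when there were no implausible voxels to begin with.
    """
    nb = before.n_implausible if isinstance(before, PlausibilityCounts) else int(before)
    na = after.n_implausible if isinstance(after, PlausibilityCounts) else int(after)
    if nb < 0 or na < 0:
        raise ValidationError("counts must be non-negative")
    if nb == 0:
        return float("nan")
    return 100.0 * (nb - na) / nb


def distribution_shift(before: VoxelScatter, after: VoxelScatter) -> pd.DataFrame:
    """Percent change of distribution moments between two scatters.

    Reports mean, SD, skewness and excess kurtosis for ADC and SUV
    separately.  With fewer than 4 voxels in either scatter the higher
    moments are omitted (NaN) since they are not meaningfully estimable.
    """
    if len(before) == 0 or len(after) == 0:
        raise ValidationError("scatters must be nonempty")
    small = min(len(before), len(after)) < 4

    def moments(x):
        return {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
            "skewness": float(stats.skew(x)) if not small else np.nan,
            "kurtosis": float(stats.kurtosis(x)) if not small else np.nan,
        }

    rows = []
    for name, b, a in (("adc", before.adc, after.adc), ("suv", before.suv, after.suv)):
        mb, ma = moments(b), moments(a)
        for mom in ("mean", "sd", "skewness", "kurtosis"):
            if np.isnan(mb[mom]) or mb[mom] == 0:
                pct = np.nan
            else:
                pct = 100.0 * (ma[mom] - mb[mom]) / abs(mb[mom])
            rows.append(
                {"parameter": name, "moment": mom, "before": mb[mom], "after": ma[mom],
                 "pct_change": pct}
            )
    return pd.DataFrame(rows)


def backmap(
    cell_ids: np.ndarray,
    voxel_index: np.ndarray,
    grid: GridSpec,
    voi_mask: np.ndarray,
    rules: PlausibilityRuleSet | None = None,
) -> CDMIClassMap:
    """Back-map per-voxel scatter classes onto the anatomical grid.

    Every classified voxel must lie inside the VOI mask and the grid;
    stored values are ``cell_id + 1`` so 0 stays "outside VOI".  The round
    trip classify -> backmap -> per-voxel lookup is exact.
    """
    rules = rules or default_rules()
    cell_ids = np.asarray(cell_ids, int).ravel()
    idx = np.asarray(voxel_index, int).reshape(-1, 3)
    if idx.shape[0] != cell_ids.size:
        raise ValidationError("cell_ids and voxel_index must have equal length")
    voi_mask = np.asarray(voi_mask, bool)
    shape = tuple(grid.shape)
    if idx.size and (idx.min() < 0 or np.any(idx.max(axis=0) >= np.asarray(shape))):
        raise ValidationError("voxel index outside the grid")
    if idx.size and not voi_mask[idx[:, 0], idx[:, 1], idx[:, 2]].all():
        raise ValidationError("classified voxel outside the VOI mask")
    labels = np.zeros(shape, dtype=np.int16)
    keep = cell_ids >= 0
    labels[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = cell_ids[keep] + 1
    legend = {
        3 * i + j + 1: {
            "name": rules.cell_labels[i][j],
            "plausible": bool(rules.cell_plausible[i][j]),
            "color": rules.cell_colors[i][j],
        }
        for i in range(3)
        for j in range(3)
    }
    return CDMIClassMap(labels, legend, grid)


def scatter_plot(
    scatter: VoxelScatter,
    rules: PlausibilityRuleSet | None = None,
    out_path=None,
    overlay: VoxelScatter | None = None,
    labels: tuple[str, str] = ("original", "registered"),
):
    """ADC-SUV scatter with the threshold grid; optional before/after overlay.

    Returns the matplotlib figure; when ``out_path`` is given the figure is
    also written there (PNG/SVG by extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rules = rules or default_rules()
    if len(scatter) == 0:
        raise ValidationError("cannot plot an empty scatter")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scatter.adc, scatter.suv, s=3, alpha=0.4, c="#5b3794", label=labels[0])
    if overlay is not None:
        ax.scatter(overlay.adc, overlay.suv, s=3, alpha=0.4, c="#e07b27", label=labels[1])
        ax.legend(loc="upper right")
    for e in rules.adc_edges:
        ax.axvline(e, color="k", lw=0.8, ls="--")
    for e in rules.suv_edges:
        ax.axhline(e, color="k", lw=0.8, ls="--")
    ax.set_xlabel("ADC [1e-6 mm$^2$/s]")
    ax.set_ylabel("SUVbw")
    ax.set_title("voxel-wise ADC-SUV distribution")
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
    return fig
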