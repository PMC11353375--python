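"""Quantitative parametric maps: ADC from DWI and SUVbw from PET.

Units: ADC values are expressed in 1e-6 mm^2/s throughout the package (the
clinical convention in which soft tissue spans roughly 300-1600).  SUVbw is
dimensionless, normalizing tissue activity concentration by the
decay-corrected injected activity per gram of body weight (tissue density
taken as 1 g/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import DWISeries
from .grid import GridSpec, ValidationError, Volume

__all__ = ["ADCMap", "SUVMap", "TracerDose", "compute_adc", "compute_suv", "F18_HALF_LIFE_S"]

F18_HALF_LIFE_S = 6586.0  # physical half-life of 18F in seconds


@dataclass
class ADCMap:
    """ADC volume (1e-6 mm^2/s) with a validity mask.

    Voxels where the fit is undefined (non-positive or non-finite signal)
    are flagged invalid rather than silently zeroed; their ``values`` entry
    is 0.  Negative fitted ADCs (pure noise) are clipped to 0 but remain
    valid so downstream classification stays total.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        shape = tuple(self.grid.shape)
        self.values = np.asarray(self.values, float)
        self.valid_mask = np.asarray(self.valid_mask, bool)
        if self.values.shape != shape or self.valid_mask.shape != shape:
            raise ValidationError("ADC map arrays must match the grid shape")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValidationError("valid ADC voxels must be finite")
        if np.any(self.values[self.valid_mask] < 0):
            raise ValidationError("valid ADC voxels must be >= 0")


@dataclass
class SUVMap:
    """Dimensionless SUVbw volume."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValidationError("SUV map must match the grid shape")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("SUV values must be finite and >= 0")


@dataclass(frozen=True)
class TracerDose:
    """Injection and timing information needed for SUV normalization."""

    injected_activity: float  # MBq at injection time
    body_weight: float  # kg
    uptake_interval: float  # s between injection and acquisition
    half_life: float = F18_HALF_LIFE_S  # s

    def __post_init__(self):
        for name in ("injected_activity", "body_weight", "uptake_interval", "half_life"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def decayed_activity_kbq(self) -> float:
        """Injected activity decay-corrected to acquisition time, in kBq."""
        return self.injected_activity * 1000.0 * 2.0 ** (-self.uptake_interval / self.half_life)


def compute_adc(dwi: DWISeries) -> ADCMap:
    """Estimate ADC (1e-6 mm^2/s) from a DWI series.

    With exactly two b-values the estimator is the analytic two-point
    inversion ``ln(S_low/S_high) / (b_high - b_low)``; with more, the slope
    of an ordinary least-squares fit of ``-ln S`` against ``b``.  Voxels
    with any non-positive or non-finite signal are marked invalid; negative
    estimates are clipped to 0 and stay valid.
    """
    b = np.asarray(dwi.b_values, float)
    vols = np.stack(dwi.volumes)
    valid = np.all((vols > 0) & np.isfinite(vols), axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(vols > 0, np.log(np.where(vols > 0, vols, 1.0)), 0.0)
        if b.size == 2:
            lo, hi = np.argmin(b), np.argmax(b)
            adc = (logs[lo] - logs[hi]) / (b[hi] - b[lo])
        else:
            bc = b - b.mean()
            denom = np.sum(bc**2)
            adc = -np.einsum("i,i...->...", bc, logs) / denom
    adc = adc * 1e6  # mm^2/s -> 1e-6 mm^2/s
    adc = np.where(valid, np.clip(adc, 0.0, None), 0.0)
    return ADCMap(adc, valid, dwi.grid)


def compute_suv(activity: Volume, dose: TracerDose) -> SUVMap:
    """Convert an activity image (kBq/mL) to SUVbw.

    ``SUV = C * BW_g / A_decayed`` with body weight in grams and activity
    decay-corrected to acquisition time; a uniform distribution of the dose
    over the body mass (1 g/mL) gives SUV = 1 everywhere.
    """
    c = np.asarray(activity.data, float)
    if np.any(c < 0):
        raise ValidationError("activity concentrations must be >= 0")
    suv = c * (dose.body_weight * 1000.0) / dose.decayed_activity_kbq
    return SUVMap(suv, activity.grid)
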