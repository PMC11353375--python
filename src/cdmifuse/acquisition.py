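"""Simulated acquisitions: distorted multi-b DWI, PET, and the anatomical
reference image.

The DWI signal model is mono-exponential, ``S_b = PD * exp(-b * ADC)``, the
standard description of Gaussian diffusion over the clinical b-value range.
Simulated diffusion images are (i) warped by the susceptibility field,
(ii) resampled to the acquisition grid with a box slice profile (emulating
thick, gapped 2D slices), and (iii) corrupted with Rician noise, the
magnitude-image noise law of MRI.  PET is simulated as the undistorted
modality: Gaussian point-spread blur plus Poisson counting noise, with no
geometric warp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import DeformationField, apply_field
from .grid import GridSpec, ValidationError, Volume
from .phantoms import PhantomScene
from .resample import resample_with_slice_profile

__all__ = ["DWISeries", "simulate_dwi", "simulate_pet", "simulate_reference"]


@dataclass
class DWISeries:
    """A set of diffusion-weighted volumes sharing one grid.

    ``b_values`` are in s/mm^2; ``volumes`` holds one signal array per
    b-value.  When produced by :func:`simulate_dwi`, ``truth_field`` stores
    the ground-truth distortion field (on the scene grid) for evaluation.
    """

    b_values: tuple[float, ...]
    volumes: list[np.ndarray]
    grid: GridSpec
    truth_field: DeformationField | None = None

    def __post_init__(self):
        self.b_values = tuple(float(b) for b in self.b_values)
        if len(set(self.b_values)) < 2:
            raise ValidationError("need at least two distinct b-values")
        if any(b < 0 for b in self.b_values):
            raise ValidationError("b-values must be >= 0")
        if len(self.volumes) != len(self.b_values):
            raise ValidationError("one volume per b-value required")
        shape = tuple(self.grid.shape)
        self.volumes = [np.asarray(v, float) for v in self.volumes]
        for v in self.volumes:
            if v.shape != shape:
                raise ValidationError("all DWI volumes must share the grid shape")

    def volume(self, b: float) -> np.ndarray:
        return self.volumes[self.b_values.index(float(b))]

    @property
    def b_low(self) -> float:
        return min(self.b_values)


def _noiseless_signal(scene: PhantomScene, b: float) -> np.ndarray:
    # ADC is carried in 1e-6 mm^2/s; b in s/mm^2
    return scene.proton_density * np.exp(-b * scene.true_adc * 1e-6)


def simulate_dwi(
    scene: PhantomScene,
    field: DeformationField | None,
    b_values,
    noise_sigma: float = 0.02,
    grid_out: GridSpec | None = None,
    seed: int | None = None,
    slice_thickness: float = 5.0,
) -> DWISeries:
    """Simulate a distorted, noisy DWI series from a phantom scene.

    Per b-value: compute the mono-exponential signal on the scene grid, warp
    it by ``field`` (the susceptibility distortion; ``None`` or a zero field
    leaves geometry intact), resample to ``grid_out`` with a
    ``slice_thickness`` mm box slice profile, and add Rician noise whose
    Gaussian sigma is ``noise_sigma`` times the 99th-percentile signal of
    the lowest-b volume.
    """
    b_values = tuple(float(b) for b in b_values)
    if len(set(b_values)) < 2:
        raise ValidationError("need at least two distinct b-values")
    if any(b < 0 for b in b_values):
        raise ValidationError("b-values must be >= 0")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if field is not None and not field.grid.compatible_with(scene.grid):
        raise ValidationError("distortion field must live on the scene grid")
    grid_out = grid_out or scene.grid

    clean = []
    for b in b_values:
        sig = _noiseless_signal(scene, b)
        if field is not None:
            sig = apply_field(field, sig)
        vol = resample_with_slice_profile(
            Volume(sig, scene.grid), grid_out, slice_thickness
        )
        clean.append(vol.data)

    ref = float(np.percentile(clean[int(np.argmin(b_values))], 99))
    sigma = noise_sigma * ref
    rng = np.random.default_rng(seed)
    out = []
    for sig in clean:
        if sigma > 0:
            n1 = rng.normal(0.0, sigma, sig.shape)
            n2 = rng.normal(0.0, sigma, sig.shape)
            sig = np.sqrt((sig + n1) ** 2 + n2**2)
        out.append(sig)
    return DWISeries(b_values, out, grid_out, truth_field=field)


def simulate_pet(
    scene: PhantomScene,
    psf_sigma: float = 2.5,
    count_scale: float = 100.0,
    seed: int | None = None,
) -> Volume:
    """Simulate a PET activity image (kBq/mL) on the scene grid.

    The true activity is blurred with an isotropic Gaussian point-spread
    function of ``psf_sigma`` mm, converted to expected counts per voxel
    with ``count_scale`` (counts per kBq/mL), Poisson-sampled, and scaled
    back to concentration units.  No geometric distortion is applied: PET
    is the geometrically faithful modality in this workflow.
    """
    if psf_sigma < 0:
        raise ValidationError("psf_sigma must be >= 0")
    if count_scale < 0:
        raise ValidationError("count_scale must be >= 0")
    act = scene.activity
    if psf_sigma > 0:
        act = ndimage.gaussian_filter(
            act, [psf_sigma / h for h in scene.grid.spacing], mode="constant"
        )
    if count_scale > 0:
        rng = np.random.default_rng(seed)
        act = rng.poisson(act * count_scale).astype(float) / count_scale
    return Volume(act, scene.grid)


def simulate_reference(scene: PhantomScene) -> Volume:
    """Undistorted anatomical reference image on the scene grid.

    A monotone mapping of proton density with a light sub-voxel blur, so
    compartment boundaries coincide with the label transitions; serves as
    the static image for registration (the T2w / water-image role).
    """
    img = ndimage.gaussian_filter(scene.proton_density, 0.5, mode="nearest")
    return Volume(img, scene.grid)
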