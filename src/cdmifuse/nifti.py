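"""NIfTI input/output for scalar volumes and vector displacement fields.

Volumes are written with diagonal affines derived from the grid (spacing on
the diagonal, origin in the translation column).  Only axis-aligned images
are supported on read; a NIfTI with rotational components in its affine is
rejected explicitly rather than silently re-oriented.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fields import DeformationField
from .grid import GridSpec, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "write_provenance",
]


class NiftiIOError(IOError):
    """Raised for unreadable or unsupported NIfTI input."""


def _grid_from_affine(affine: np.ndarray, shape, **axes) -> GridSpec:
    if affine is None or not np.all(np.isfinite(affine)):
        raise NiftiIOError("image has no usable affine")
    lin = np.abs(np.asarray(affine)[:3, :3])
    off = lin - np.diag(np.diag(lin))
    if np.any(off > 1e-4 * max(np.diag(lin).max(), 1.0)):
        raise NiftiIOError(
            "only axis-aligned (diagonal-affine) NIfTI images are supported"
        )
    spacing = tuple(float(s) for s in np.diag(lin))
    origin = tuple(float(o) for o in np.asarray(affine)[:3, 3])
    return GridSpec(tuple(int(s) for s in shape[:3]), spacing, origin, **axes)


def read_volume(path, **axes) -> Volume:
    """Read a scalar NIfTI volume and its grid.

    ``axes`` may carry ``phase_encode_axis`` / ``slice_axis`` overrides for
    the returned grid.  Raises :class:`NiftiIOError` with the filename for
    missing or corrupt input.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # missing file, bad header, ...
        raise NiftiIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise NiftiIOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape, **axes)
    return Volume(data, grid)


def write_volume(vol: Volume, path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI (.nii / .nii.gz by extension)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))
    return path


def write_field(field: DeformationField, path) -> Path:
    """Write a displacement field as a 4D vector NIfTI (mm, world axes)."""
    path = Path(path)
    img = nib.Nifti1Image(field.displacement.astype(np.float32), field.grid.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))
    return path


def read_field(path, **axes) -> DeformationField:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise NiftiIOError(f"cannot read displacement field {path}: {exc}") from exc
    if data.ndim == 5:  # (x, y, z, 1, 3) layout is also accepted
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise NiftiIOError(f"{path}: expected a (x, y, z, 3) vector image")
    grid = _grid_from_affine(img.affine, data.shape[:3], **axes)
    return DeformationField(data, grid)


def write_provenance(path, config: dict, seed: int | None, extra: dict | None = None) -> Path:
    """Record the resolved configuration and seed next to the outputs."""
    from . import __version__

    payload = {
        "software": "cdmifuse",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
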