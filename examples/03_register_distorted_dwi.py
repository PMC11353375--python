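"""Correct simulated susceptibility distortion by volume-preserving
elastic registration and compare the recovered field to the ground truth.

The demons-style loop estimates a deformation from the distorted low-b
image to the undistorted anatomical reference; every update increment is
projected onto the divergence-free subspace, so the Jacobian determinant
of the recovered field stays near 1 and warped quantitative maps keep
their values.
"""

import numpy as np

from cdmifuse import (
    DistortionModel,
    GridSpec,
    TumorPhantomSpec,
    Volume,
    build_tumor_phantom,
    elastic_register,
    invert_field,
    jacobian_determinant,
    make_susceptibility_field,
    resample_field,
    simulate_dwi,
    simulate_reference,
)
from cdmifuse.fields import apply_field
from cdmifuse.resample import resample_volume

scene_grid = GridSpec.centered((64, 64, 64), (1.5, 1.5, 1.25))
static_grid = GridSpec.centered((64, 64, 32), (1.5, 1.5, 2.5))
dwi_grid = GridSpec.centered((48, 48, 12), (2.0, 2.0, 6.0))

scene = build_tumor_phantom(TumorPhantomSpec(), scene_grid)
truth = make_susceptibility_field(scene, DistortionModel(amplitude=3.0, smoothing_sigma=6.0))
ref = resample_volume(simulate_reference(scene), static_grid)
dwi = simulate_dwi(scene, truth, (50.0, 800.0), 0.02, dwi_grid, seed=1)

result = elastic_register(ref, Volume(dwi.volume(50.0), dwi_grid))
tissue = resample_volume(
    Volume(scene.tissue_mask.astype(float), scene_grid), static_grid, "nearest"
).data > 0.5
truth_inv = invert_field(resample_field(truth, static_grid))
resid = np.linalg.norm(result.field.displacement - truth_inv.displacement, axis=-1)
jac = jacobian_determinant(result.field)[1:-1, 1:-1, 1:-1]
warped_mask = apply_field(result.field, tissue.astype(float))

print(f"converged: {result.converged}")
print(f"mean |recovered - truth| inside tissue: {resid[tissue].mean():.2f} mm "
      f"(truth field mean {np.linalg.norm(truth_inv.displacement, axis=-1)[tissue].mean():.2f} mm)")
print(f"Jacobian determinant: mean {jac.mean():.4f}, range ({jac.min():.3f}, {jac.max():.3f})")
print(f"tissue-mask volume change: {100 * (warped_mask.sum() - tissue.sum()) / tissue.sum():+.2f} %")
# A mean Jacobian of ~1 and a field error at the voxel scale mean geometry
# is restored without inflating or compressing the quantitative maps.
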