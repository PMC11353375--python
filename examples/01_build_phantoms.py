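"""Build the three digital phantoms and check their geometry.

The sector cylinder carries six gels of known diffusivity (two wedges left
as air, FDG in gels 3 and 6), the sphere phantom is a single gel ball, and
the tumor phantom is an FDG-avid core inside a gel shell.
"""

import numpy as np

from cdmifuse import (
    GridSpec,
    SectorPhantomSpec,
    TumorPhantomSpec,
    build_sector_phantom,
    build_sphere_phantom,
    build_tumor_phantom,
)

grid = GridSpec.centered((144, 144, 16), (1.0, 1.0, 4.0))
spec = SectorPhantomSpec(height=40.0)
scene = build_sector_phantom(spec, grid)
sl = grid.shape[2] // 2
print("sector phantom (radius %.1f mm):" % spec.radius)
for lab, adc in enumerate(spec.sector_adc, start=1):
    area = (scene.labels[:, :, sl] == lab).sum() / 100.0
    print(f"  gel {lab}: per-slice area {area:5.1f} cm^2 (nominal 16.2), ADC {adc:.0f}")
# Each wedge covers 1/8 of the disc; the printed areas deviate from 16.2
# only by pixelization of the curved boundary.

sphere = build_sphere_phantom(40.0, 1000.0, 0.0, GridSpec.centered((56, 56, 56), (1, 1, 1)))
vol = sphere.tissue_mask.sum() * sphere.grid.voxel_volume / 1000.0
print(f"\n40 mm sphere: voxelized volume {vol:.2f} cm^3, analytic {np.pi * 4**3 / 6:.2f} cm^3")

tumor = build_tumor_phantom(TumorPhantomSpec(), GridSpec.centered((64, 64, 64), (1.5, 1.5, 1.25)))
core = (tumor.labels == 2).sum() * tumor.grid.voxel_volume / 1000.0
shell = (tumor.labels == 1).sum() * tumor.grid.voxel_volume / 1000.0
print(f"tumor phantom: core {core:.1f} cm^3 (ADC 1000, 25 kBq/mL), "
      f"shell {shell:.1f} cm^3 (ADC 1800, cold)")
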