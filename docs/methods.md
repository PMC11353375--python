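# Methods

This note documents the models implemented in `cdmifuse`, the defaults and
why they were chosen, what the simulators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Digital phantoms

Three phantom families reproduce the geometry of 3D-printed validation
objects. All are voxelized by center-inclusion on an axis-aligned grid
(world coordinates in mm, diagonal NIfTI affines, axis order x/y/z with
phase-encode = y and slice = z by default).

**Sector cylinder.** Eight equal angular wedges; six hold gels with nominal
ADC (800, 1400, 1110, 800, 1400, 1110) ×10⁻⁶ mm²/s, the last two wedges are
air, and gels 3 and 6 carry tracer. The radius defaults to 64.23 mm,
back-derived from the nominal 16.2 cm² per-wedge cross-section
(r = √(8A/π)); this is a reconstruction from the published area, not a
measured dimension of the physical object. Proton density is graded mildly
per gel (1000 + 25·label) so the anatomical reference shows the wedge
boundaries.

**Spheres.** Single homogeneous gel spheres (diameter a parameter); the
voxelized volume converges to πd³/6 as the diameter grows (within 5 % at
20 mm, 2.5 % at 40 mm on a 1 mm grid).

**Tumor.** Concentric spheres, 30 mm core inside a 60 mm shell. Defaults,
chosen once to put the phantom in a clinically representative regime: core
ADC 1000 (cellular tumor), shell ADC 1800 (fluid-like, falls in the
*plausible* high-ADC/low-SUV "fluid" cell), core activity 25 kBq/mL, which
at the default dose (330 MBq, 70 kg, 60 min uptake, ¹⁸F half-life 6586 s)
gives core SUVbw ≈ 7.7 — an avid lesion — and a cold shell.

## Susceptibility distortion model

EPI distortion displaces signal along the phase-encode axis, strongest at
air–tissue interfaces. The simulator computes the Gaussian-smoothed air
indicator g (smoothing σ, default 6 mm), and scales it so that the
displacement at the air–tissue interface equals the chosen amplitude
(default 3 mm); values beyond the interface level (far air, where nothing
is visible) are clipped at the amplitude. Tissue deeper than the smoothing
reach barely moves, and small objects surrounded by air shift almost
rigidly — both clinically observed behaviours. The field acts along the
phase-encode axis only, is invertible for amplitudes up to roughly half the
smoothing length (the constructor refuses non-positive Jacobians with a
diagnostic), and is returned as the ground-truth backward-warp field for
later comparison.

An earlier variant normalized the zero-meaned indicator by its maximum over
the *tissue* mask; that normalization is degenerate for small phantoms (the
smoothed air fraction is nearly constant over a 10 mm sphere, so the
normalizer approaches zero and the warp explodes). The interface-anchored
scaling keeps the amplitude parameter meaningful for every phantom size.

## Acquisition simulation

**DWI.** Noiseless signal S_b = PD·exp(−b·ADC·10⁻⁶) on the scene grid,
backward-warped by the distortion field, then resampled to the acquisition
grid with a box slice profile: each output slice averages the signal over a
`slice_thickness` window (default 5 mm, midpoint rule with 5 sub-slices)
centred on slice positions spaced by the grid's slice spacing (default
6 mm) — the gapped 2D multislice sampling of the clinical protocol.
Rician noise is applied last: S' = √((S+n₁)² + n₂²) with
n ~ N(0, σ), σ = `noise_sigma` × the 99th-percentile low-b signal. The
default noise_sigma = 0.02 (2 %) is a config parameter; no noise level is
prescribed by the protocol being emulated. T2/TE/TR weighting, k-space
artifacts and eddy currents are not modelled.

**PET.** Gaussian PSF blur (σ default 2.5 mm, i.e. ~6 mm FWHM, typical for
clinical PET/MR), conversion to expected counts with `count_scale`
(default 100 counts per kBq/mL, ~1–2 % relative error in the hot core),
Poisson sampling, conversion back to kBq/mL. PET is simulated *undistorted*:
it is the geometrically faithful modality in this workflow. Attenuation,
scatter and reconstruction are not modelled.

**Reference.** A monotone mapping of proton density with a 0.5-voxel blur;
compartment edges coincide with label transitions. It plays the T2w /
water-image role as the static image for registration.

All stochastic steps take explicit seeds; identical seeds reproduce
volumes bit for bit.

## Parametric maps

ADC is estimated by the exact two-point inversion for two b-values and by
log-linear least squares for more; the two coincide when only two b-values
exist. Voxels with non-positive or non-finite signal are flagged invalid
(never silently zeroed); negative estimates (pure noise) are clipped to 0
but stay valid so that downstream classification remains total. ADC is
carried in 10⁻⁶ mm²/s everywhere: thresholds like "300" and "1600" are in
these units even where clinical writing abbreviates them as mm²/s.
SUVbw assumes 1 g/mL tissue density and decay-corrects the injected
activity to acquisition time: a uniform distribution of the decayed dose
over the body mass gives SUV = 1 by construction.

## Registration

The rigid stage wraps SimpleITK's multiresolution Euler3D registration
(correlation or Mattes MI metric, dense sampling — hence deterministic).

The elastic stage is a demons-style multiresolution loop written here
because the volume-preserving contract is the point of the package:

1. warp the moving image with the accumulated field u;
2. compute the local-normalized-cross-correlation force
   (window 5 voxels; the ANTs-style windowed-CC derivative times ∇J);
   windows with negligible variance contribute nothing;
3. normalize the step (95th-percentile force → `step_length` mm, scaled by
   the pyramid factor so coarse levels stride further), smooth with the
   fluid kernel `update_sigma` (2 mm), taper to zero over 2 boundary voxels;
4. **project the increment onto the divergence-free subspace** when
   `volume_preserving` is on;
5. compose with u, smooth with the elastic kernel `field_sigma` (3 mm),
   apply the restoring decay (below), and verify the Jacobian stays
   positive — otherwise halve the increment (up to 5 times, then abort);
6. track the best-metric field per level and stop after 5 iterations
   without improvement.

The projection is spectral: with derivative symbols matching the
central-difference operator, the longitudinal component κ(κ·û)/|κ|² is
removed per Fourier mode. Rigid shifts (k = 0) and rotations pass through
unchanged; pure expansions are removed exactly; the central-difference
divergence of the output vanishes at interior voxels to machine precision.
Projecting each increment keeps the mean Jacobian of the accumulated field
within a fraction of a percent of 1 in practice.

`field_decay` (default 0.05 per iteration) is a weak restoring force toward
zero displacement. Without it, the per-iteration elastic smoothing slowly
diffuses boundary displacement into texture-free interiors — regions where
the images contain no evidence — and the recovered field overshoots there.
The decay makes unobserved regions relax to "no displacement", which is the
correct prior for susceptibility warps that die out away from interfaces.
The cost is a slight underestimation of true displacement at the interfaces
themselves; the default balances the two (field error well under one voxel
in tissue, boundary misalignment reduced by ~2/3).

The deformation is estimated once from the low-b image against the
reference and reused for the ADC map, the other b-images and PET, via an
`Alignment` object that chains rigid resampling and the elastic warp.

In the phantom studies the rigid stage is off by default: the simulated
distortion contains no rigid component, and a data-driven rigid fit absorbs
a global phase-encode shift that is wrong for the phantom interior, only
for the elastic stage to have to undo it. The rigid stage is validated by
its own self-recovery tests and is available everywhere by configuration.

## Plausibility classification and cDMI

The 3×3 grid uses half-open, lower-edge-inclusive bins
([0,300), [300,1600), [1600,∞) × [0,1), [1,4), [4,∞)), which reproduces the
strict printed rules while making the partition total — every finite
non-negative pair lands in exactly one cell; non-finite pairs are excluded
and reported, not classified. The six plausible cells carry descriptive
names (air, fluid, tumor core, ...) following the conventional color
legend; they are labels, not biological claims. Thresholds are
config-overridable since plausibility windows are disease-specific.
Back-mapping writes cell-id + 1 into an integer volume on the anatomical
grid with a JSON legend; the classify → backmap → lookup round trip is
exact.

## Evaluation

**Sector statistics.** Per wedge and slice, the "area with a signal" is the
count of above-threshold voxels (Otsu on the low-b image by default — no
threshold is prescribed, so it is config-overridable) times the in-plane
pixel area; the reported area is the mean/SD across slices (slices are the
natural repeats of a uniform cylinder). In the *unregistered* condition the
wedge partition itself is warped by the ground-truth field before
attribution: this is the digital analogue of a reader outlining the visibly
warped gels, and it is what makes the measurement sensitive in wedges whose
boundaries parallel the phase-encode axis (a PE-only warp cannot change the
area of a fixed wedge with PE-parallel boundaries; it *does* compress and
stretch the visible gel regions everywhere).

**Repeated-measures ANOVA.** Classical sum-of-squares decomposition with
sectors as subjects and {expected, unregistered, registered} as conditions;
F = MS_cond/MS_err with df (c−1, (n−1)(c−1)), p from the F distribution.
On the published bench table of the physical phantom this gives F = 1.1209
(→ 1.12) at df (2, 10) with p = 0.364; the p-value is reported exactly for
these df. Cross-checked against pingouin in the test suite.

**Lesion-size sweep.** For each sphere diameter: simulate distorted DWI at
5 mm slices / 6 mm spacing, register, threshold the registered low-b image
(Otsu), and compute the Dice overlap with the true sphere support on the
static grid. A sphere is flagged as producing registration artifacts when
Dice < 0.90. In the packaged study the Dice is strictly increasing in
diameter and the flag clears exactly from diameter = 4× slice thickness.

**Tumor study.** Ten seeded replicates of simulate → map → register →
classify inside the whole-phantom VOI. PET is not re-warped here (it is
simulated undistorted and already aligned); the SUV column of the
before/after comparison therefore isolates exclusion-mask effects, while
the clinical pipeline does propagate the field to PET as the workflow
prescribes.

## Study problem sizes

The sector study runs at 1 mm in-plane (144×144 grid — the 64.23 mm radius
needs more than 128 mm of field of view plus the 2-voxel air margin), 2 mm
static slices, DWI at 2 mm in-plane with 5 mm/6 mm slices. The sphere and
tumor studies use 1.5 mm in-plane grids of 64³-scale. These sizes keep each
study in the tens-of-seconds range on one core while preserving the
acquisition geometry; they are the package's chosen study conditions, and
all reported numbers refer to them.

## Known limitations

* The distortion model is phenomenological (smoothed air indicator), not a
  B0 field-map computation; amplitudes in real scans are unknown and the
  simulator's amplitude is a free parameter.
* Interior displacement of homogeneous phantoms is unobservable by any
  intensity-driven registration; accuracy there reflects the regularization
  prior, not image evidence. Real tissue has texture that real registrations
  exploit; the phantom results are conservative in this respect.
* The volume-preserving constraint is enforced per increment
  (divergence-free projection), so the composed field is volume-preserving
  to first order; large-deformation exactness is not claimed.
* No motion, no attenuation/scatter, no reconstruction modelling; reader
  studies and clinical datasets are out of scope.
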