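# Methods

This note documents the models, parameter choices and numerical decisions
behind `petmrac`, and what the synthetic experiments do and do not show.

## HU → LAC conversion

CT Hounsfield units are mapped to 511 keV linear attenuation coefficients
with the standard bilinear scaling

    LAC(HU) = 9.6e-5 · (HU + 1000)            for HU ≤ BP(kVp)
    LAC(HU) = a(kVp) · (HU + 1000) + b(kVp)   for HU > BP(kVp)

clipped at zero. The water-equivalent slope 9.6e-5 cm⁻¹/HU fixes the two
anchors LAC(−1000) = 0 and LAC(0) = 0.096 cm⁻¹ (water). The bone-segment
parameters are the published per-tube-voltage pairs for PET/CT conversion:
BP = 47 HU, a = 5.10e-5 at 120 kVp and BP = 52 HU, a = 4.43e-5 at 100 kVp.
The intercept is derived from continuity at the breakpoint,
b = (9.6e-5 − a)(BP + 1000), which reproduces the published intercepts
(0.0471, 0.0544) to their printed precision while making the map exactly
continuous — the published rounded intercepts would leave a ~1e-5 cm⁻¹ jump.

Compartments are thresholded on LAC inside the body contour: bone strictly
above 0.11 cm⁻¹, air strictly below 0.007 cm⁻¹ with lung excluded.
Boundary-valued voxels belong to neither compartment. The body contour is
computed as threshold (> 0.007 cm⁻¹) → 3×3 in-plane morphological closing →
slice-wise hole filling → largest 3D connected component. Slice-wise (2D)
filling is deliberate: an air channel open to the volume ends (trachea)
is still enclosed by tissue in every axial slice, so internal cavities end
up inside the body mask, which is what the evaluation requires.

## Synthetic phantoms

Anatomy is procedural — an elliptical body (default semi-axes 80 × 62 mm)
with a subcutaneous fat rim, a posterior bone column with an interior canal
(spine + spinal cord/brain stem), an anterior bone arc in the cranial
slices (mandible), an anterior air channel (trachea/larynx), an oral air
pocket, an esophagus tube between air channel and spine, two caudal lung
regions, and spherical hot lesions. Only the topological relations that
drive the metrics are modeled: cord surrounded by bone, air inside
larynx/trachea, esophagus between air and bone, lesion in soft tissue near
the spine. The trachea ends at 60 % of the axial extent and the cranial
block (mandible, oral pocket) starts at least two slices higher, so the two
air cavities are always distinct connected components — the degradation
model selects whole cavities, and the component structure should not depend
on resolution.

Tissue HU anchors (configurable): air −1000, lung −700, fat −100, soft
tissue +40, bone +700. These map to LACs of 0, 0.029, 0.086, 0.0998 and
0.134 cm⁻¹ at 120 kVp, so bone and air fall on the correct sides of the
0.11/0.007 thresholds with margin. Activity is authored directly in SUV:
0 outside the body, 1.0 everywhere inside (including air cavities, whose
measured uptake in practice is small but nonzero through partial volume —
a uniform background keeps the no-lesion phantom single-valued and the
ratio denominators stable), lesions 5.0. The default lesion is 16 mm in
diameter and sits ~7 mm from the spine surface, emulating a nodal tumor in
proximity to bone.

Per-subject variation ("jitter") perturbs sizes by ±8 % and structure
positions by ±2–4 mm with the subject seed; lesion diameters are exact so
analytic volume checks stay meaningful. Phantoms are bitwise deterministic
per (config, seed).

## Degradation models

*Atlas-like* emulates a Dixon segmentation + bone-atlas method. Bone voxels
take the soft-tissue LAC (a configurable subset of named structures, e.g.
the spine, can be retained intact; the default retains none — superimposing
*misplaced* bone is out of scope because non-bone voxels must remain
untouched). A seeded random subset holding `round(f·n)` of the n connected
air cavities is set to soft-tissue LAC; at the default f = 0.5 exactly one
of the phantom's two cavities is misclassified per subject, so the larynx
is overestimated in every subject while the air Dice stays mid-range. An
optional fat–water swap exchanges the fat and soft-tissue LACs.

*Deep-like* emulates a CNN synthetic-CT. Each bone structure's HU is
shifted by one draw from Normal(−199, 60²) HU — one draw per structure, not
per voxel, because a network's bone-density error behaves as a systematic,
structure-level misprediction — followed by HU→LAC conversion and a mild
Gaussian blur (default FWHM 2 mm, σ = FWHM/2.3548) restricted to a band
around bone boundaries. Voxels outside the modified scope are bitwise equal
to the reference map in both modes.

## PET simulation

The acquisition model is 2D per axial slice with parallel-beam geometry:
for each line of response, counts = (emission line integral, cm) ×
exp(−attenuation line integral), the full-LOR coincidence attenuation
factor. Line integrals use Joseph-style sampling at half-pixel steps with
bilinear weights, assembled once per geometry into a sparse matrix, so
backprojection is the exact transpose of forward projection — which makes
the MLEM likelihood monotone by construction rather than approximately.
Path lengths are converted mm→cm before exponentiation. Default geometry:
84 views over [0°, 180°), radial pitch equal to the pixel pitch, radial
span covering the grid diagonal.

Reconstruction is multiplicative OSEM with an interleaved angle partition
(angle i → subset i mod S) and the attenuation factors of the *correction*
map in the system model; the correction map may differ from the map used to
generate the data, and that mismatch is the experiment. Defaults are
4 iterations × 21 subsets with a 3 mm FWHM Gaussian post-filter. Output is
calibrated to SUV by a single factor from a matched-map noiseless
reconstruction of a uniform water cylinder (the factor is within ~2 % of
unity; it absorbs residual projector-pair discretization). Scatter,
randoms, decay and detector-resolution modeling are out of scope: every
evaluated quantity is a ratio between reconstructions that differ only in
the correction map.

The projector reproduces the analytic chord-length sinogram of a uniform
disk to < 0.5 % (and the attenuated closed form to < 1 %) when the disk is
rasterized with area-fraction (partial-volume) edge voxels; binary-edge
rasterization leaves ~1 % single-ray discretization errors at the rim, so
the convergence and fidelity checks use partial-volume phantom edges.

## Evaluation

- Voxelwise relative difference: 100·(test − ref)/ref on body voxels with
  ref > 0 (zero-reference voxels are excluded — tiny absolute differences
  at near-zero uptake would otherwise appear as huge relative errors).
  Summary uses the population SD.
- R²: squared Pearson correlation of paired voxel values (the
  joint-histogram reading); an identity-line alternative was considered
  and rejected as it conflates correlation with calibration, which the
  mean error already reports.
- Distance profiles: per-slice 2D Euclidean distance transforms (exact, via
  `scipy.ndimage.distance_transform_edt` with in-plane spacing) to bone and
  air. Valid voxels are inside the body, outside lung, and not strictly
  closer to the other compartment; equidistant voxels are kept in both
  maps. Bin 0 is distance = 0 (inside the compartment); bin k ≥ 1 covers
  (3(k−1), 3k] mm. Per-bin error is the ratio of means
  100·(mean test − mean ref)/mean ref — "error in SUV_mean" — not the mean
  of voxel ratios; bins with fewer than 10 voxels or zero reference mean
  are missing. Across-subject aggregation reports the lower quartile,
  median and upper quartile (linear interpolation), skipping missing bins
  per subject.
- Dice 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks. Regional errors
  use the same ratio-of-means convention; empty ROIs yield NaN rather than
  an error.

## Cohort experiment

Default: 11 subjects on a 64 × 64 × 16 grid at 3 mm isotropic voxels,
noiseless projections, per-subject seeds derived order-independently from
the master seed via `SeedSequence((master, index, stream))`. The sinogram
is always generated with the reference map; three reconstructions are
corrected with the reference, atlas-like and deep-like maps respectively.
Noiseless mode is the default analysis surface so that sign and ordering
statements reflect the attenuation mismatch alone, not Monte-Carlo
variance; Poisson noise at a configurable count scale is available. All
outputs (JSON/CSV) are written without timestamps, making repeat runs
byte-identical. A failing subject is logged and skipped rather than
aborting the cohort.

The grid and cohort sizes were chosen so the full experiment runs in tens
of seconds, which the acceptance battery exploits to rerun it from scratch.

## What the synthetic experiments show — and what they do not

Passing the battery demonstrates that the *measurement machinery* is
correct (metrics match closed forms and brute force, the reconstruction is
faithful under a matched map) and that the pipeline reproduces the
qualitative structure of MR-AC errors: PET underestimation inside and near
missing/underdense bone, overestimation inside misclassified air, rapid
decay of both with distance, and a uniform ordering of the mild (deep-like)
over the severe (atlas-like) degradation in voxel-error SD, compartment
Dice and bin-0 errors. The phantoms are not anthropomorphic: absolute error
magnitudes depend on the synthetic geometry, uniform uptake, 2D physics and
the absence of scatter/randoms/registration error, and should not be read
as predictions for patient data. Known limitations: no Dixon signal or
fat–water physics (the swap acts directly on LACs), no misplaced-bone
atlas artifacts, single-bed parallel-beam geometry, and air-cavity uptake
set to the body background rather than near zero.
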