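# Methods

## Problem setting

Cranioplasty repairs a hole in the skull (after trauma, tumour excision or
decompressive craniectomy) with a patient-specific implant.  Framed
computationally, the task is volumetric shape completion: given a binary
bone mask of a *defected* skull on a regular voxel grid, predict the
*complete* skull; the implant is then the Boolean difference
`reconstruction AND NOT defected`.  `craniorec` implements this pipeline
end to end on synthetic data: phantom generation, preprocessing, parametric
defect injection, a residual encoder–decoder completion network, implant
extraction, and quantitative evaluation.

## Geometry model

A `Volume` is a rank-3 scalar array indexed `[x, y, z]` with per-axis
spacing (mm), an origin (mm position of voxel (0,0,0)) and a 3×3
direction-cosine matrix whose columns are the voxel-axis directions.  The
canonical anatomical frame after alignment is +Z superior, +Y anterior,
+X subject-left.  `BinaryVolume` restricts values to {0, 1} (uint8);
1 means bone or implant material.  NRRD I/O goes through SimpleITK
(gzip-encoded on write); DICOM series are assembled slice-wise with
pydicom, sorted along the slice normal, with single-slice studies rejected
as incomplete and mixed-series directories rejected with both series UIDs
named.

## Skull phantoms

Real cranial CT cohorts are hollow bone shells plus scanner artefacts.
The phantom generator emulates exactly those gross properties and nothing
more: a hollow ellipsoidal shell (voxel foreground iff its center lies
between the inner and outer ellipsoid surfaces), an optional disconnected
support-plate slab kept ≥ 2 background voxels from the skull, and
independent Bernoulli voxel-flip ("salt-and-pepper") noise.

Defaults, chosen once as a desk-scale caricature of adult cranial anatomy:

| parameter | default | note |
|---|---|---|
| grid | 64×64×32 voxels at 2 mm | 128×128×64 mm physical extent |
| semi-axes | (42, 52, 26) mm | distinct on purpose: principal axes well defined |
| thickness | 5 mm | 2–3 voxels at desk scale |
| base_cut | 0 (closed shell) | see below |
| cohort jitter | ±10 % on radii and thickness | uniform, per-member stream `seed + index` |

With `base_cut = 0` the shell is closed, so the background has exactly two
components (exterior + cranial cavity) — the "hollow" topology invariant
the tests assert.  A positive `base_cut` opens the skull base the way a
foramen magnum does, which necessarily connects the cavity to the
exterior; the hollowness invariant therefore applies to closed shells
only, and the closed shell is the default.

What phantoms deliberately do **not** model: sutures, mandibles, facial
bones, variable bone density, beam hardening, partial-volume grey values.
Consequently a test that passes on phantoms shows the pipeline's
*machinery* is correct (topology handling, geometry bookkeeping, learning
dynamics); it does not certify accuracy on clinical CT.

## Preprocessing

Stage order is fixed: threshold → median filter → connected-component
analysis → canonical alignment → resampling.

- **Threshold**: inclusive (`intensity ≥ lo`).  The default (300) is a
  config placeholder for raw CT ingest; phantom input is already binary
  and skips the stage.
- **Median filter**: default 3×3×3 window, reflected borders
  (edge-including, i.e. scipy's `reflect`).  The minimal salt-and-pepper
  remedy; on binary masks it is a neighborhood majority vote.
- **CCA**: keep the largest 26-connected foreground component; size ties
  break toward the component containing the smallest linear voxel index.
  26-connectivity is the conventional choice for 3-D bone masks.
- **Alignment**: template-free principal-axes alignment.  Second moments
  of the foreground (in mm) are diagonalized; the largest-variance axis
  maps to +Y (skulls are longest front-to-back), the middle to +X, the
  smallest to +Z.  Eigenvector signs are chosen nearest the identity,
  then flipped by a third-moment heuristic (superior mass up, anterior
  mass forward) when |skewness| > 0.1.  Near-degenerate spectra (adjacent
  eigenvalue gap < 2 % of the largest) return the identity transform with
  a warning rather than an arbitrary orientation.  Rotation is about the
  foreground centroid; resampling is nearest-neighbor.
- **Resampling**: physical-extent preserving (spacing rescaled so
  dims × spacing is invariant).  Scalar volumes are interpolated
  trilinearly.  Binary masks are resampled *anti-aliased*: trilinear
  interpolation of the {0,1} field re-thresholded at 0.5.  Pure
  nearest-neighbor picking carries a half-voxel surface bias that
  compounds over a down–up round trip on shells only a few voxels thick
  (measured round-trip DSC 0.88 vs 0.93 anti-aliased on a 5-voxel shell);
  the anti-aliased variant is the package's choice and is what the
  round-trip quality bound is measured against.

## Defect injection

Four parametric solids — sphere, axis-aligned cube, cylinder, triangular
prism — are voxelized with the inclusive rule (voxel set iff its center is
inside or on the closed boundary).  The prism's cross-section is a right
triangle with legs `base × height`; its extrusion interval is the centered
half-open band `[-L/2, L/2)` so an extrusion of k unit voxels covers
exactly k slices.  Reference lattice counts (unit spacing): sphere r=2 →
33 voxels; cube 3³ → 27; cylinder r=1, h=3 → 15; prism 4×4 base, extrusion
2 → 30.

Placement uses a five-sector angular atlas about the skull centroid in the
canonical frame: **top** above 60° elevation; **front/back/left/right**
azimuth quadrants centered on +Y/−Y/+X/−X with elevation in (10°, 60°].
Defect centers are sampled uniformly from *outer*-surface shell voxels
(boundary of the cavity-filled mask) inside the sector — sampling the
inner cavity wall would aim the through-thickness axis into the cavity.
Defect sizes scale with the skull: linear parameters are drawn uniformly
from 15–25 % of the mean semi-axis (full widths doubled), so holes look
like craniectomy defects rather than drill holes or hemispherectomies.
Cylinder and prism axes default to the radial direction at the sampled
center, approximating a through-thickness trephination.

Injection is pure Boolean: `defected = skull AND NOT mask`,
`implant_gt = skull AND mask`.  Two invariants are asserted over every
generated pair: the two parts are disjoint and their union is the healthy
skull, voxel-exact.

The dataset composer mirrors a 5-region × 4-shape plan: the training
cohort splits evenly into five region subsets (each skull gets all four
shapes in its one region); every test skull gets all twenty cases.  360
training and 36 test skulls hence yield 1440 + 720 = 2160 samples.
Per-case seeds derive from CRC-32 of (cohort seed, skull id, region,
shape), so any single pair regenerates in isolation.

## Networks

Both networks are implemented as a small self-contained NumPy layer stack
(im2col convolutions over BLAS, explicit backward passes, Adam), fully
deterministic for a fixed seed; every layer's analytic gradient is checked
against central finite differences in the test suite.

**Reconstruction network** — a residual U-Net: `levels` encoder stages of
residual blocks (two 3³ convolutions each followed by batch normalisation,
ReLU after the first, identity shortcut or 1³ projection when widths
change, ReLU after the add) with 2× max-pooling between stages; the
deepest stage is the bottleneck; `levels − 1` decoder stages upsample with
2×-stride transposed convolutions, concatenate the matching encoder
feature map, and apply another residual block; a final 1³ convolution +
sigmoid emits one occupancy-probability channel at input resolution.
Channel widths double per level from `base_channels` (desk default 8;
a full-scale configuration would use 32).  Input dims must be divisible by
`2**levels`.

**Enhancement network** — a light 2× super-resolution head: conv–BN–ReLU,
2× max-pool, conv–BN–ReLU, then two transposed-convolution upsamplings to
twice the input size producing 16 learned channels, concatenated with a
trilinear 2× interpolation of the input (fused width 17), reduced by a
final 3³ convolution + sigmoid.  The 16 + 1 = 17 fused-channel split is a
design interpretation, not a uniquely determined topology.  Enhancement
training pairs are synthesized by 2×-downsampling ground-truth skulls; at
inference the head consumes the reconstruction network's binarized output.

Parameter counts are a pure function of the config and are verified
against hand tallies (27·c_in·c_out + c_out per 3³ conv, 2c per BN, 8·c_in·c_out + c_out per
transposed conv) for small configs.

## Training recipe

Soft Dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1e-6 (per sample,
averaged over the batch), Adam at a constant learning rate 1e-3, batch
size 2.  A seeded 10 % validation split is held out for monitoring only;
checkpoints are written on validation improvement; a NaN loss aborts with
the epoch named.  Same seed + same build ⇒ bit-identical histories.

## Implant extraction and evaluation

Probabilities are binarized at τ = 0.5 (inclusive).  The implant is the
Boolean difference against the defected skull — by construction it can
never intersect it — and is cleaned by keeping the largest 26-connected
component (opt-out), which provably cannot worsen the Hausdorff distance
to the ground truth.

Metrics: DSC, JSC, precision, recall, specificity from an exhaustive voxel
confusion tally, and the Hausdorff distance over foreground *surface*
voxels (≥ 1 face-adjacent background neighbor; grid borders count as
background) scaled by spacing.  Default HD mode is the classical maximum;
a 95th-percentile variant is available and reports always label the mode.
Both-masks-empty scores DSC = JSC = 1 by convention (logged); HD is then
undefined.  The suite aggregator averages per (region, shape) — 20 rows
under the full plan — plus a grand-mean row.

**Edge-gap fitment**: the cavity rim is the ring of ground-truth implant
voxels face-adjacent to the residual skull (taking the rim on the cavity
side makes a perfect implant score exactly 0 mm).  Rim voxels are
partitioned into four angular quadrants (L, B, R, T) in the tangent plane
at the defect center viewed along the outward normal; 10 points per side
are sampled uniformly (seeded); each gap is the mm distance to the nearest
implant voxel; the report gives per-side means and the overall mean, with
empty quadrants reported as undefined.

## Desk-scale experiment sizes

The recovery experiment trains the base-8 network on 40 defect pairs from
20 phantoms at 32×32×16 (4 mm spacing, 6 mm shell) for 10 epochs with the
full recipe, and scores binarized DSC against the healthy skull on 4
held-out phantoms; three seeded replicates must reach DSC ≥ 0.90 in at
least two cases.  These sizes are the package's desk-scale choice — they
reach the DSC plateau (held-out DSC ≈ 0.99) while keeping a single-CPU
run short.  Hole-*filling* (as opposed to shell reproduction) emerges
later in training than the DSC plateau, because the defect occupies only
a few dozen of ~1300 foreground voxels at this scale; the reproduction
script therefore trains its single replicate for 25 epochs (training loss
≈ 0.04), at which point extracted implants are nonempty and the held-out
edge gap can be reported.  Composition arithmetic is checked at the full
396-skull cohort size; metric and median-filter oracles run exhaustively
on volumes ≤ 9³; edge-gap bands are measured at 1 mm spacing on a
128×128×64 phantom so "one voxel" is 1 mm.

## Known limitations

- Phantoms are ellipsoid shells; none of the anatomy that makes real
  alignment and defect placement hard (asymmetry, sinuses, foramina) is
  present.
- Principal-axes alignment assumes the three principal extents are
  distinct; spherical heads fall back to identity with a warning.
- The networks are CPU-bound NumPy; full-scale (128×128×64, base 32)
  training is supported in configuration but impractically slow without
  hardware acceleration.
- The edge-gap sampler is a reproducible voxel-distance proxy for a
  CAD-style caliper measurement, not a re-implementation of one.
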