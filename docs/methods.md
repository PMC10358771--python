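# Methods

`contourqa` implements the evaluation and preprocessing machinery used to
audit deep-learning auto-segmentation of upper-abdominal organs-at-risk on
multi-sequence MRI: six contour-accuracy metrics, clinical quality
categories and an editing scorecard, the MRI intensity-standardization
chain, training-time augmentation transforms, and a synthetic phantom
generator that stands in for clinical data. This note records the models,
the conventions chosen where the field has more than one, and what the
synthetic tests do and do not demonstrate.

## Surface representation and distances

Binary masks live on regular grids with anisotropic voxel spacing
`(dx, dy, dz)` in mm. A mask's surface is the set of *exposed voxel
faces*: faces between a true voxel and a false voxel, including faces on
the volume border. Each face is represented by its center position in
physical mm and weighted by its area (`dy·dz`, `dx·dz`, or `dx·dy`).
This representation is deterministic and exactly enumerable, which is why
it was preferred over marching-cubes meshes: every distance-based metric
can be validated against an explicit all-pairs computation.

Directed surface distances are exact nearest-neighbour Euclidean
distances between the two face-center point sets, computed with a k-d
tree. `contourqa.oracle` re-implements the same quantities with explicit
per-voxel loops and O(N²) all-pairs minima; the test suite demands
agreement to 1e-6 mm on hundreds of random anisotropic mask pairs. A
voxel-grid distance transform was deliberately not used: it measures
distances from voxel centers rather than boundary elements and cannot
reach sub-voxel agreement with the face-center definition.

## The six metrics

- **DSC** `2|A∩R| / (|A|+|R|)`. Defined as 1 when both masks are empty.
- **MDA (mm)** — area-weighted mean of the pooled directed distance sets
  (both directions combined), i.e. the average symmetric surface
  distance. Symmetric by construction.
- **HD95% (mm)** — by default the maximum of the two directed
  area-weighted 95th percentiles (the common radiotherapy convention);
  a pooled-percentile mode is available via `MetricConfig.hd_convention`
  because the phrase "95th percentile Hausdorff" is used both ways in the
  literature. The weighted percentile is the smallest distance whose
  cumulative area reaches the target fraction.
- **PVD (%)** `100·(V_auto − V_ref)/V_ref`, signed: negative means the
  auto contour under-draws the organ.
- **sDSC** — fraction of the combined surface area lying within the
  tolerance (default 2 mm, an estimate of inter-observer variation in
  abdominal contouring) of the other surface. Boundary-inclusive
  (`d ≤ τ`), with a 1e-9 mm guard against float ties.
- **APL (mm)** — editing-effort proxy: the length of reference contour
  that must be redrawn. Default `slice2d` mode works the way editing
  does, slice by slice: on each axial slice the reference in-plane
  contour (exposed in-plane voxel edges, length-weighted) is compared to
  the auto contour of the same slice, and edges farther than the
  tolerance are summed; a slice with reference but no auto contributes
  its full contour length. A `surface3d` mode applies the same rule to 3D
  faces but reports mm² and is never used for rAPL, because "path length"
  is intrinsically a 2D notion.
- **rAPL (mm/cc)** — APL divided by the *reference* organ volume, so
  editing effort is comparable between a 3 cc esophagus and a 300 cc
  liver. The reference volume (not the auto volume) is the denominator
  because it is the stable anchor; this choice is configurable in
  principle by calling `apl` and dividing manually.

Empty-mask policy: DSC(∅,∅)=1, DSC(∅,X)=0; MDA/HD95/sDSC are undefined
when either mask is empty and are reported as missing with a flag, never
silently zero — a missed organ must not score well. A missed organ
(auto empty, reference present) carries PVD = −100% and APL equal to the
full reference contour length.

## Quality categories, scorecard, aggregation

Each metric value maps to `best` / `good` / `suboptimal` via inclusive
thresholds (defaults: best DSC ≥ 0.9, MDA ≤ 1.5 mm, HD95 ≤ 5 mm,
|PVD| ≤ 3%, sDSC ≥ 0.85, rAPL ≤ 5 mm/cc; good DSC ≥ 0.8, MDA ≤ 3 mm,
HD95 ≤ 10 mm, |PVD| ≤ 6%, sDSC ≥ 0.75, rAPL ≤ 10 mm/cc). PVD is graded
on magnitude since both over- and under-drawn contours need edits. A
whole contour's single category is the majority vote over its six metric
categories with ties resolved toward the worse category — a convention,
documented as such, since no standard exists.

The 1–6 editing scorecard grades burden from the number of edited slices
and the kind of edit (1 = none; 2 = few deletions/expansions on < 5
slices; 3 = fixing incomplete segmentation on < 10 slices; 4 = junction/
hilum edits or ~20 slices while under half the organ; 5 = more than half
the slices; 6 = > 80% of slices or full redo). Rules are evaluated from
worst to best so ambiguous records resolve to the higher score, and the
score is monotone in the number of edited slices for a fixed edit kind.

Aggregation produces per-organ means across cases, per-model overall
means computed as *unweighted* means of the twelve per-organ means (each
organ counts once, regardless of its size or case count), and radar-ready
values normalized by the per-metric maximum magnitude across all organs
and models. The bundled benchmark table of published per-organ means
exists so this arithmetic has a fixed worked example; the acceptance
tests verify the recomputed per-model summaries at 1% relative tolerance
(0.005 absolute floor), which absorbs the rounding of the printed
per-organ cells.

## Intensity standardization

The chain is bias-field correction → anisotropic diffusion → median
normalization, with a percentile-windowed Z-score available for training
input.

**N4 bias correction** is delegated to SimpleITK's
`N4BiasFieldCorrectionImageFilter`. The fit runs on a 2×-shrunk copy
(`bias_shrink_factor`, standard N4 practice — the field is smooth, so the
fit loses nothing measurable) and the log-field is reconstructed at full
resolution. The estimated field is normalized to mean 1 before division,
so the global mean intensity is preserved; constant images are returned
unchanged (N4's histogram sharpening is degenerate there). On phantoms
with a known amplitude-0.3 multiplicative field the residual modulation
loses ≥ 90% of its coefficient of variation.

**Anisotropic diffusion** is the Perona–Malik explicit divergence-form
scheme on the physical grid with Neumann boundaries (flux form, so the
global mean is conserved to float precision). Conductance is rational
`1/(1+(|∇u|/κ)²)` by default (exponential available); κ defaults to the
90th percentile of the finite-difference gradient magnitudes, which puts
noise below the knee and organ boundaries above it. The explicit time
step must satisfy `dt ≤ 1/(2(1/dx² + 1/dy² + 1/dz²))`; the default is
80% of that bound and a larger configured value is rejected, never
silently clamped. Default 5 iterations. This scheme is hand-written
because no installed library exposes a 3D anisotropic-spacing
Perona–Malik filter with an inspectable conductance convention.

**Median normalization** divides by the volumetric median of the
foreground, where foreground = voxels above the 5th intensity percentile
of the positive voxels (excluding air/background). The percentile-based
threshold makes the operation exactly invariant to positive global
rescaling. The precise in-house definition of "thresholding to
volumetric median" used clinically is not public; this convention is
documented, scale-invariant, and not claimed to match any specific tool.

**Percentile Z-score**: mean and SD are computed only from voxels inside
the closed [0.25%, 99.75%] intensity-percentile window of all voxels, and
the affine map `(v − μ_w)/σ_w` is applied to *every* voxel — outliers are
transformed, not clipped, so they cannot drag the statistics but remain
outliers. Statistics are per-volume; pooling across sequences of one
patient can be done by the caller on concatenated arrays.

## Augmentation

**Gamma**: with probability `p = 0.3` the image is rescaled to [0, 1],
raised to γ ~ Uniform(0.7, 1.3), and mapped back to its original
[min, max]. The rescale makes the power well-defined for Z-scored
(negative-valued) input, keeps min and max exact fixed points, and
preserves rank order for γ > 0. Randomness comes from an explicit
per-call seeded stream (`make_rng(config, call_index)`), so a training
loop replays exactly.

**3D elastic**: independent per-axis displacements are drawn uniformly in
±`elastic_max_disp_mm` (default 4 mm — "minor" relative to organ scale)
on a coarse control grid (default 50 mm spacing), upsampled to voxel
resolution with a cubic spline, clipped to the amplitude bound (cubic
interpolation can overshoot a few percent between control points), and
converted to voxel units per axis. The image is resampled with linear
interpolation and every mask with nearest-neighbour *on the same field*,
so labels stay binary, gain no new values, and move exactly with the
image; out-of-volume samples are edge-clamped to avoid background bleed.
Amplitude and grid spacing are package choices: the source workflow calls
its deformation "minor" without quantifying it.

## Phantoms

`make_phantom` builds a 12-organ abdominal caricature on a
96×96×48 grid at (1.640625, 1.640625, 3.0) mm spacing (typical
post-contrast T1 resolution; a T2-like spacing constant is provided):
ellipsoids for parenchymal organs, z-tubes for aorta, spinal cord and
esophagus, half-torus C-loops for duodenum and large bowel. Volumes span
~2.6 cc (esophagus) to ~225 cc (liver) — two orders of magnitude, so
volume-dependent behaviour (rAPL in particular) is exercised. Organs are
pairwise disjoint by construction; overlap is an error unless explicitly
allowed. Intensities are piecewise constant per organ, multiplied by a
smooth in-[1−a, 1+a] cosine-product bias field (default amplitude 0.3,
~120 mm wavelength) and degraded with Gaussian noise (default SD 5 on a
background of 60–260 intensity units). The generating field and the
noiseless image are returned as ground truth for oracle use, and
everything is bit-reproducible from `(spec, seed)`.

Perturbation operators create "auto" contours with known geometric
effects: whole-voxel translations (the realized mm shift is reported, so
analytic distance expectations stay exact), 6-connected or box
erosion/dilation, dropping the top occupied axial slices, and seeded
boundary jitter. `make_benchmark_suite` assembles seven families ×
three-plus magnitudes of (reference, auto) pairs, each with expected
metric values tagged `analytic` (closed form) or `oracle` (brute force).

**What the phantoms do not show.** They have crisp boundaries, no partial
volume, no motion artifacts, no MR physics, and convex-ish shapes.
Passing tests demonstrate that the *computations* are correct under their
stated definitions — not that any segmentation model is accurate on real
anatomy, and not that the standardization chain matches the in-house
clinical tool parameter-for-parameter.

## Problem sizes and numerical choices

The test and acceptance runs use the default phantom grid (96×96×48),
12×12×8 grids for the brute-force oracle ensembles (where O(N²) all-pairs
is exact and fast), 10,000 draws for the gamma-rate binomial check
(±0.015 is 3σ at p = 0.3), and 200 random pairs for oracle equivalence.
Float ties at category or tolerance boundaries are resolved inclusively;
percentile definitions are the inverse-CDF convention throughout.
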