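# contourqa

Quality assurance for MRI auto-segmentation contours in radiotherapy
planning.

When a deep-learning model auto-segments organs-at-risk (OARs) on
abdominal MRI, someone has to decide whether each contour is usable,
needs minor edits, or must be redrawn. `contourqa` implements the
evaluation machinery for that decision:

- **Six contour-accuracy metrics** comparing an auto-segmented mask `A`
  to a manual reference contour `R` on a voxel grid with physical
  spacing: Dice similarity coefficient (DSC = 2|A∩R|/(|A|+|R|)), mean
  distance to agreement (MDA, mm), 95th-percentile Hausdorff distance
  (HD95%, mm), signed percent volume difference (PVD, %), surface Dice at
  a 2 mm tolerance (sDSC), and added path length (APL, mm) — the length
  of reference contour beyond tolerance of the auto contour, a proxy for
  editing effort — plus its volume-normalized form rAPL = APL/V_ref
  (mm/cc), which makes editing effort comparable between a 3 cc
  esophagus and a 300 cc liver.
- **Quality categories and an editing scorecard**: per-metric
  best/good/suboptimal thresholds, a 1–6 ordinal editing-burden score,
  and the aggregation that turns per-case per-organ results into
  per-organ and per-model summary tables.
- **MRI intensity standardization**: N4 bias-field correction,
  Perona–Malik anisotropic diffusion, foreground-median normalization,
  and a percentile-windowed Z-score for training input.
- **Augmentation transforms**: seeded random gamma (p = 0.3,
  γ ∈ [0.7, 1.3]) and smooth 3D elastic deformation applied identically
  to image and labels.
- **Synthetic phantoms**: a 12-organ abdominal caricature with known
  masks, bias field and noise, plus perturbation operators and a
  benchmark suite with analytically known metric values — so everything
  above is testable without clinical data.

Surface metrics are computed on exposed voxel faces with exact
nearest-neighbour distances and are validated against an explicit
brute-force oracle to 1e-6 mm (see `docs/methods.md` for conventions and
assumptions).

## Worked example

```python
import numpy as np
from contourqa import (MetricConfig, PerturbationSpec, PhantomSpec,
                       evaluate_pair, make_phantom, perturb,
                       structures_from_masks, grade_metric)

# a 12-organ phantom, and an "auto-segmentation" that misses each organ
# by a 3 mm shift
vol, ref, _ = make_phantom(PhantomSpec(seed=3))
auto = structures_from_masks({
    name: perturb(m, PerturbationSpec("translate_mm", 3.0)).mask
    for name, m in ref.items()})

results = evaluate_pair(auto, ref, MetricConfig(tolerance_mm=2.0))
r = results["liver"]
print(f"liver DSC={r.dsc:.3f} MDA={r.mda_mm:.2f}mm "
      f"sDSC={r.sdsc:.3f} rAPL={r.rapl_mm_per_cc:.1f}mm/cc")
print("DSC category:", grade_metric("dsc", r.dsc))
```

prints

```
liver DSC=0.939 MDA=1.54mm sDSC=0.645 rAPL=14.4mm/cc
DSC category: best
```

A 3 mm shift barely dents the volumetric overlap of a ~225 cc liver
(DSC 0.94, graded *best*), but the surface metrics expose it: only 64% of
the boundary lies within the 2 mm tolerance, and correcting the contour
would mean redrawing ~14 mm of contour per cc of organ — exactly the
distinction between volume overlap and editing effort the surface
metrics exist to make.

The same operations are available as shell commands
(`contourqa phantom | standardize | augment | metrics`); the `metrics`
command writes a per-organ CSV report with metric values, categories, and
flags.

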