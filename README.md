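# gaussmap

Gauss-map curvature descriptors for subcortical shape analysis — a pipeline
for classifying subjects as normal control (NC), mild cognitive impairment
(MCI) or Alzheimer's disease (AD) from the *shape*, not just the volume, of
segmented hippocampus and amygdala masks.

## Why shape

Hippocampal and amygdalar atrophy in AD is focal: subregions erode, changing
how the surface bends long before global volume collapses. The Gauss map
sends each surface point p to its unit normal n(p); its derivative is the
shape operator S, a symmetric linear map on the tangent plane whose
eigenvalues are the principal curvatures κ₁ ≥ κ₂ (mm⁻¹). From it:

- **Gaussian curvature** K = κ₁κ₂ = det S — its sign classifies each point
  as elliptic (K > 0, sphere-like), parabolic (K = 0, cylinder-like) or
  hyperbolic (K < 0, saddle-like). Focal erosion creates hyperbolic rims.
- **Mean curvature** H = (κ₁+κ₂)/2 = tr S / 2 — the average signed bending.

The pipeline: NIfTI ROI masks → marching-cubes surface in world mm (Taubin
smoothed) → per-vertex quadric-fit shape operator → area-weighted histogram
descriptors → Fisher-score feature selection → hierarchical RBF-SVM
(stage 1: NC vs abnormal; stage 2: AD vs MCI), evaluated with repeated
stratified cross-validation, ROC curves and AUC. Two fusion designs are
built in: region-level (voxel union of the two ROIs before feature
extraction) and feature-level (per-region descriptors concatenated), plus a
volume-only baseline. A seeded phantom generator produces synthetic
two-region cohorts with class-dependent focal indentations so the whole
chain is testable with no clinical data.

See `docs/methods.md` for the model, estimators, calibration and
limitations.

## Worked example

Simulate a cohort of 8 subjects per class (two NIfTI masks each plus a
manifest CSV), then run the region-fusion shape-operator experiment:

```bash
gaussmap simulate --out demo_cohort --n-per-class 8 --seed 1
gaussmap run --manifest demo_cohort/manifest.csv --out demo_results \
    --mode region_fusion --feature shape_operator \
    --folds 4 --repeats 2 --seed 1
```

which prints

```json
{
  "mode": "region_fusion",
  "feature_type": "shape_operator",
  "overall_accuracy": 0.9166666666666666
}
```

and writes `results.json`, per-stage ROC point CSVs, per-subject
predictions and a full config snapshot into `demo_results/`. In this run
stage 1 (NC vs abnormal) reaches accuracy 1.000 with AUC 1.000, and stage 2
(AD vs MCI, the harder problem) accuracy 0.875 with AUC 0.902; overall
accuracy 0.917 is the fraction of subjects whose final hierarchical label
(NC, MCI or AD) matches the truth under cross-validation, so every stage-1
miss is also an overall miss. The same cohort under
`--mode volume_baseline` (one volume scalar per region) drops to stage-1
AUC ≈ 0.73 — the phantoms are built so that volume alone is a weak
classifier and curvature carries the class signal.

Other entry points: `gaussmap extract-surface` (mask → PLY),
`gaussmap curvature` (per-vertex κ₁, κ₂, K, H as CSV, optionally PLY),
`gaussmap features` (descriptor table), `gaussmap train` /
`gaussmap evaluate` (persist and reuse a fitted model). The same
functionality is available as a library:

```python
from gaussmap import (load_mask, fuse_regions, extract_surface,
                      compute_curvature)

fused = fuse_regions(load_mask("hippo.nii.gz"), load_mask("amyg.nii.gz"))
mesh = extract_surface(fused)          # world-mm, watertight, outward
field = compute_curvature(mesh)        # per-vertex S, kappa1/2, K, H
```

## Validation

The curvature stack is held to analytic ground truth: spheres and cylinders
must return their known curvatures, flat patches zero, and the integral of
K over any closed genus-0 surface must hit the Gauss-Bonnet value 4π within
2% (zero for a torus). Statistical components are checked against
independent brute-force oracles (Fisher scores by direct arithmetic, AUC by
pairwise win counting), and the end-to-end phantom experiment must recover
class structure while label permutation stays at chance.

`scripts/acceptance.py` re-runs the headline experiment from scratch —
generates a seeded phantom cohort, runs the hierarchical region-fusion
shape-operator pipeline and the volume baseline, prints their accuracies
and AUCs, and writes a JSON results object:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope

The package consumes already-segmented binary masks; brain extraction,
registration and segmentation (FSL/FreeSurfer/VolBrain territory) are
upstream. Phantoms emulate mask geometry, not hippocampal anatomy.
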