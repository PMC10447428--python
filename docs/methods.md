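# Methods

## Problem and approach

Alzheimer's disease and its prodromal stage (mild cognitive impairment, MCI)
atrophy the hippocampus and amygdala not only in volume but in local shape:
focal erosion changes the way the surface bends. `gaussmap` quantifies that
bending through the Gauss map — the map sending each surface point to its
unit normal — whose derivative at a point is the shape operator. The package
takes already-segmented binary ROI masks (NIfTI with a voxel-to-world
affine), reconstructs a closed triangle surface per ROI, estimates the
per-vertex shape operator and its invariants, reduces them to fixed-length
per-subject descriptors, and classifies subjects NC / MCI / AD with a
hierarchical pair of RBF-kernel SVMs. A phantom generator provides a fully
synthetic, seeded cohort so every stage is testable without clinical data.

## Surface reconstruction

The occupancy grid is zero-padded, filtered with a Gaussian of σ = 1 voxel,
and triangulated by marching cubes at level 0.5; vertices are mapped to
world millimetres through the affine and winding is fixed so the enclosed
signed volume is positive (outward normals), which also handles
mirror-image (negative-determinant) affines. The mesh is then smoothed with
Taubin's λ/μ flow (λ = 0.5, μ = −0.53, 20 iterations), which suppresses the
±45° staircase facets of binary marching cubes while changing enclosed
volume by well under 5%.

The pre-filter width matters because curvature is a second derivative: with
σ = 0.5 voxel the staircase residue leaves a Gauss-Bonnet residual of ~12%
and biases the median Gaussian curvature of a radius-20 sphere by −39%;
σ = 1.0 brings the residual to 0.7% and the bias to −9% while the
radius-20 sphere's mean curvature stays within 2% of 1/r. Both σ and the
smoothing schedule are configuration, not constants, and every run snapshots
them next to its results.

## Curvature estimation

At each vertex an orthonormal tangent frame (e1, e2, n) is erected from the
area-weighted vertex normal, and the neighbourhood within two topological
rings is fitted by least squares with the Monge patch

    z = ½(a x² + 2 b x y + c y²) + d x + e y .

The linear terms absorb error in the estimated normal. With gradient
(d, e) and Hessian [[a, b], [b, c]], the first and second fundamental forms
of the patch give the symmetric shape operator

    S = − I^{−1/2} II I^{−1/2},  II = Hess/√(1+d²+e²) ,

the minus sign fixing the convention that a sphere seen from outside curves
positively. Eigenvalues (closed form for symmetric 2×2) are the principal
curvatures κ1 ≥ κ2; K = κ1κ2 = det S and H = (κ1+κ2)/2 = tr S / 2 hold to
machine precision by construction. Rank-deficient neighbourhoods are
retried with a 3-ring; vertices that still fail are flagged and excluded
from descriptors (they are counted, and a cohort run aborts if more than
10% of subjects fail outright). Vertex areas are barycentric one-third
weights, which partition the mesh area exactly.

Two independent global checks guard the stack: the discrete Gauss-Bonnet
identity via angle deficits (exact for any closed mesh) and the requirement
that the fitted K integrate to 2πχ — within 2% on smoothed genus-0 phantoms,
and to zero (within 0.1·4π) on a torus.

Known bias: the quadric fit over a finite neighbourhood has an O(h²)
resolution-dependent bias (≈ +4% in K on a unit icosphere at subdivision 3,
+1% at subdivision 4). Descriptors are therefore comparable across subjects
meshed at the same voxel resolution, which the pipeline guarantees, but not
across resolutions.

## Descriptors

Vertex counts vary with ROI size, so per-vertex features are reduced to an
area-weighted histogram over a fixed value range (default) or an empirical
quantile vector (ablation; preserves units of mm⁻¹ / mm⁻²). The range is
the pooled 1st–99th percentile span of the training cohort, frozen and
re-applied to test subjects; values outside are clipped (winsorized),
taming the heavy tails that staircase residue creates. Feature types:
`shape_operator` (κ1 and κ2 histograms concatenated), `gaussian_curvature`
(K) and `mean_curvature` (H).

Default length is 32 bins per channel. At desk scale (60 subjects) the
64-bin shape-operator descriptor (128 dimensions) measurably overfits —
overall cross-validated accuracy drops from ~0.95 to ~0.89 across cohort
seeds — so 32 is the default and 64+ remains a flag.

Fusion designs mirror the two study arms: region-level fusion takes the
voxelwise union of the two masks before surface extraction (one fused ROI);
feature-level fusion concatenates per-region descriptors, hippocampus
first. The volume baseline (one scalar per region) exists to be beaten.

## Selection and classification

Dimensions are ranked by the multiclass Fisher score
F_j = Σ_c n_c(μ_cj − μ_j)² / Σ_c n_c σ²_cj (population variances); a
perfectly separating dimension (zero within-class variance, nonzero spread)
scores +∞ and ranks first. The two-stage classifier trains stage 1 on NC
vs {MCI ∪ AD} and stage 2 on AD vs MCI only; prediction short-circuits at
stage 1, with a decision value of exactly 0 breaking toward abnormal.
Each stage is Fisher selection → z-scoring → RBF SVM, with
k ∈ {16, 32, 64, 128, all}, C ∈ {0.1, 1, 10, 100} and
γ ∈ {0.1, 1, 10}/d chosen by an inner stratified 3-fold grid search.

Evaluation is repeated stratified k-fold (default 5×5, seeded). Every
fitted quantity — descriptor ranges, ranking, scaler, grid choice — is
refitted inside each training fold; a leakage canary test (an injected
feature equal to the label must be learnable, its shuffled twin must not)
guards the contract. Per-stage reports pool out-of-fold decision values;
stage 2's ROC is computed over truly-abnormal subjects only, its eligible
population. AUC is the trapezoid under the threshold-swept ROC, which
equals the normalised Mann-Whitney pairwise-win count.

The permutation-null check compares each stage's accuracy under label
permutation against the binomial 95% interval around that stage's
no-information rate. With equal class sizes stage 1 is 1:2 unbalanced, so
its chance level is the majority prior 2/3, not 1/2; stage 2's is 1/2.

## Phantom cohort

Each synthetic subject is two ellipsoids on a shared 1 mm grid: a
hippocampus-like shape (semi-axes 14×9×7 mm) and a smaller amygdala-like
one (8×6×5 mm, offset 24 mm). Disease class enters as a localized
atrophy-like indentation: a spherical-cap dent with C²-smooth profile
(1−t²)³, angular half-width 0.9 rad, depth 0 / 2.6 / 4.0 mm for
NC / MCI / AD (amygdala dents at 60% of that). Nuisance variation: a
uniform random rotation, log-normal global scale jitter (SD 0.012) and
smooth radial noise (SD 0.15 mm, five random low-frequency angular modes).
All draws descend from one SeedSequence, so cohorts are bit-reproducible.

The constants are a frozen calibration of the stated world: jitter sized so
that a volume-only classifier is weak but not useless (NC-vs-AD volume AUC
≈ 0.81–0.89 across cohort seeds, inside the intended 0.6–0.9 band), depths
sized so the full curvature pipeline clears 90% overall cross-validated
accuracy on three independent cohort seeds (0.975 / 0.950 / 0.925). They
are module constants, never adjusted by tests.

What a green phantom run does and does not establish: it shows the
geometry, descriptor, selection and CV machinery recover a known localized
curvature effect against realistic nuisance at clinical voxel sizes. It
does not model hippocampal anatomy (no CA subfields, no lateralization),
real segmentation error, scanner effects, or the overlapping biological
variation of an actual cohort — clinical accuracies cannot be inferred
from it.

## Numerical choices and edge cases

- Binarization threshold 0.5 on probabilistic maps; integer label maps via
  a label-select parameter; multiple connected components kept by default
  (warned) with a largest-component flag, since segmentation specks distort
  curvature statistics.
- Region fusion requires identical grid shape and affine agreement within
  1e-4; overlap collapses to 1 (set union).
- A mask too small to enclose an isosurface after filtering (e.g. a single
  voxel) raises a degenerate-surface error rather than returning an empty
  mesh.
- Ties in Fisher ranking break by ascending dimension index; stage-1
  decision ties break toward abnormal; both are deterministic.
- Multi-component masks yield one multi-component mesh; ring neighbourhoods
  never cross components, and Euler characteristic is 2 per genus-0
  component.

## Limitations

- No mesh correspondence across subjects: descriptors are distributional,
  so spatial localization of atrophy is not recovered, only its curvature
  signature.
- Curvature bias is resolution-dependent; cohorts must be processed at one
  voxel size.
- Spherical-harmonic descriptors, texture features, and volume as an extra
  classification feature are out of scope (volume exists only as the
  baseline arm).
- Brain extraction, registration and segmentation are upstream of this
  tool; masks are consumed as given.
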