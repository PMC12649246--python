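# Methods

This note documents the models, parameters and numerical choices behind
`carposeg`, and what its synthetic experiments do and do not demonstrate.

## Phantom model

The generator renders the intensity structure a wrist CT presents to a
threshold-based segmentation: a dense cortical shell (default 2106 HU)
around a trabecular interior (300 HU) on a soft-tissue background
(40 HU), with additive zero-mean Gaussian noise (default SD 20 HU), on an
anisotropic grid at the scan-protocol spacing 0.17 × 0.17 × 0.2 mm.
Shapes are a single ellipsoid or a smooth-max blend of two overlapping
ellipsoids (a waisted, scaphoid-like body); the cortical shell is
realized by shrinking every semi-axis by the shell thickness (default
1.2 mm, within the range of dense carpal cortex), which approximates —
but is not exactly — a constant-thickness shell.  Pose is applied to the
shape, never to the grid, so voxel geometry stays axis-aligned.  An
optional second ellipsoidal body at a controlled surface gap supports
joint-space experiments.

Ground truth: ellipsoid volumes are closed-form (4/3·π·abc); blended
shapes are integrated by quadrature — voxels whose 26-neighbourhood
contains a sign change of the implicit function are re-evaluated on a
10× oversampled sub-grid (configurable), everything else is classified by
its center.  The quadrature machinery is itself validated against the
ellipsoid closed form in the test suite.

What the phantom does **not** emulate: beam hardening, scanner PSF,
partial-volume blur, reconstruction kernels, patient/operator
variability, or cartilage.  Consequently segmented phantom volumes are
far more reproducible than real scans (replicate CV ~0.001% at default
noise versus ~0.6% in practice), and passing reproducibility tests bounds
only the algorithmic, not the acquisition, variability.

## Segmentation chain

1. **Region growing** — connected component of `{HU ≥ 1150}` (upper bound
   +∞ by default) containing the seed, 6-connected foreground.  The
   threshold is configurable; 1150 HU sits ≥ 3σ from both the cortical
   and trabecular levels at all noise levels used here.
2. **Hole filling** — background unreachable from the grid border becomes
   foreground, with 26-connected background (the complement of the
   foreground connectivity, avoiding topological paradoxes).
3. **Laplacian level set** — the front is initialized as the two-sided
   Euclidean signed distance of the filled mask (negative inside).  The
   zero crossing of this initialization lies on the voxel face between
   foreground and background centers; a distance map measured to voxel
   *centers* would start the front half a voxel inside the object and
   systematically lose ~4% volume on a 6 mm sphere.  The front then
   evolves with speed driven by the Laplacian of the Gaussian-smoothed
   image (ITK's Laplacian segmentation level set, expansion oriented to
   grow the bright region), with propagation/curvature weights 1.0/0.2.
   Evolution stops at the toolkit's default RMS-change criterion (0.02);
   the configured iteration counts (20 tight / 30 smooth) are caps.  This
   matters physically: on a curved surface the zero set of ∇²(G_σ∗I) sits
   ~2σ²/r outside the edge, and running a converged-front evolution to
   the bitter end would drag a σ = 1 mm segmentation ~0.2 mm outward on a
   6 mm bone; the convergence criterion keeps the front at the image
   edge, matching the near-zero signed deviation observed between tight
   and smooth models.
4. **Mesh extraction** — marching cubes at φ = 0 with linear edge
   interpolation; winding follows the field's sign convention (outward
   normals for negative-inside), so negating the field flips orientation.
   Duplicate vertices are merged; the result is watertight whenever the
   zero level avoids the grid border (guaranteed by the phantom margin).

The smooth workflow erodes the filled mask by a *physical* 0.5 mm radius
(ellipsoidal structuring element in index space — a per-axis voxel count
would be anisotropic) and overwrites the eroded region with 2106 HU.
Voxels already at cortical intensity inside the erosion are overwritten
too, giving a uniform interior.  The shell of the thin-shell test
phantom is 0.8 mm: thin relative to σ = 1.0 mm (so naive smoothing
widens it strongly, ~+31% volume) yet thicker than the 0.5 mm erosion
(so erosion + shell still tile the interior without a dark ring).

## Mesh measurements

* **Volume** — signed-tetrahedra sum over triangles; requires a closed
  mesh (boundary-edge count is reported otherwise).  Exact for closed
  oriented surfaces and translation-invariant.
* **Nearest-point queries** — exact: a KD-tree on the target's vertices
  yields a per-query upper bound (nearest vertex), every triangle with a
  vertex within that bound plus the largest triangle diameter is a
  candidate, and the true minimum is taken over exact point-triangle
  distances.  Equivalence with exhaustive search is asserted to 1e-9 in
  the tests.  Inside/outside comes from the angle-weighted pseudonormal
  of the nearest feature (face, edge or vertex), exact for watertight
  meshes.
* **Registration** — trimmed ICP with point-to-plane updates (linearized
  rigid solve against the nearest triangle's plane), correspondences
  trimmed at the 95th distance percentile, moving vertices subsampled by
  a deterministic stride to 2000 points.  The returned transform is the
  best (lowest RMS) visited, so the final RMS never exceeds the initial
  one; non-convergence is flagged, not raised.  Known-transform recovery
  (10°/2 mm) is accurate to < 0.1° / 0.01 mm.
* **Deviation maps** — sampled at reference-mesh vertices (one sample per
  vertex, so the included count equals the vertex count), signed positive
  where the reference lies outside the other mesh.  Summary SDs use the
  sample convention (n − 1).
* **Joint-space thickness** — articular region = vertices whose nearest
  point on the other bone is within 5 mm and whose outward normal faces
  it within 60° (both configurable; the articular region of a real joint
  is otherwise a manual delineation).  Interpenetrating meshes are
  rejected; an empty region returns an explicit "no facing surface"
  result.

## Paired statistics

Per-scan relative difference uses the second condition (thawed) as
denominator: 100·(B − A)/B; the display column is its absolute value.
The summary over relative differences takes the *signed* mean and a
*population* (divisor n) SD — the only pair of conventions consistent
with the reference table's printed summary row — while raw volume columns
use sample SDs.  The paired t-test reports t = d̄/(s_d/√n) with
df = n − 1, a two-sided p, CI d̄ ± t₀.₉₇₅·s_d/√n, and Cohen's
d = d̄/s_d; all four are mutually consistent by construction (the
reference table's separately printed SD of differences is not consistent
with its own t/CI/d and is not reproduced).  Zero-variance, zero-mean
differences define t = 0, p = 1.  Report display rounds half-up to two
decimals.

## Simulation design and problem sizes

The null/power simulation draws 20 repetitions of 10 two-condition scan
pairs of a 4 mm sphere phantom (≤ 64³ voxels), tight-segments all 400
volumes per simulation and tests each repetition at α = 0.05.  Condition
B is the same shape scaled isotropically to (1 + p)× the volume.  The
simulation noise is SD 250 HU — the largest value keeping every intensity
band ≥ 3σ from the growing threshold.  At the default SD 20 the segmented
volume responds to noise only in quantized boundary-voxel jumps
(difference SD ~0.007 mm³), a discrete, non-Gaussian regime in which the
n = 10 t-test is measurably anticonservative; at SD 250 the response is
continuous (volume CV ≈ 0.05%) and the test is well calibrated while a 3%
perturbation is detected with essentially full power.

Other standing sizes: volume-recovery and reproducibility checks use the
6 mm sphere at study spacing (~6·10⁵ voxels, ~3·10⁴ mesh vertices); the
end-to-end demo uses compact two-lobe and two-body phantoms.

## Known limitations

* The level-set speed weights and the growing threshold are not
  calibrated against any scanner; they are defaults that separate the
  phantom's intensity bands cleanly.
* The cortical shell is an offset-ellipsoid approximation, not a
  constant-thickness layer; truth volumes account for this exactly.
* Registration assumes a good initial overlap (same-object comparisons);
  there is no global initialization search.
* Real-specimen quantities (absolute scaphoid volumes, deviation extremes
  of a real bone, the scapho-capitate gap) require real scans; the
  package reproduces their report formats and the methodology, not their
  values.
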