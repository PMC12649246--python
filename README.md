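# carposeg

Segmentation and 3-D model comparison for small carpal bones in CT, built
around the workflow used to design patient-specific scaphoid prostheses.

When a prosthesis is modelled from a cadaver wrist, two questions decide
whether the model can be trusted: does frozen storage change the bone's
dimensions between scans, and does the surface smoothing required for a
manufacturable implant distort the anatomy?  `carposeg` implements the
complete measurement chain needed to answer both on volumetric data —
threshold-based segmentation with level-set refinement, mesh volumetry,
rigid registration, signed surface-deviation maps, joint-space thickness —
together with a synthetic CT phantom generator with analytic ground truth,
so every stage is testable without cadaver material.  It is aimed at
researchers in medical image analysis and additive-manufacturing
workflows who need a reproducible, scriptable version of this pipeline.

## Method

Segmentation follows the classic bone-modelling chain.  From a user seed
in the cortical shell, threshold-connected region growing selects the
connected component of `{v : HU(v) ≥ τ}` (default τ = 1150 HU), hole
filling closes the trabecular interior, and a Laplacian level set refines
the boundary: the front φ(x) (negative inside) is initialized as the
signed distance of the filled mask and evolves with speed proportional to
∇²(G_σ ∗ I), locking the zero level onto second-derivative zero crossings
of the Gaussian-smoothed image.  A triangle mesh is extracted at φ = 0 by
marching cubes, and its volume is the divergence-theorem sum
V = Σ_t det(v₀, v₁, v₂)/6 over triangles.

Two parameterizations are provided:

* **tight** — σ = 0.3 mm, ≤ 20 iterations: tracks the native cortical
  surface; used for volumetric comparison.
* **smooth** — σ = 1.0 mm, ≤ 30 iterations: prosthesis-ready surface.
  Because a Gaussian of width σ widens a *thin* bright shell (the
  inflection points of a blurred bar of half-width w < σ sit near ±σ, not
  ±w), the smooth workflow first segments without a level set, erodes the
  object by 0.5 mm, and overwrites the eroded region with 2106 HU (the
  cortical intensity).  The interior becomes uniformly bright, the outer
  boundary behaves like a step edge, and the widening largely disappears.

Model comparison: meshes are aligned by trimmed point-to-plane ICP; the
deviation map samples, at every reference-mesh vertex, the exact nearest
distance to the other surface, signed positive where the reference lies
outside ("reference larger").  Joint-space thickness is the nearest
distance from one bone's articular region (vertices facing the other bone
within 60° and within 5 mm) to the other bone.  Paired scan experiments
are summarized with a paired t-test (t = d̄/(s_d/√n)), its 95% CI, and
Cohen's d = d̄/s_d.

## Worked example

The package ships a reference table of ten frozen/thawed scaphoid volume
pairs (`src/carposeg/data/freeze_thaw_volumes.csv`).  Reproduce the
paired analysis:

```bash
carposeg stats compare --table src/carposeg/data/freeze_thaw_volumes.csv
```

```
n = 10 scan pairs (frozen vs thawed)
frozen: mean 1257.43 mm^3 (SD 7.85)
thawed: mean 1259.21 mm^3 (SD 3.98)
mean difference: 1.78 mm^3 (95% CI [-3.43, 6.98])
t(9) = 0.77, p = 0.46, Cohen's d = 0.24
relative difference: mean 0.14% (SD 0.55)
```

The mean frozen→thawed change is 1.78 mm³ (0.14% of the bone volume) with
p = 0.46: no detectable freezing effect.  The same workflow runs end to
end on synthetic data:

```python
from carposeg import (PhantomSpec, generate_phantom, cortical_seed,
                      tight_segment, mesh_volume)

spec = PhantomSpec(semi_axes=(6, 6, 6), noise_sd_hu=0.0)  # 6 mm sphere
volume, truth = generate_phantom(spec)                    # truth: 904.7787 mm^3
mesh = tight_segment(volume, cortical_seed(spec, volume))
print(round(mesh_volume(mesh), 2))                        # 905.64  (+0.09%)
```

`carposeg run` executes the full phantom study — replicate frozen/thawed
pairs with paired statistics, tight-vs-smooth deviation mapping, and a
two-bone joint-space report — writing CSV/JSON artifacts plus a hashed
manifest.

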