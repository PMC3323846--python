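# blobpet

Blob-based 3D PET image reconstruction on a polar grid, with a
symmetry-folded sparse system matrix and ML-EM.

## Who this is for

Researchers in emission-tomography image reconstruction who want a compact,
fully tested reference implementation of reconstruction with overlapping
spherically symmetric basis functions ("blobs") instead of cubic voxels:
scanner geometry modelling, system-matrix construction and folding over the
scanner's symmetry group, maximum-likelihood reconstruction, phantom
simulation and the standard image-quality figures of merit.

## The model

The radiotracer distribution is expanded in generalized Kaiser–Bessel
windows placed body-centred on a polar grid,

```
f(r) ≈ Σᵢ cᵢ ψ(|r − rᵢ|),
ψ(r) = [√(1−(r/a)²)]^m · I_m(α√(1−(r/a)²)) / I_m(α),   r ≤ a
```

with defaults m = 2, a = 1.994 Δ, α = 10.4 (continuous first derivative at
the support edge).  Measured coincidence counts y_d per line of response
(LOR) d are Poisson with mean q_d = Σ_b p_{d,b} c_b, where the system
response matrix (SRM) element p_{d,b} is the detection weight of blob b in
crystal pair d.  The ML-EM update

```
c_b ← (c_b / s_b) Σ_d p_{d,b} y_d / q_d,     s_b = Σ_d p_{d,b}
```

monotonically increases the Poisson log-likelihood and preserves
non-negativity.

The default scanner model is a small-animal ring of 18 polygonal modules
with two crystal layers of 4 × 8 crystals each (1,152 crystals, 662,976
LORs, 71 mm bore, 18.1 mm axial FOV).  Its symmetry group — 18 module-step
rotations × transaxial mirror × axial mirror, 72 elements — acts on
crystals, LORs and polar-grid blobs alike, so the SRM is computed and
stored only for one canonical "wedge" of blobs (1/72 of the grid) and every
other element is regenerated exactly through a look-up table:
p_{T(d),T(b)} = p_{d,b}.  The forward projection is a gathering operation
over the folded matrix across all 72 transforms; the backprojection is a
scattering operation offered in two equivalent strategies, `transpose`
(iterate a blob-ordered copy of the SRM) and `scatter` (LOR-ordered rows in
independent chunks with chunk-local accumulators, optionally in seeded
random order).

## Worked example

A desk-scale end-to-end study — scaled-down single-layer scanner, analytic
wedge SRM, hot/cold-rod image-quality phantom, 5 × 10⁶ Poisson
coincidences, 300 ML-EM iterations:

```python
import numpy as np
from blobpet import (ScannerSpec, build_polar_grid, BlobParams,
                     build_symmetry_lut, analytic_srm_wedge, lor_count,
                     make_image_quality_phantom, activity_to_coefficients,
                     simulate_counts, run_mlem, BlobImage, VoxelGrid,
                     rasterize, ROISpec)
from blobpet.fom import roi_stats

spec = ScannerSpec(n_modules=18, n_layers=1, crystals_tangential=4,
                   crystals_axial=4, crystal_size_mm=((2.0, 2.0, 6.0),),
                   layer_face_radius_mm=(35.5,), axial_pitch_mm=18.1 / 4,
                   tangential_pitch_mm=2.0)
grid = build_polar_grid(16, 72, 8, 2.0, params=BlobParams(delta=2.0),
                        n_modules=spec.n_modules)
lut = build_symmetry_lut(spec, grid)
print(f"{spec.n_crystals} crystals, {lor_count(spec)} LORs, "
      f"{spec.n_transforms} symmetries, {grid.n_blobs} blobs "
      f"({lut.n_wedge} in the wedge)")

srm = analytic_srm_wedge(spec, grid, lut, n_rays=16)
print(f"wedge SRM: {srm.n_rows} x {srm.n_cols}, {srm.nnz} nonzeros")

phantom = make_image_quality_phantom()          # warm 1 : hot 3 : cold 0
c_true = activity_to_coefficients(phantom, grid, mode="sample")
data = simulate_counts(c_true, srm, lut, total_counts=5e6, seed=1)
print(f"simulated {int(data.y.sum())} coincidences")

state = run_mlem(data, srm, lut, n_iter=300, log_every=300)
vg = VoxelGrid(nx=140, ny=140, nz=40, voxel_size=0.5)
vol = rasterize(BlobImage(grid, state.c), vg)
hot, _ = roi_stats(vol, ROISpec(centre=(15, 0, 0)), vg)
warm, _ = roi_stats(vol, ROISpec(centre=(0, 15, 0)), vg)
print(f"hot/warm ROI means: {hot:.3f} / {warm:.3f} "
      f"-> contrast ratio {hot / warm:.3f} (true 3.0)")
```

Output (about one minute on a laptop):

```
288 crystals, 41328 LORs, 72 symmetries, 9216 blobs (128 in the wedge)
wedge SRM: 41328 x 128, 199605 nonzeros
simulated 5001178 coincidences
hot/warm ROI means: 12.125 / 4.134 -> contrast ratio 2.933 (true 3.0)
```

The ROI means are in arbitrary activity units (the data carry only a count
budget); their ratio estimates the phantom's 3:1 hot-to-warm contrast, here
recovered to 2.2%.  The same pipeline is available from the shell via
`blobpet geometry / srm / simulate / recon / fom` with a YAML config; see
`blobpet --help`.

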