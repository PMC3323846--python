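# On-disk formats

Every binary payload is raw little-endian arrays plus a JSON sidecar at
`<file>.json`.  Sidecars always carry `magic`, `version` (currently 1) and
`package_version`; readers validate the payload size byte-for-byte against
the sidecar and raise `FormatError` on any mismatch.

## Sparse SRM — `.srm`

Payload: three arrays concatenated in order

| array   | dtype        | length          |
|---------|--------------|-----------------|
| row_ptr | `<i8`        | n_rows + 1      |
| col_idx | `<i4`        | nnz             |
| values  | sidecar says | nnz             |

Sidecar fields: `magic: "blobpet-srm"`, `ordering` (`"lor"` rows = LORs or
`"blob"` rows = blobs), `wedge_folded` (bool), `n_rows`, `n_cols`, `nnz`,
the three dtypes, and a `provenance` block (projector, ray/event counts,
floor, seed, grid shape, config hash).  `values_dtype` defaults to the
in-memory dtype (`<f8`); `<f4` halves the file at reduced precision.

An equivalent single-file HDF5 container (`write_srm_h5`) stores the same
arrays as datasets `row_ptr`, `col_idx`, `values` with the sidecar fields
as attributes.

## LOR histogram — `.lh`

Payload: `<u4` coincidence counts, one per LOR, indexed by
d = c₂(c₂−1)/2 + c₁ (c₁ < c₂).  Sidecar: `magic: "blobpet-lorhist"`,
`n_lor`, `total_counts` (validated against the payload sum) and a free
`meta` block (seed, count budget, config hash).

## Blob coefficients — `.coef`

Payload: `<f8` coefficients in blob-id order
(b = (k·n_angular + j)·n_axial + i_z).  Sidecar: `magic: "blobpet-coef"`,
`n`, `meta`.

## Volumes

Rasterized volumes are written either as NIfTI (`.nii.gz`, isotropic voxel
size and origin in the affine; float32) or as raw `<f4` in x-fastest
C-order with a sidecar (`magic: "blobpet-volume"`, `shape`, `voxel_size`,
`origin`).

## Crystal table — CSV

Header `id,module,layer,tangential,axial,x,y,z`; positions are inner-face
centres in mm in the scanner frame (z along the axis, module 0 centred on
+x).

## Run configuration — YAML

Blocks `scanner`, `grid`, `srm`, `simulate`, `recon`, `fom`; every block
and key is optional with the documented defaults.  A configuration fully
determines all deterministic outputs; its SHA-256 hash (first 16 hex
digits) is echoed into output provenance.  Example:

```yaml
scanner:
  n_modules: 18
  n_layers: 1
  crystals_tangential: 4
  crystals_axial: 4
  crystal_size_mm: [[2.0, 2.0, 6.0]]
  layer_face_radius_mm: [35.5]
  axial_pitch_mm: 4.525
grid:
  n_radial: 16
  n_angular: 72
  n_axial: 8
  delta: 2.0
srm:
  projector: analytic    # or mc (requires seed)
  n_rays: 16
  floor: 1.0e-9
simulate:
  phantom: iq            # or resolution
  total_counts: 5.0e6
  seed: 1
recon:
  iters: 300
  strategy: transpose    # or scatter
  log_every: 10
```
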