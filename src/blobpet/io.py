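"""File formats: sparse SRM, LOR histograms, coefficients, volumes, configs.

All binary payloads are raw little-endian arrays accompanied by a JSON
sidecar (``<file>.json``) that records the format magic/version, array
dtypes and lengths, dimensions and provenance.  Readers validate the
sidecar against the payload byte-for-byte and refuse truncated or
inconsistent files.

* ``.srm``    : row_ptr (int64) + col_idx (int32) + values (dtype in
                sidecar, float64 default) concatenated.
* ``.lh``     : uint32 coincidence counts, one per LOR.
* ``.coef``   : float64 blob coefficients.
* volumes     : NIfTI via nibabel (isotropic voxel size in the header) or
                raw float32 + sidecar.

An optional single-file HDF5 container mirrors the ``.srm`` arrays under
the same names.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import __version__
from .srm import SparseSRM

SRM_MAGIC = "blobpet-srm"
HIST_MAGIC = "blobpet-lorhist"
COEF_MAGIC = "blobpet-coef"
VOL_MAGIC = "blobpet-volume"
FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised on magic/version mismatch, truncation or sidecar conflicts."""


def config_hash(cfg: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, meta: dict):
    meta = dict(meta, package_version=__version__)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def _read_sidecar(path, magic: str) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing sidecar {sc}")
    with open(sc) as fh:
        meta = json.load(fh)
    if meta.get("magic") != magic:
        raise FormatError(f"{path}: magic {meta.get('magic')!r}, "
                          f"expected {magic!r}")
    if meta.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported format version "
                          f"{meta.get('version')}")
    return meta


# ---------------------------------------------------------------------------
# SRM
# ---------------------------------------------------------------------------

def write_srm(srm: SparseSRM, path, values_dtype=None):
    """Write ``path`` (raw arrays) + ``path.json`` sidecar.

    ``values_dtype`` defaults to the in-memory dtype (lossless round trip);
    pass 'float32' for a compact file.
    """
    m = srm.matrix
    row_ptr = np.asarray(m.indptr, dtype="<i8")
    col_idx = np.asarray(m.indices, dtype="<i4")
    vdt = np.dtype(values_dtype) if values_dtype else m.data.dtype
    values = np.asarray(m.data, dtype=vdt.newbyteorder("<"))
    with open(path, "wb") as fh:
        fh.write(row_ptr.tobytes())
        fh.write(col_idx.tobytes())
        fh.write(values.tobytes())
    _write_sidecar(path, {
        "magic": SRM_MAGIC, "version": FORMAT_VERSION,
        "ordering": srm.ordering, "wedge_folded": srm.wedge_folded,
        "n_rows": srm.n_rows, "n_cols": srm.n_cols, "nnz": int(m.nnz),
        "row_ptr_dtype": "<i8", "col_idx_dtype": "<i4",
        "values_dtype": values.dtype.str,
        "provenance": srm.provenance,
    })


def read_srm(path) -> SparseSRM:
    meta = _read_sidecar(path, SRM_MAGIC)
    n_rows, n_cols, nnz = meta["n_rows"], meta["n_cols"], meta["nnz"]
    vdt = np.dtype(meta["values_dtype"])
    expected = (n_rows + 1) * 8 + nnz * 4 + nnz * vdt.itemsize
    raw = Path(path).read_bytes()
    if len(raw) != expected:
        raise FormatError(f"{path}: file has {len(raw)} bytes, sidecar "
                          f"implies {expected} (truncated or inconsistent)")
    off = 0
    row_ptr = np.frombuffer(raw, dtype="<i8", count=n_rows + 1, offset=off)
    off += (n_rows + 1) * 8
    col_idx = np.frombuffer(raw, dtype="<i4", count=nnz, offset=off)
    off += nnz * 4
    values = np.frombuffer(raw, dtype=vdt, count=nnz, offset=off)
    if row_ptr[-1] != nnz:
        raise FormatError(f"{path}: row_ptr end {row_ptr[-1]} != nnz {nnz}")
    mat = sp.csr_matrix((values.copy(), col_idx.copy(), row_ptr.copy()),
                        shape=(n_rows, n_cols))
    return SparseSRM(matrix=mat, ordering=meta["ordering"],
                     wedge_folded=meta["wedge_folded"],
                     provenance=meta.get("provenance", {}))


def write_srm_h5(srm: SparseSRM, path):
    """Single-file HDF5 container with the same named arrays."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["magic"] = SRM_MAGIC
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["ordering"] = srm.ordering
        f.attrs["wedge_folded"] = srm.wedge_folded
        f.attrs["n_rows"] = srm.n_rows
        f.attrs["n_cols"] = srm.n_cols
        f.attrs["provenance"] = json.dumps(srm.provenance, default=str)
        f.create_dataset("row_ptr", data=srm.row_ptr.astype(np.int64))
        f.create_dataset("col_idx", data=srm.col_idx.astype(np.int32))
        f.create_dataset("values", data=srm.values)


def read_srm_h5(path) -> SparseSRM:
    import h5py
    with h5py.File(path, "r") as f:
        if f.attrs.get("magic") != SRM_MAGIC:
            raise FormatError(f"{path}: not a blobpet SRM container")
        mat = sp.csr_matrix(
            (f["values"][:], f["col_idx"][:], f["row_ptr"][:]),
            shape=(int(f.attrs["n_rows"]), int(f.attrs["n_cols"])))
        return SparseSRM(matrix=mat, ordering=str(f.attrs["ordering"]),
                         wedge_folded=bool(f.attrs["wedge_folded"]),
                         provenance=json.loads(f.attrs["provenance"]))


# ---------------------------------------------------------------------------
# LOR histograms
# ---------------------------------------------------------------------------

def write_histogram(hist, path, n_lor=None):
    from .recon import LORHistogram
    if not isinstance(hist, LORHistogram):
        hist = LORHistogram(y=hist)
    y = np.asarray(hist.y, dtype="<u4")
    if n_lor is not None and len(y) != n_lor:
        raise FormatError(f"histogram length {len(y)} != expected {n_lor}")
    with open(path, "wb") as fh:
        fh.write(y.tobytes())
    _write_sidecar(path, {
        "magic": HIST_MAGIC, "version": FORMAT_VERSION,
        "n_lor": len(y), "dtype": "<u4",
        "total_counts": int(y.sum()), "meta": hist.meta,
    })


def read_histogram(path, n_lor=None):
    from .recon import LORHistogram
    meta = _read_sidecar(path, HIST_MAGIC)
    raw = Path(path).read_bytes()
    if len(raw) != meta["n_lor"] * 4:
        raise FormatError(f"{path}: size {len(raw)} != 4*{meta['n_lor']}")
    if n_lor is not None and meta["n_lor"] != n_lor:
        raise FormatError(f"{path}: histogram length {meta['n_lor']} "
                          f"disagrees with the scanner spec ({n_lor} LORs)")
    y = np.frombuffer(raw, dtype="<u4").copy()
    if int(y.sum()) != meta["total_counts"]:
        raise FormatError(f"{path}: stored total_counts disagrees with data")
    return LORHistogram(y=y, meta=meta.get("meta", {}))


# ---------------------------------------------------------------------------
# Coefficients and volumes
# ---------------------------------------------------------------------------

def write_coefficients(c: np.ndarray, path, meta=None):
    c = np.asarray(c, dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(c.tobytes())
    _write_sidecar(path, {"magic": COEF_MAGIC, "version": FORMAT_VERSION,
                          "n": len(c), "dtype": "<f8",
                          "meta": meta or {}})


def read_coefficients(path) -> np.ndarray:
    meta = _read_sidecar(path, COEF_MAGIC)
    raw = Path(path).read_bytes()
    if len(raw) != meta["n"] * 8:
        raise FormatError(f"{path}: size mismatch")
    return np.frombuffer(raw, dtype="<f8").copy()


def write_volume_nifti(volume: np.ndarray, vg, path):
    """NIfTI export with the voxel size and origin in the affine."""
    import nibabel as nib
    affine = np.diag([vg.voxel_size] * 3 + [1.0])
    affine[:3, 3] = vg.origin
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms((vg.voxel_size,) * 3)
    nib.save(img, str(path))


def write_volume_raw(volume: np.ndarray, vg, path, meta=None):
    vol = np.asarray(volume, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(vol.tobytes())
    _write_sidecar(path, {"magic": VOL_MAGIC, "version": FORMAT_VERSION,
                          "shape": list(vol.shape), "dtype": "<f4",
                          "voxel_size": vg.voxel_size,
                          "origin": list(vg.origin), "meta": meta or {}})


def read_volume_raw(path):
    meta = _read_sidecar(path, VOL_MAGIC)
    raw = Path(path).read_bytes()
    shape = tuple(meta["shape"])
    if len(raw) != int(np.prod(shape)) * 4:
        raise FormatError(f"{path}: size mismatch")
    return np.frombuffer(raw, dtype="<f4").reshape(shape).copy(), meta
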