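"""Sparse system response matrix (SRM) construction and folding.

The SRM holds the detection weight p_{d,b} coupling an emission in blob b to
a coincidence in crystal pair (LOR) d.  Exploiting the scanner symmetry
group, weights are computed and stored only for the canonical "wedge" blobs;
every other element is regenerated through the look-up table:

    p_{d, T(b0)} = p_{T^-1(d), b0}        for any group transform T.

Two builders are provided.  The analytic projector averages the blob's
closed-form line footprint over a deterministic bundle of chords sampled
between the two crystal faces (a crystal-face generalisation of a line-
integral projector; geometric acceptance is deliberately absorbed into the
ML-EM sensitivity).  The Monte Carlo builder traces isotropic back-to-back
ray pairs from emission points drawn inside each blob proportionally to
psi, scoring the crystal pair whose volumes both rays intersect; it is a
physics-free (no attenuation, scatter, positron range or noncollinearity)
estimate of the absolute per-emission coincidence probability.

Matrices are stored LOR-ordered (CSR over LOR rows) or blob-ordered (the
transpose); both orderings carry identical nonzeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .blobgrid import PolarBlobGrid, kb_footprint
from .geometry import (CrystalTable, ScannerSpec, SymmetryLUT,
                       build_crystal_table, lor_count, lor_index, lor_unindex)

logger = logging.getLogger("blobpet")

DEFAULT_FLOOR = 1e-9
DEFAULT_N_RAYS = 16


@dataclass
class SparseSRM:
    """Sparse p_{d,b} container.

    ``ordering`` is 'lor' (rows = LORs) or 'blob' (rows = blobs).  For a
    wedge-folded matrix the blob dimension indexes canonical wedge blobs
    (column slot = ``lut.wedge_col[blob_id]``); otherwise it indexes all
    blobs.  ``matrix`` is scipy CSR; ``row_ptr``/``col_idx``/``values``
    expose the raw arrays.
    """

    matrix: sp.csr_matrix
    ordering: str
    wedge_folded: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ordering not in ("lor", "blob"):
            raise ValueError("ordering must be 'lor' or 'blob'")
        self.matrix = sp.csr_matrix(self.matrix)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def nnz(self) -> int:
        return self.matrix.nnz

    @property
    def row_ptr(self) -> np.ndarray:
        return self.matrix.indptr

    @property
    def col_idx(self) -> np.ndarray:
        return self.matrix.indices

    @property
    def values(self) -> np.ndarray:
        return self.matrix.data


# ---------------------------------------------------------------------------
# Crystal-face ray sampling
# ---------------------------------------------------------------------------

def _face_points(table: CrystalTable, g: int) -> np.ndarray:
    """(C, g*g, 3) stratified sample points on every inner crystal face.

    Offsets (i+1/2)/g - 1/2 are symmetric about the face centre, so the point
    set is invariant under the scanner's reflection symmetries.
    """
    offs = (np.arange(g) + 0.5) / g - 0.5
    ot, oz = np.meshgrid(offs, offs, indexing="ij")
    ot = ot.ravel()
    oz = oz.ravel()
    zhat = np.array([0.0, 0.0, 1.0])
    pts = (table.positions[:, None, :]
           + (ot[None, :, None] * (2.0 * table.half_width[:, None, None]))
           * table.tangentials[:, None, :]
           + (oz[None, :, None] * (2.0 * table.half_height[:, None, None]))
           * zhat[None, None, :])
    return pts


def _ray_grid_side(n_rays: int) -> int:
    g = int(round(np.sqrt(n_rays)))
    if g * g != n_rays or g < 1:
        raise ValueError("n_rays must be a positive perfect square (1, 4, 16, ...)")
    return g


def _chord_weights(spec, grid, blob_centres, c1, c2, pts, params):
    """Mean footprint over paired face-to-face chords for a block of LORs.

    Returns a dense (n_lor_block, n_blob_sel) array of p values.
    """
    A = pts[c1]              # (L, R, 3)
    B = pts[c2]              # (L, R, 3)
    u = B - A
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    P = blob_centres         # (W, 3)
    v = P[None, None, :, :] - A[:, :, None, :]          # (L, R, W, 3)
    t = np.einsum("lrwk,lrk->lrw", v, u)
    perp = v - t[..., None] * u[:, :, None, :]
    dist = np.linalg.norm(perp, axis=-1)                # (L, R, W)
    out = np.zeros_like(dist)
    mask = dist < params.a
    if np.any(mask):
        out[mask] = kb_footprint(dist[mask], params)
    return out.mean(axis=1)                             # (L, W)


def _build_analytic(spec: ScannerSpec, grid: PolarBlobGrid,
                    blob_ids: np.ndarray, n_rays: int, floor: float,
                    chunk: int = 512) -> sp.csr_matrix:
    """LOR-ordered CSR over the given blob columns (dense column slots)."""
    table = build_crystal_table(spec)
    g = _ray_grid_side(n_rays)
    pts = _face_points(table, g)
    n_lor = lor_count(spec)
    centres = grid.centres[blob_ids]
    params = grid.params

    all_d = np.arange(n_lor, dtype=np.int64)
    c1, c2 = lor_unindex(all_d)

    indptr = np.zeros(n_lor + 1, dtype=np.int64)
    idx_parts, val_parts = [], []
    for start in range(0, n_lor, chunk):
        sl = slice(start, min(start + chunk, n_lor))
        p = _chord_weights(spec, grid, centres, c1[sl], c2[sl], pts, params)
        keep = p >= floor if floor > 0 else p > 0
        counts = keep.sum(axis=1)
        indptr[start + 1:sl.stop + 1] = counts
        rows, cols = np.nonzero(keep)
        idx_parts.append(cols.astype(np.int32))
        val_parts.append(p[rows, cols])
    np.cumsum(indptr, out=indptr)
    indices = (np.concatenate(idx_parts) if idx_parts
               else np.empty(0, dtype=np.int32))
    data = (np.concatenate(val_parts) if val_parts
            else np.empty(0, dtype=np.float64))
    return sp.csr_matrix((data, indices, indptr),
                         shape=(n_lor, len(blob_ids)))


def analytic_srm_wedge(spec: ScannerSpec, grid: PolarBlobGrid,
                       lut: SymmetryLUT, n_rays: int = DEFAULT_N_RAYS,
                       floor: float = DEFAULT_FLOOR) -> SparseSRM:
    """Wedge-folded analytic SRM: rows = all LORs, columns = canonical blobs.

    p_{d,b} is the mean over ``n_rays`` face-sampled chords of the blob's
    line footprint at the chord's perpendicular distance; entries below
    ``floor`` are dropped.  Deterministic: identical configs rebuild
    bit-identical matrices.
    """
    mat = _build_analytic(spec, grid, lut.wedge_blobs, n_rays, floor)
    if mat.nnz == 0:
        raise ValueError(
            "analytic SRM is empty: no chord passes within a blob radius of "
            "any wedge blob (check grid placement vs scanner bore)")
    prov = {"projector": "analytic-footprint", "n_rays": n_rays,
            "floor": floor, "n_modules": spec.n_modules,
            "grid": [grid.n_radial, grid.n_angular, grid.n_axial],
            "delta": grid.delta}
    logger.info("analytic wedge SRM: %d x %d, nnz=%d",
                mat.shape[0], mat.shape[1], mat.nnz)
    return SparseSRM(matrix=mat, ordering="lor", wedge_folded=True,
                     provenance=prov)


def analytic_srm_full(spec: ScannerSpec, grid: PolarBlobGrid,
                      n_rays: int = DEFAULT_N_RAYS,
                      floor: float = DEFAULT_FLOOR) -> SparseSRM:
    """Unfolded analytic SRM over all blobs (no symmetry use); the brute
    force reference for fold/unfold validation and the dense oracle in
    projector tests."""
    blob_ids = np.arange(grid.n_blobs, dtype=np.int64)
    mat = _build_analytic(spec, grid, blob_ids, n_rays, floor)
    prov = {"projector": "analytic-footprint", "n_rays": n_rays,
            "floor": floor, "folded": False}
    return SparseSRM(matrix=mat, ordering="lor", wedge_folded=False,
                     provenance=prov)


# ---------------------------------------------------------------------------
# Geometric Monte Carlo builder
# ---------------------------------------------------------------------------

def _sample_blob_points(rng, centre, params, n):
    """Emission points within a blob, density proportional to psi (rejection
    from the uniform ball; psi(0)=1 bounds the density)."""
    from .blobgrid import kb_profile
    out = np.empty((0, 3))
    while len(out) < n:
        m = max(n - len(out), 1024)
        u = rng.standard_normal((m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = params.a * rng.random(m) ** (1.0 / 3.0)
        pts = u * r[:, None]
        accept = rng.random(m) < kb_profile(r, params)
        out = np.vstack([out, pts[accept]])
    return centre + out[:n]


def _ray_crystal_hits(table: CrystalTable, origins, dirs):
    """First crystal intersected by each ray, -1 if none.

    Crystals are axis-aligned boxes in their module frame (tangential, axial,
    radial); a slab test per crystal, vectorised over rays.
    """
    n = len(origins)
    best_t = np.full(n, np.inf)
    best_c = np.full(n, -1, dtype=np.int64)
    for c in range(len(table)):
        e_r = -table.normals[c]
        e_t = table.tangentials[c]
        zhat = np.array([0.0, 0.0, 1.0])
        centre = (table.positions[c] + 0.5 * table.depth[c] * e_r)
        half = np.array([table.half_width[c], table.half_height[c],
                         0.5 * table.depth[c]])
        axes = np.stack([e_t, zhat, e_r])        # (3, 3)
        o = (origins - centre) @ axes.T          # local coords
        d = dirs @ axes.T
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-half - o) / d
            t2 = (half - o) / d
        lo = np.minimum(t1, t2)
        hi = np.maximum(t1, t2)
        # rays parallel to a slab: inside iff |o| <= half
        par = d == 0.0
        inside = np.abs(o) <= half
        lo = np.where(par, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(par, np.where(inside, np.inf, -np.inf), hi)
        t_in = lo.max(axis=1)
        t_out = hi.min(axis=1)
        hit = (t_out >= np.maximum(t_in, 0.0)) & (t_out > 0.0)
        t_entry = np.maximum(t_in, 0.0)
        better = hit & (t_entry < best_t)
        best_t = np.where(better, t_entry, best_t)
        best_c = np.where(better, c, best_c)
    return best_c


def mc_srm_wedge(spec: ScannerSpec, grid: PolarBlobGrid, lut: SymmetryLUT,
                 n_events: int, seed, floor: float = 0.0,
                 batch: int = 65536) -> SparseSRM:
    """Geometric Monte Carlo wedge SRM: p_{d,b} = coincidences / n_events.

    ``n_events`` back-to-back ray pairs are traced per canonical blob; a
    coincidence scores the unordered pair of the first-intersected crystals
    (first-hit layer wins).  ``seed`` is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("mc_srm_wedge requires an explicit seed")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    table = build_crystal_table(spec)
    n_lor = lor_count(spec)
    rng = np.random.default_rng(seed)

    mat = sp.lil_matrix((n_lor, lut.n_wedge), dtype=np.float64)
    for col, b in enumerate(lut.wedge_blobs):
        if n_events == 0:
            continue
        centre = grid.centres[b]
        counts = {}
        done = 0
        while done < n_events:
            m = min(batch, n_events - done)
            pts = _sample_blob_points(rng, centre, grid.params, m)
            u = rng.standard_normal((m, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            h1 = _ray_crystal_hits(table, pts, u)
            h2 = _ray_crystal_hits(table, pts, -u)
            ok = (h1 >= 0) & (h2 >= 0) & (h1 != h2)
            if np.any(ok):
                d = lor_index(h1[ok], h2[ok])
                d = np.atleast_1d(d)
                uniq, cnt = np.unique(d, return_counts=True)
                for dd, cc in zip(uniq, cnt):
                    counts[int(dd)] = counts.get(int(dd), 0) + int(cc)
            done += m
        for dd, cc in counts.items():
            p = cc / n_events
            if p > floor:
                mat[dd, col] = p

    mat = mat.tocsr()
    prov = {"projector": "mc-geometric", "n_events": int(n_events),
            "seed": int(seed), "floor": floor}
    logger.info("MC wedge SRM: %d x %d, nnz=%d", mat.shape[0], mat.shape[1],
                mat.nnz)
    return SparseSRM(matrix=mat, ordering="lor", wedge_folded=True,
                     provenance=prov)


# ---------------------------------------------------------------------------
# Transpose, unfolded lookup, validation
# ---------------------------------------------------------------------------

def transpose_srm(srm: SparseSRM) -> SparseSRM:
    """Blob-ordered view of a LOR-ordered SRM (and vice versa); identical
    nonzeros, p^T_{b,d} == p_{d,b}."""
    mat = srm.matrix.T.tocsr()
    ordering = "blob" if srm.ordering == "lor" else "lor"
    return SparseSRM(matrix=mat, ordering=ordering,
                     wedge_folded=srm.wedge_folded,
                     provenance=dict(srm.provenance, transposed=True))


def unfold_lookup(srm: SparseSRM, lut: SymmetryLUT, d, b) -> float:
    """p_{d,b} for ANY LOR d and blob b from a wedge-folded LOR-ordered SRM.

    Blob b = T(b0) for its canonical wedge blob b0 and stored transform T;
    by equivariance p_{d,b} = p_{T^-1(d), b0}.  Returns 0 for absent
    elements.
    """
    if srm.ordering != "lor" or not srm.wedge_folded:
        raise ValueError("unfold_lookup needs a wedge-folded LOR-ordered SRM")
    n_lor = srm.n_rows
    if not (0 <= d < n_lor):
        raise ValueError("LOR index out of range")
    if not (0 <= b < lut.grid.n_blobs):
        raise ValueError("blob id out of range")
    b0 = lut.blob_canon[b]
    tid = lut.blob_tf[b]
    d0 = lut.lor_perms[lut.inv_ids[tid]][d]
    col = lut.wedge_col[b0]
    return float(srm.matrix[d0, col])


def unfold_full_matrix(srm: SparseSRM, lut: SymmetryLUT) -> sp.csr_matrix:
    """Materialise the full (n_lor x n_blobs) matrix from a wedge-folded
    LOR-ordered SRM.  Intended for small systems (validation, oracles)."""
    if srm.ordering != "lor" or not srm.wedge_folded:
        raise ValueError("expects a wedge-folded LOR-ordered SRM")
    n_blob = lut.grid.n_blobs
    # each blob b receives the column S[:, wedge_col[canon(b)]] with its
    # LOR axis permuted by the inverse of the stored transform
    csc = srm.matrix.tocsc()
    dense = np.zeros((srm.n_rows, n_blob), dtype=np.float64)
    for b in range(n_blob):
        b0 = lut.blob_canon[b]
        tid = lut.blob_tf[b]
        perm_inv = lut.lor_perms[lut.inv_ids[tid]]
        colvec = csc[:, lut.wedge_col[b0]].toarray().ravel()
        dense[:, b] = colvec[perm_inv]      # p_{d,b} = p_{T^-1(d), b0}
    return sp.csr_matrix(dense)


def validate_srm(srm: SparseSRM) -> dict:
    """Invariant check report: failures list plus nnz/fill/per-row stats."""
    failures = []
    m = srm.matrix
    if np.any(m.data < 0):
        failures.append("negative values present")
    if not np.all(np.isfinite(m.data)):
        failures.append("non-finite values present")
    if np.any(np.diff(m.indptr) < 0):
        failures.append("row_ptr not non-decreasing")
    if m.nnz and (m.indices.min() < 0 or m.indices.max() >= m.shape[1]):
        failures.append("column indices out of range")
    row_nnz = np.diff(m.indptr)
    report = {
        "failures": failures,
        "n_rows": m.shape[0],
        "n_cols": m.shape[1],
        "nnz": int(m.nnz),
        "fill_fraction": float(m.nnz / (m.shape[0] * m.shape[1])),
        "row_nnz_min": int(row_nnz.min()) if len(row_nnz) else 0,
        "row_nnz_max": int(row_nnz.max()) if len(row_nnz) else 0,
        "row_nnz_mean": float(row_nnz.mean()) if len(row_nnz) else 0.0,
        "value_min": float(m.data.min()) if m.nnz else None,
        "value_max": float(m.data.max()) if m.nnz else None,
    }
    return report
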