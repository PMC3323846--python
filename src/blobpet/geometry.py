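"""Polygonal PET scanner geometry and its cylindrical symmetry group.

The scanner is a ring of ``n_modules`` flat detector modules, each carrying
``n_layers`` radial layers of a ``crystals_tangential x crystals_axial``
crystal array.  The default specification reproduces the MADPET-II small
animal scanner: 18 modules, two LYSO layers (front 2x2x6 mm3, rear
2x2x8 mm3), 71 mm radial diameter and 18.1 mm axial field of view, for a
total of 1,152 crystals and 662,976 unordered crystal pairs (LORs).

The polygonal layout admits a symmetry group generated by module-step
rotations about the scanner axis, a transaxial reflection (about the plane
through the centre of module 0) and an axial reflection (about the central
transaxial plane): ``4 * n_modules`` elements, 72 for the default scanner.
Folding the system response matrix over this group stores each probability
once per group orbit; the look-up tables built here map every crystal, LOR
and blob to its canonical orbit representative and the transform that
regenerates it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("blobpet")

# ---------------------------------------------------------------------------
# Scanner specification
# ---------------------------------------------------------------------------

#: MADPET-II-like defaults: per-layer (tangential, axial, radial) crystal
#: sizes in mm and inner face radii in mm.  The front face sits at 35.5 mm
#: (71 mm bore diameter); the rear layer face at 35.5 + 6 mm.  Crystal pitch
#: equals crystal width (no tangential gap) and the axial pitch spreads
#: 8 crystals over the 18.1 mm axial FOV.  Gaps are not published for the
#: scanner; these are configurable assumptions.
_DEFAULT_SIZES = ((2.0, 2.0, 6.0), (2.0, 2.0, 8.0))
_DEFAULT_RADII = (35.5, 41.5)


@dataclass(frozen=True)
class ScannerSpec:
    """Parametric polygonal dual-layer scanner description (mm units)."""

    n_modules: int = 18
    n_layers: int = 2
    crystals_tangential: int = 4
    crystals_axial: int = 8
    crystal_size_mm: tuple = _DEFAULT_SIZES
    layer_face_radius_mm: tuple = _DEFAULT_RADII
    axial_pitch_mm: float = 18.1 / 8
    tangential_pitch_mm: float = 2.0

    def __post_init__(self):
        if self.n_modules < 3:
            raise ValueError("n_modules must be >= 3")
        for name in ("n_layers", "crystals_tangential", "crystals_axial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.crystal_size_mm) != self.n_layers:
            raise ValueError("crystal_size_mm needs one (t, z, r) triple per layer")
        if len(self.layer_face_radius_mm) != self.n_layers:
            raise ValueError("layer_face_radius_mm needs one radius per layer")
        for triple in self.crystal_size_mm:
            if len(triple) != 3 or any(s <= 0 for s in triple):
                raise ValueError("crystal sizes must be positive (t, z, r) triples")
        if any(r <= 0 for r in self.layer_face_radius_mm):
            raise ValueError("layer face radii must be positive")
        if self.axial_pitch_mm <= 0 or self.tangential_pitch_mm <= 0:
            raise ValueError("pitches must be positive")

    @property
    def n_crystals(self) -> int:
        return (self.n_modules * self.n_layers
                * self.crystals_tangential * self.crystals_axial)

    @property
    def n_transforms(self) -> int:
        """Order of the symmetry group: rotations x 2 mirrors."""
        return 4 * self.n_modules

    def crystal_id(self, module, layer, tangential, axial):
        """Flat crystal id for (module, layer, tangential, axial) indices."""
        module = np.asarray(module)
        nt, na = self.crystals_tangential, self.crystals_axial
        return ((module * self.n_layers + layer) * nt + tangential) * na + axial

    def crystal_tuple(self, cid):
        cid = np.asarray(cid)
        nt, na = self.crystals_tangential, self.crystals_axial
        axial = cid % na
        rest = cid // na
        tangential = rest % nt
        rest = rest // nt
        layer = rest % self.n_layers
        module = rest // self.n_layers
        return module, layer, tangential, axial


# ---------------------------------------------------------------------------
# Crystal table
# ---------------------------------------------------------------------------

@dataclass
class CrystalTable:
    """Per-crystal geometry derived from a :class:`ScannerSpec`.

    ``positions`` are inner-face centres in mm; ``normals`` are inward unit
    vectors; ``tangentials`` / ``axials_dir`` span each face.  The face half
    extents and radial depths are kept for ray sampling and Monte Carlo
    crystal-volume intersection.
    """

    spec: ScannerSpec
    module: np.ndarray
    layer: np.ndarray
    tangential: np.ndarray
    axial: np.ndarray
    positions: np.ndarray      # (C, 3) face centres
    normals: np.ndarray        # (C, 3) inward
    tangentials: np.ndarray    # (C, 3) unit tangential axis (in-face)
    half_width: np.ndarray     # (C,) tangential half size
    half_height: np.ndarray    # (C,) axial half size
    depth: np.ndarray          # (C,) radial size

    def __len__(self):
        return len(self.module)

    def to_csv(self, path_or_buf):
        """Export id, indices and face-centre position as CSV."""
        header = "id,module,layer,tangential,axial,x,y,z"
        ids = np.arange(len(self))
        cols = np.column_stack([
            ids, self.module, self.layer, self.tangential, self.axial,
            self.positions[:, 0], self.positions[:, 1], self.positions[:, 2],
        ])
        fmt = ["%d"] * 5 + ["%.6f"] * 3
        if hasattr(path_or_buf, "write"):
            np.savetxt(path_or_buf, cols, fmt=fmt, delimiter=",",
                       header=header, comments="")
        else:
            with open(path_or_buf, "w") as fh:
                np.savetxt(fh, cols, fmt=fmt, delimiter=",",
                           header=header, comments="")


def build_crystal_table(spec: ScannerSpec) -> CrystalTable:
    """Place every crystal of the polygonal ring.

    Module ``m`` is centred at azimuth ``2*pi*m / n_modules`` with its face
    perpendicular to the radial direction; crystals are offset symmetrically
    about the module centre along the tangential and axial directions.
    """
    C = spec.n_crystals
    cid = np.arange(C)
    module, layer, tang, axial = spec.crystal_tuple(cid)

    phi = 2.0 * np.pi * module / spec.n_modules
    e_r = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(C)])
    e_t = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(C)])

    radii = np.asarray(spec.layer_face_radius_mm, dtype=float)[layer]
    sizes = np.asarray(spec.crystal_size_mm, dtype=float)[layer]  # (C, 3)

    u = (tang - (spec.crystals_tangential - 1) / 2.0) * spec.tangential_pitch_mm
    z = (axial - (spec.crystals_axial - 1) / 2.0) * spec.axial_pitch_mm

    pos = radii[:, None] * e_r + u[:, None] * e_t
    pos[:, 2] = z

    return CrystalTable(
        spec=spec, module=module, layer=layer, tangential=tang, axial=axial,
        positions=pos, normals=-e_r, tangentials=e_t,
        half_width=sizes[:, 0] / 2.0, half_height=sizes[:, 1] / 2.0,
        depth=sizes[:, 2],
    )


# ---------------------------------------------------------------------------
# LOR (unordered crystal pair) indexing
# ---------------------------------------------------------------------------

def lor_index(c1, c2):
    """Flat index of the unordered crystal pair: ``d = c2*(c2-1)/2 + c1``
    with ``c1 < c2`` after sorting.  Order-insensitive; ``c1 == c2`` invalid.
    """
    c1 = np.asarray(c1, dtype=np.int64)
    c2 = np.asarray(c2, dtype=np.int64)
    if np.any(c1 == c2):
        raise ValueError("a LOR requires two distinct crystals")
    lo = np.minimum(c1, c2)
    hi = np.maximum(c1, c2)
    d = hi * (hi - 1) // 2 + lo
    return d if d.ndim else int(d)


def lor_unindex(d):
    """Inverse of :func:`lor_index`: returns the sorted pair ``(c1, c2)``."""
    d = np.asarray(d, dtype=np.int64)
    if np.any(d < 0):
        raise ValueError("LOR index must be non-negative")
    hi = ((1.0 + np.sqrt(1.0 + 8.0 * d.astype(np.float64))) / 2.0).astype(np.int64)
    # guard against float rounding at large indices
    hi = np.where(hi * (hi - 1) // 2 > d, hi - 1, hi)
    hi = np.where((hi + 1) * hi // 2 <= d, hi + 1, hi)
    lo = d - hi * (hi - 1) // 2
    if d.ndim:
        return lo, hi
    return int(lo), int(hi)


def lor_count(spec: ScannerSpec) -> int:
    """Number of unordered crystal pairs, ``C*(C-1)/2``."""
    C = spec.n_crystals
    return C * (C - 1) // 2


# ---------------------------------------------------------------------------
# Symmetry transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymmetryTransform:
    """One element of the scanner symmetry group.

    Acting on a point: apply the transaxial mirror (y -> -y) if ``mirror_t``,
    the axial mirror (z -> -z) if ``mirror_z``, then rotate by
    ``2*pi*rot/n_modules``.  With this convention composition is
    ``(r2,t2,z2) o (r1,t1,z1) = (r2 + (-1)^t2 * r1, t1^t2, z1^z2)``.
    """

    rot: int
    mirror_t: bool
    mirror_z: bool
    n_modules: int

    def __post_init__(self):
        if not 0 <= self.rot < self.n_modules:
            raise ValueError("rot out of range")

    @property
    def id(self) -> int:
        return self.rot + self.n_modules * (int(self.mirror_t)
                                            + 2 * int(self.mirror_z))

    @classmethod
    def from_id(cls, tid: int, n_modules: int) -> "SymmetryTransform":
        if not 0 <= tid < 4 * n_modules:
            raise ValueError("transform id out of range")
        rot = tid % n_modules
        rest = tid // n_modules
        return cls(rot=rot, mirror_t=bool(rest % 2), mirror_z=bool(rest // 2),
                   n_modules=n_modules)

    def compose(self, other: "SymmetryTransform") -> "SymmetryTransform":
        """self o other (apply ``other`` first)."""
        if self.n_modules != other.n_modules:
            raise ValueError("transforms belong to different groups")
        sign = -1 if self.mirror_t else 1
        rot = (self.rot + sign * other.rot) % self.n_modules
        return SymmetryTransform(rot=rot,
                                 mirror_t=self.mirror_t ^ other.mirror_t,
                                 mirror_z=self.mirror_z ^ other.mirror_z,
                                 n_modules=self.n_modules)

    def inverse(self) -> "SymmetryTransform":
        rot = self.rot if self.mirror_t else (-self.rot) % self.n_modules
        return SymmetryTransform(rot=rot, mirror_t=self.mirror_t,
                                 mirror_z=self.mirror_z,
                                 n_modules=self.n_modules)


def all_transforms(spec: ScannerSpec):
    """The full group, ordered by flat transform id (identity first)."""
    return [SymmetryTransform.from_id(i, spec.n_modules)
            for i in range(spec.n_transforms)]


def transform_crystals(t: SymmetryTransform, spec: ScannerSpec, cid):
    """Image of crystal id(s) under a symmetry transform."""
    cid = np.asarray(cid)
    if np.any(cid < 0) or np.any(cid >= spec.n_crystals):
        raise ValueError("crystal id out of range")
    module, layer, tang, axial = spec.crystal_tuple(cid)
    module = module.copy()
    tang = tang.copy()
    axial = axial.copy()
    if t.mirror_t:
        module = (-module) % spec.n_modules
        tang = spec.crystals_tangential - 1 - tang
    if t.mirror_z:
        axial = spec.crystals_axial - 1 - axial
    module = (module + t.rot) % spec.n_modules
    out = spec.crystal_id(module, layer, tang, axial)
    return out


def transform_lors(t: SymmetryTransform, spec: ScannerSpec, d):
    """Image of LOR index/indices under a transform (endpoints mapped, pair
    re-canonicalized)."""
    scalar = np.ndim(d) == 0
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if np.any(d < 0) or np.any(d >= lor_count(spec)):
        raise ValueError("LOR index out of range")
    c1, c2 = lor_unindex(d)
    out = lor_index(transform_crystals(t, spec, c1),
                    transform_crystals(t, spec, c2))
    out = np.atleast_1d(out)
    return int(out[0]) if scalar else out


def transform_blobs(t: SymmetryTransform, grid, b):
    """Image of blob id(s) under a transform (grid from blobpet.blobgrid)."""
    b = np.asarray(b)
    if np.any(b < 0) or np.any(b >= grid.n_blobs):
        raise ValueError("blob id out of range")
    k, j, iz = grid.blob_tuple(b)
    j = j.copy()
    iz = iz.copy()
    if t.mirror_t:
        j = (grid.n_angular - 1 - j) % grid.n_angular
    if t.mirror_z:
        iz = grid.n_axial - 1 - iz
    step = grid.n_angular // t.n_modules
    j = (j + t.rot * step) % grid.n_angular
    return grid.blob_id(k, j, iz)


def apply_transform(t: SymmetryTransform, spec: ScannerSpec, x,
                    kind: str = "crystal", grid=None):
    """Apply a transform to a crystal id, LOR index or blob id."""
    if kind == "crystal":
        return transform_crystals(t, spec, x)
    if kind == "lor":
        return transform_lors(t, spec, x)
    if kind == "blob":
        if grid is None:
            raise ValueError("blob transforms need the grid")
        return transform_blobs(t, grid, x)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Symmetry look-up tables
# ---------------------------------------------------------------------------

@dataclass
class SymmetryLUT:
    """Orbit folding tables for LORs and blobs.

    For every element ``x``, ``*_canon[x]`` is the canonical representative
    (minimum flat index over the orbit of ``x``) and ``*_tf[x]`` the flat id
    of the transform with ``T(canonical) == x``.  ``wedge_blobs`` lists the
    canonical blob ids in increasing order; ``wedge_col[b]`` gives the column
    slot of canonical blob ``b`` in a wedge-folded SRM (-1 otherwise).
    """

    spec: ScannerSpec
    grid: "object"
    lor_canon: np.ndarray
    lor_tf: np.ndarray
    blob_canon: np.ndarray
    blob_tf: np.ndarray
    wedge_blobs: np.ndarray
    wedge_col: np.ndarray
    lor_perms: np.ndarray = field(repr=False, default=None)  # (T, n_lor)
    inv_ids: np.ndarray = None                               # (T,)

    @property
    def n_transforms(self) -> int:
        return self.spec.n_transforms

    @property
    def n_wedge(self) -> int:
        return len(self.wedge_blobs)

    def lor_perm(self, tid: int) -> np.ndarray:
        """Permutation array ``p`` with ``p[d] = T_tid(d)``."""
        return self.lor_perms[tid]


def check_commensurate(spec: ScannerSpec, grid):
    if grid.n_angular % (2 * spec.n_modules) != 0:
        raise ValueError(
            f"grid n_angular={grid.n_angular} is incommensurate with the "
            f"symmetry wedge: it must be divisible by 2*n_modules="
            f"{2 * spec.n_modules}")


def build_symmetry_lut(spec: ScannerSpec, grid) -> SymmetryLUT:
    """Fold LORs and blobs onto canonical orbit representatives.

    The canonical representative of an orbit is its minimum flat index; the
    stored transform maps the canonical element onto the original one, so
    unfolding visits each real element exactly once even for orbits with
    fewer than ``4*n_modules`` members (fixed points).
    """
    check_commensurate(spec, grid)
    transforms = all_transforms(spec)
    n_lor = lor_count(spec)
    n_blob = grid.n_blobs

    all_d = np.arange(n_lor, dtype=np.int64)
    all_b = np.arange(n_blob, dtype=np.int64)

    lor_perms = np.empty((len(transforms), n_lor), dtype=np.int32)
    lor_canon = all_d.copy()
    lor_min_tid = np.zeros(n_lor, dtype=np.int32)
    blob_canon = all_b.copy()
    blob_min_tid = np.zeros(n_blob, dtype=np.int32)

    for t in transforms:
        td = transform_lors(t, spec, all_d)
        lor_perms[t.id] = td
        better = td < lor_canon
        lor_canon = np.where(better, td, lor_canon)
        lor_min_tid = np.where(better, t.id, lor_min_tid)

        tb = transform_blobs(t, grid, all_b)
        better = tb < blob_canon
        blob_canon = np.where(better, tb, blob_canon)
        blob_min_tid = np.where(better, t.id, blob_min_tid)

    # stored transform maps canonical -> element: inverse of the minimizer
    inv_ids = np.array([t.inverse().id for t in transforms], dtype=np.int32)
    lor_tf = inv_ids[lor_min_tid]
    blob_tf = inv_ids[blob_min_tid]

    wedge_blobs = np.unique(blob_canon)
    wedge_col = np.full(n_blob, -1, dtype=np.int64)
    wedge_col[wedge_blobs] = np.arange(len(wedge_blobs))

    logger.info("symmetry LUT: %d transforms, %d canonical LORs, %d wedge blobs",
                len(transforms), len(np.unique(lor_canon)), len(wedge_blobs))
    return SymmetryLUT(spec=spec, grid=grid,
                       lor_canon=lor_canon, lor_tf=lor_tf.astype(np.int32),
                       blob_canon=blob_canon, blob_tf=blob_tf.astype(np.int32),
                       wedge_blobs=wedge_blobs, wedge_col=wedge_col,
                       lor_perms=lor_perms, inv_ids=inv_ids)
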