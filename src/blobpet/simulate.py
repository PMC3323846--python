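"""Synthetic phantoms and Poisson coincidence data.

Two study phantoms are generated as analytic activity fields in relative
concentration units (absolute activities are not modelled; the data scale
is set by a total-count budget):

* image-quality phantom — a warm cylinder (20 mm long, 30 mm radius,
  concentration 1) with two parallel rod inserts (20 mm long, 10 mm radius)
  placed symmetrically off-centre: a hot rod at 3x the background (3:1) and
  a cold rod at 0.
* resolution phantom — a warm ellipsoid (35 x 20 mm transaxially, 2 mm
  long, offset 12.5 mm) holding six hot point sources at 200:1 spaced 5 mm
  radially, and six cold spheres of 1.5 mm diameter.  Point sources are
  modelled as 0.5 mm diameter spheres (one reference voxel) so the field
  stays integrable.

Counts are simulated per LOR: the expected sinogram lambda = P c_true is
scaled to the requested total and each bin drawn as an independent Poisson
variable.  Back-to-back emission only — no decay, randoms or scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blobgrid import BlobImage, PolarBlobGrid, VoxelGrid, rasterize
from .geometry import SymmetryLUT
from .recon import FoldedSystem, LORHistogram
from .srm import SparseSRM


# ---------------------------------------------------------------------------
# Geometric components and phantom specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One geometric primitive with a relative activity concentration.

    ``kind`` in {'cylinder', 'ellipsoid', 'sphere'}; cylinders are axial
    (dims = (radius, length)); ellipsoids use semi-axes (rx, ry, rz);
    spheres use (radius,).  Later components override earlier ones.
    """

    kind: str
    centre: tuple
    dims: tuple
    concentration: float
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("cylinder", "ellipsoid", "sphere"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if any(d <= 0 for d in self.dims):
            raise ValueError("component dimensions must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pts) - np.asarray(self.centre)
        if self.kind == "cylinder":
            radius, length = self.dims
            return ((p[:, 0] ** 2 + p[:, 1] ** 2 <= radius ** 2)
                    & (np.abs(p[:, 2]) <= length / 2.0))
        if self.kind == "ellipsoid":
            rx, ry, rz = self.dims
            return ((p[:, 0] / rx) ** 2 + (p[:, 1] / ry) ** 2
                    + (p[:, 2] / rz) ** 2) <= 1.0
        radius, = self.dims
        return (p ** 2).sum(axis=1) <= radius ** 2


@dataclass
class PhantomSpec:
    """Ordered component list; evaluation is last-match-wins."""

    components: list
    total_counts: float = 4.5e7
    label: str = ""

    def activity(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        out = np.zeros(len(pts))
        for comp in self.components:
            inside = comp.contains(pts)
            out[inside] = comp.concentration
        return out

    def __call__(self, pts):
        scalar = np.ndim(pts) == 1
        out = self.activity(pts)
        return float(out[0]) if scalar else out


@dataclass
class ActivityMap:
    """Callable activity field with a bounding box (zero outside)."""

    phantom: PhantomSpec
    bbox: tuple   # ((xmin, xmax), (ymin, ymax), (zmin, zmax))

    def __call__(self, pts):
        scalar = np.ndim(pts) == 1
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        out = self.phantom.activity(pts)
        for ax, (lo, hi) in enumerate(self.bbox):
            out[(pts[:, ax] < lo) | (pts[:, ax] > hi)] = 0.0
        return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Study phantoms
# ---------------------------------------------------------------------------

#: rod offsets are not published; +/-15 mm keeps the 10 mm rods inside the
#: 30 mm warm cylinder with a 5 mm margin
IQ_ROD_OFFSET = 15.0


def make_image_quality_phantom(scale: float = 1.0,
                               warm_radius: float = 30.0,
                               rod_offset: float = IQ_ROD_OFFSET,
                               total_counts: float = 4.5e7) -> PhantomSpec:
    """Hot/cold-rod image-quality phantom (3:1 hot:warm)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    s = scale
    comps = [
        Component("cylinder", (0.0, 0.0, 0.0), (warm_radius * s, 20.0 * s),
                  1.0, "warm"),
        Component("cylinder", (rod_offset * s, 0.0, 0.0), (10.0 * s, 20.0 * s),
                  3.0, "hot"),
        Component("cylinder", (-rod_offset * s, 0.0, 0.0), (10.0 * s, 20.0 * s),
                  0.0, "cold"),
    ]
    return PhantomSpec(components=comps, total_counts=total_counts,
                       label="image-quality")


#: default point-source x positions (mm, scanner frame): six sources 5 mm
#: apart from the FOV centre outward; cold spheres on a parallel chord
RES_SOURCE_X = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)
RES_COLD_Y = -5.0
RES_POINT_DIAMETER = 0.5


def make_resolution_phantom(scale: float = 1.0,
                            total_counts: float = 9.6e6) -> PhantomSpec:
    """Ellipsoidal resolution phantom: six 200:1 point sources 5 mm apart
    and six cold 1.5 mm spheres on a warm background, offset 12.5 mm."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    s = scale
    comps = [Component("ellipsoid", (12.5 * s, 0.0, 0.0),
                       (17.5 * s, 10.0 * s, 1.0 * s), 1.0, "background")]
    for i, x in enumerate(RES_SOURCE_X):
        comps.append(Component("sphere", (x * s, RES_COLD_Y * s, 0.0),
                               (0.75 * s,), 0.0, f"cold{i}"))
    for i, x in enumerate(RES_SOURCE_X):
        comps.append(Component("sphere", (x * s, 0.0, 0.0),
                               (RES_POINT_DIAMETER / 2.0 * s,), 200.0,
                               f"ps{i}"))
    return PhantomSpec(components=comps, total_counts=total_counts,
                       label="resolution")


# ---------------------------------------------------------------------------
# Phantom -> blob coefficients
# ---------------------------------------------------------------------------

def activity_to_coefficients(phantom, grid: PolarBlobGrid,
                             mode: str = "sample",
                             vg: VoxelGrid = None) -> BlobImage:
    """Convert an activity field to blob coefficients.

    'sample' sets c_i = A(r_i) at each blob centre; 'lstsq' solves the
    non-negative least-squares fit of the rasterized blob expansion to the
    field sampled on a voxel grid (small grids only).
    """
    if mode == "sample":
        c = np.asarray(phantom(grid.centres), dtype=np.float64)
    elif mode == "lstsq":
        from scipy.optimize import lsq_linear
        if vg is None:
            ext = grid.n_radial * grid.delta + grid.params.a
            n = int(np.ceil(2 * ext / grid.delta)) + 1
            nz = grid.n_axial + 2
            vg = VoxelGrid(nx=n, ny=n, nz=nz, voxel_size=grid.delta)
        ax, ay, az = vg.axes()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        target = np.asarray(phantom(pts))
        cols = []
        for b in range(grid.n_blobs):
            e = np.zeros(grid.n_blobs)
            e[b] = 1.0
            cols.append(rasterize(BlobImage(grid, e), vg).ravel())
        G = np.column_stack(cols)
        res = lsq_linear(G, target, bounds=(0.0, np.inf), tol=1e-10)
        c = res.x
    else:
        raise ValueError("mode must be 'sample' or 'lstsq'")
    if not np.any(c > 0):
        raise ValueError("phantom does not overlap the blob grid "
                         "(all coefficients zero)")
    return BlobImage(grid=grid, c=c)


# ---------------------------------------------------------------------------
# Poisson data
# ---------------------------------------------------------------------------

def simulate_counts(c_true, srm: SparseSRM, lut: SymmetryLUT,
                    total_counts: float, seed) -> LORHistogram:
    """Poisson LOR histogram with E[sum y] = total_counts.

    lambda = forward(c_true) rescaled to the requested total; seed is
    mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("simulate_counts requires an explicit seed")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if isinstance(c_true, BlobImage):
        c_true = c_true.c
    lam = FoldedSystem(srm, lut).forward(c_true)
    total = lam.sum()
    if total <= 0:
        raise ValueError("expected sinogram is identically zero")
    lam *= total_counts / total
    rng = np.random.default_rng(seed)
    y = rng.poisson(lam).astype(np.uint32)
    return LORHistogram(y=y, meta={"seed": int(seed),
                                   "total_counts": float(total_counts),
                                   "realized_counts": int(y.sum())})
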