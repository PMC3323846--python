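"""Polar blob grid and generalized Kaiser-Bessel basis functions.

The radiotracer distribution f(r) is represented as a linear combination of
spherically symmetric, compactly supported basis functions ("blobs")

    f(r) ~= sum_i c_i * psi(|r - r_i|),

with centres r_i body-centred on a polar grid: radii (k+1/2)*delta, azimuths
(j+1/2)*2*pi/n_angular and axial planes spaced delta symmetrically about the
scanner mid-plane.  The half offsets put each centre at the centre of its
polar voxel and make the scanner's reflection symmetries act on the grid
without fixed points, so a commensurate grid folds exactly onto a wedge of
n_blobs / (4*n_modules) canonical blobs.

The blob is the generalized Kaiser-Bessel window of order m, radius a and
taper alpha,

    psi(r) = [sqrt(1-(r/a)^2)]^m * I_m(alpha*sqrt(1-(r/a)^2)) / I_m(alpha)

for r <= a and 0 beyond; the defaults m=2, a=1.994*delta, alpha=10.4 give a
continuous first derivative at the support boundary.  Its X-ray transform
(the line integral at perpendicular distance s, the "footprint" used by the
analytic projector) has the closed form

    F(s) = (a / I_m(alpha)) * sqrt(2*pi/alpha) * w^(m+1/2)
           * I_(m+1/2)(alpha*w),      w = sqrt(1-(s/a)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special


# ---------------------------------------------------------------------------
# Blob parameters and profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobParams:
    """Kaiser-Bessel parameters: order m, radius a (mm), taper alpha,
    grid spacing delta (mm).  ``a`` defaults to 1.994*delta."""

    delta: float = 0.5
    m: int = 2
    a: float = None
    alpha: float = 10.4

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.m < 0:
            raise ValueError("m must be a non-negative integer")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.a is None:
            object.__setattr__(self, "a", 1.994 * self.delta)
        if self.a <= 0:
            raise ValueError("a must be positive")


def kb_profile(r, params: BlobParams):
    """Blob value psi(r); zero for r > a (compact support), psi(0) = 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    rho2 = np.clip(1.0 - (r / params.a) ** 2, 0.0, None)
    w = np.sqrt(rho2)
    out = (w ** params.m) * special.iv(params.m, params.alpha * w)
    out = out / special.iv(params.m, params.alpha)
    out = np.where(r <= params.a, out, 0.0)
    return out if out.ndim else float(out)


def kb_footprint(s, params: BlobParams):
    """Line integral of the blob along a chord at perpendicular distance s
    (mm-weighted); even in s, zero for |s| >= a."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("distance must be non-negative (pass |s|)")
    m, a, alpha = params.m, params.a, params.alpha
    w = np.sqrt(np.clip(1.0 - (s / a) ** 2, 0.0, None))
    if alpha == 0.0:
        # taper-free limit: psi = w^m, integral = a*sqrt(pi)*w^(m+1)
        #                   * Gamma((m+2)/2-1/2... use direct beta form
        out = a * w ** (m + 1) * special.beta(0.5, m / 2.0 + 1.0)
        out = np.where(s < a, out, 0.0)
        return out if out.ndim else float(out)
    front = a / special.iv(m, alpha) * np.sqrt(2.0 * np.pi / alpha)
    out = front * w ** (m + 0.5) * special.iv(m + 0.5, alpha * w)
    out = np.where(s < a, out, 0.0)
    return out if out.ndim else float(out)


def kb_integral(params: BlobParams) -> float:
    """Total volume integral 4*pi*int_0^a r^2 psi(r) dr (closed form)."""
    m, a, alpha = params.m, params.a, params.alpha
    if alpha == 0.0:
        from scipy.integrate import quad
        val, _ = quad(lambda r: r * r * kb_profile(r, params), 0.0, a)
        return 4.0 * np.pi * val
    # 3-D integral of the generalized KB window
    return ((2.0 * np.pi) ** 1.5 * a ** 3 / special.iv(m, alpha)
            / alpha ** 1.5 * special.iv(m + 1.5, alpha))


# ---------------------------------------------------------------------------
# Polar grid
# ---------------------------------------------------------------------------

@dataclass
class PolarBlobGrid:
    """Body-centred polar placement grid for blob centres.

    Blob id ordering is axial-fastest: ``b = (k*n_angular + j)*n_axial + iz``
    for radial ring k, azimuthal slot j and axial plane iz.
    """

    n_radial: int
    n_angular: int
    n_axial: int
    params: BlobParams
    centres: np.ndarray = field(default=None, repr=False)  # (N, 3) mm

    def __post_init__(self):
        for name in ("n_radial", "n_angular", "n_axial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.centres is None:
            self.centres = self._place()

    @property
    def delta(self) -> float:
        return self.params.delta

    @property
    def n_blobs(self) -> int:
        return self.n_radial * self.n_angular * self.n_axial

    def blob_id(self, k, j, iz):
        return (np.asarray(k) * self.n_angular + j) * self.n_axial + iz

    def blob_tuple(self, b):
        b = np.asarray(b)
        iz = b % self.n_axial
        rest = b // self.n_axial
        j = rest % self.n_angular
        k = rest // self.n_angular
        return k, j, iz

    def _place(self) -> np.ndarray:
        b = np.arange(self.n_blobs)
        k, j, iz = self.blob_tuple(b)
        radius = (k + 0.5) * self.delta
        theta = (j + 0.5) * 2.0 * np.pi / self.n_angular
        z = (iz - (self.n_axial - 1) / 2.0) * self.delta
        return np.column_stack([radius * np.cos(theta),
                                radius * np.sin(theta), z])


def build_polar_grid(n_radial: int, n_angular: int, n_axial: int,
                     delta: float, params: BlobParams = None,
                     n_modules: int = None) -> PolarBlobGrid:
    """Construct the grid; if ``n_modules`` is given, reject an angular count
    that is incommensurate with the scanner's symmetry wedge."""
    if params is None:
        params = BlobParams(delta=delta)
    elif params.delta != delta:
        raise ValueError("params.delta disagrees with the delta argument")
    if n_modules is not None and n_angular % (2 * n_modules) != 0:
        raise ValueError(
            f"n_angular={n_angular} must be divisible by 2*n_modules="
            f"{2 * n_modules} for exact wedge folding")
    return PolarBlobGrid(n_radial=n_radial, n_angular=n_angular,
                         n_axial=n_axial, params=params)


# ---------------------------------------------------------------------------
# Voxel grid and rasterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic display/analysis raster; origin = centre of voxel (0,0,0)."""

    nx: int = 140
    ny: int = 140
    nz: int = 40
    voxel_size: float = 0.5
    origin: tuple = None

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1 or self.voxel_size <= 0:
            raise ValueError("voxel grid dimensions must be positive")
        if self.origin is None:
            object.__setattr__(self, "origin", (
                -(self.nx - 1) / 2.0 * self.voxel_size,
                -(self.ny - 1) / 2.0 * self.voxel_size,
                -(self.nz - 1) / 2.0 * self.voxel_size))

    @property
    def shape(self):
        return (self.nx, self.ny, self.nz)

    def axes(self):
        o = self.origin
        return (o[0] + np.arange(self.nx) * self.voxel_size,
                o[1] + np.arange(self.ny) * self.voxel_size,
                o[2] + np.arange(self.nz) * self.voxel_size)


@dataclass
class BlobImage:
    """Blob coefficient vector tied to its placement grid."""

    grid: PolarBlobGrid
    c: np.ndarray

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.c.shape != (self.grid.n_blobs,):
            raise ValueError("coefficient length must equal the blob count")


def rasterize(image: BlobImage, vg: VoxelGrid) -> np.ndarray:
    """Evaluate f(r) = sum_i c_i psi(|r - r_i|) at every voxel centre.

    Linear in the coefficients; each blob touches only the voxels within its
    compact support radius.
    """
    grid = image.grid
    a = grid.params.a
    h = vg.voxel_size
    ax, ay, az = vg.axes()
    vol = np.zeros(vg.shape, dtype=np.float64)

    nz_ids = np.nonzero(image.c)[0]
    for b in nz_ids:
        cx, cy, cz = grid.centres[b]
        i0 = max(0, int(np.ceil((cx - a - vg.origin[0]) / h)))
        i1 = min(vg.nx - 1, int(np.floor((cx + a - vg.origin[0]) / h)))
        j0 = max(0, int(np.ceil((cy - a - vg.origin[1]) / h)))
        j1 = min(vg.ny - 1, int(np.floor((cy + a - vg.origin[1]) / h)))
        k0 = max(0, int(np.ceil((cz - a - vg.origin[2]) / h)))
        k1 = min(vg.nz - 1, int(np.floor((cz + a - vg.origin[2]) / h)))
        if i0 > i1 or j0 > j1 or k0 > k1:
            continue
        dx = ax[i0:i1 + 1] - cx
        dy = ay[j0:j1 + 1] - cy
        dz = az[k0:k1 + 1] - cz
        r = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                    + dz[None, None, :] ** 2)
        vol[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] += image.c[b] * kb_profile(
            r, grid.params)
    return vol
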