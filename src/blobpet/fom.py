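"""Image-quality figures of merit on rasterized volumes.

Noise and contrast are measured over box ROIs (default 8 x 9 x 0.5 mm3):

    CV  = sigma_s / mu_s                       (coefficient of variation)
    CNR = (mu_s - mu_b) / sqrt((sigma_s^2 + sigma_b^2) / 2)

with the sample (n-1) standard deviation.  Whole-volume similarity uses the
Pearson correlation coefficient CC, computed with mean-centred sums in
double precision.  Spatial resolution is the FWHM of a trilinearly
interpolated line profile through a point source: the half maximum is taken
above the profile minimum (baseline subtraction, appropriate for point
sources sitting on a warm background) and the two half-max crossings are
located by linear interpolation on each flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .blobgrid import VoxelGrid


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned box ROI: centre and full dimensions in mm.  A voxel
    belongs to the ROI iff its centre is inside the box."""

    centre: tuple
    dims: tuple = (8.0, 9.0, 0.5)
    label: str = ""

    def __post_init__(self):
        if any(d <= 0 for d in self.dims):
            raise ValueError("ROI dimensions must be positive")

    def mask(self, vg: VoxelGrid) -> np.ndarray:
        ax, ay, az = vg.axes()
        mx = np.abs(ax - self.centre[0]) <= self.dims[0] / 2.0
        my = np.abs(ay - self.centre[1]) <= self.dims[1] / 2.0
        mz = np.abs(az - self.centre[2]) <= self.dims[2] / 2.0
        m = mx[:, None, None] & my[None, :, None] & mz[None, None, :]
        if m.sum() < 2:
            raise ValueError(
                f"ROI {self.label or self.centre} contains fewer than 2 "
                f"voxels at {vg.voxel_size} mm resolution")
        return m


def roi_stats(volume: np.ndarray, roi: ROISpec, vg: VoxelGrid):
    vals = volume[roi.mask(vg)]
    return float(vals.mean()), float(vals.std(ddof=1))


def cv(volume: np.ndarray, roi: ROISpec, vg: VoxelGrid) -> float:
    """Coefficient of variation sigma/mu over the ROI."""
    mu, sigma = roi_stats(volume, roi, vg)
    if mu == 0.0:
        raise ValueError("CV undefined for a zero-mean ROI")
    return sigma / mu


def cnr(volume: np.ndarray, roi_s: ROISpec, roi_b: ROISpec,
        vg: VoxelGrid) -> float:
    """Contrast-to-noise ratio between a signal and a background ROI."""
    mu_s, sig_s = roi_stats(volume, roi_s, vg)
    mu_b, sig_b = roi_stats(volume, roi_b, vg)
    denom = np.sqrt((sig_s ** 2 + sig_b ** 2) / 2.0)
    if denom == 0.0:
        raise ValueError("CNR undefined when both ROIs are constant")
    return (mu_s - mu_b) / denom


def cc(volume_a: np.ndarray, volume_b: np.ndarray) -> float:
    """Pearson correlation over all voxels; +1 = identical up to positive
    affine scaling, -1 = perfect anti-correlation."""
    a = np.asarray(volume_a, dtype=np.float64)
    b = np.asarray(volume_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("volumes must have equal shapes")
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na = np.sqrt(np.sum(a * a))
    nb = np.sqrt(np.sum(b * b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("CC undefined for a constant volume")
    return float(np.sum(a * b) / (na * nb))


@dataclass
class Profile:
    """Uniformly sampled line profile: positions (mm along the line) and
    values."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        d = np.diff(self.positions)
        if len(d) and (np.any(d <= 0)
                       or not np.allclose(d, d[0], rtol=1e-9, atol=1e-12)):
            raise ValueError("positions must be strictly increasing and "
                             "uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


def extract_profile(volume: np.ndarray, vg: VoxelGrid, p0, p1,
                    n: int = 200) -> Profile:
    """Trilinear interpolation at ``n`` uniform positions from p0 to p1."""
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    o = np.asarray(vg.origin)
    h = vg.voxel_size
    lims = (np.array(vg.shape) - 1) * h + o
    for p in (p0, p1):
        if np.any(p < o - 1e-9) or np.any(p > lims + 1e-9):
            raise ValueError("profile segment leaves the volume")
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    idx = (pts - o) / h
    vals = ndimage.map_coordinates(volume, idx.T, order=1, mode="nearest")
    pos = t * np.linalg.norm(p1 - p0)
    return Profile(positions=pos, values=vals)


def fwhm(profile: Profile, baseline_subtraction: bool = True) -> float:
    """Full width at half maximum of the (highest) peak, in mm.

    Baseline = profile minimum (subtracted by default); crossings of the
    half-maximum level are found by linear interpolation on the flanks
    adjacent to the peak.
    """
    v = profile.values
    x = profile.positions
    imax = int(np.argmax(v))
    if imax == 0 or imax == len(v) - 1:
        raise ValueError("profile peak lies on the boundary (monotone "
                         "profile?); cannot measure FWHM")
    base = float(v.min()) if baseline_subtraction else 0.0
    peak = float(v[imax])
    if peak <= base:
        raise ValueError("flat profile: no peak above baseline")
    half = base + (peak - base) / 2.0

    # left flank
    i = imax
    while i > 0 and v[i - 1] >= half:
        i -= 1
    if i == 0 and v[0] >= half:
        raise ValueError("left half-max crossing not inside the profile")
    xl = x[i - 1] + (half - v[i - 1]) / (v[i] - v[i - 1]) * (x[i] - x[i - 1])

    # right flank
    i = imax
    while i < len(v) - 1 and v[i + 1] >= half:
        i += 1
    if i == len(v) - 1 and v[-1] >= half:
        raise ValueError("right half-max crossing not inside the profile")
    xr = x[i] + (half - v[i]) / (v[i + 1] - v[i]) * (x[i + 1] - x[i])
    return float(xr - xl)
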