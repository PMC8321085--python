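"""Phantom image-quality figures of merit.

All three metrics are computed on the in-memory float rendering of the
phantom, at the 90-degree view where the z-direction quality is exposed:

* **FWHM** of a Gaussian fitted (with a background offset) to the z line
  profile through the 5.0 mm disk — a proxy for the disk's z definition; a
  lower value means a better-defined disk.
* **CNR** = (mu_disk - mu_BG) / sigma_BG, with mu_BG the mean of the two
  background ROI means and sigma_BG the mean of their sample standard
  deviations (n-1 denominator, matching the spreadsheet family of functions).
* **Smoothness** = 1 / STEYX of the profile restricted to a z window
  (default 16-24 mm, a region of high intensity variation), where STEYX is
  the standard error of predicted y in the simple linear regression of
  intensity on z: sqrt(SSE / (n - 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DomainError,
    FitError,
    GeometryError,
    InfiniteSmoothnessError,
    InsufficientDataError,
    UndefinedCNRError,
    UsageError,
)
from .volume_io import RenderedImage

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class LineProfile:
    """Intensity versus z (mm) through a disk center at the 90-degree view."""

    z_mm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z_mm.shape != self.intensity.shape or self.z_mm.ndim != 1:
            raise UsageError("z_mm and intensity must be matching 1D arrays")
        steps = np.diff(self.z_mm)
        if len(steps) and (steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6)):
            raise UsageError("z_mm must be strictly increasing with uniform step")


@dataclass
class ROISpec:
    """Rectangular ROI in pixel coordinates: center +/- half extents."""

    center: tuple[int, int]
    half_extent: tuple[int, int]
    role: str = "background"

    def slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        (r, c), (dr, dc) = self.center, self.half_extent
        if r - dr < 0 or c - dc < 0 or r + dr >= shape[0] or c + dc >= shape[1]:
            raise GeometryError(f"ROI {self.center}+/-{self.half_extent} exceeds image {shape}")
        return slice(r - dr, r + dr + 1), slice(c - dc, c + dc + 1)


@dataclass
class MetricsRecord:
    """One (kernel, sampling distance) cell of the study."""

    kernel: str
    d: float
    fwhm_90: float
    cnr: float
    smoothness: float
    mu_disk: float
    mu_bg: float
    sigma_bg: float
    t_interp: float = 0.0
    t_render: float = 0.0


def extract_profile(
    img: RenderedImage, disk_center_x: float, band_halfwidth: int = 2
) -> LineProfile:
    """Mean z profile over a band of columns centered on a disk's x position.

    The image must span (x, z).  Averaging ``2 * band_halfwidth + 1`` columns
    suppresses single-column noise; ``band_halfwidth = 0`` returns the single
    column at the disk center.
    """
    if tuple(img.axes) != ("x", "z"):
        raise GeometryError(f"profile extraction requires an (x, z) image, got axes {img.axes}")
    psx, psz = img.pixel_spacing
    ix = int(round((disk_center_x - img.origin[0]) / psx))
    nx, nz = img.pixels.shape
    if not (0 <= ix < nx):
        raise GeometryError(f"disk center x={disk_center_x} mm outside image")
    if ix - band_halfwidth < 0 or ix + band_halfwidth >= nx:
        raise GeometryError("column band exceeds image bounds")
    band = img.pixels[ix - band_halfwidth : ix + band_halfwidth + 1, :]
    z = img.origin[1] + np.arange(nz) * psz
    return LineProfile(z, band.mean(axis=0))


def _gaussian_offset(z, b, A, mu, sigma):
    return b + A * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2))


def fit_fwhm(profile: LineProfile, max_restarts: int = 5) -> float:
    """FWHM (mm) of a Gaussian-plus-offset least-squares fit to the profile.

    The model is ``y = b + A * exp(-(z - mu)^2 / (2 sigma^2))`` with
    ``A > 0`` and ``sigma > 0``; the returned width is
    ``2 * sqrt(2 ln 2) * sigma``.  Initialization is moment-based (mu from
    the argmax, sigma from the spread of points above half range, b from the
    profile minimum); on non-convergence the fit is restarted from jittered
    initial values a bounded number of times.
    """
    z, y = profile.z_mm, profile.intensity
    if z.size < 5:
        raise InsufficientDataError(f"need >= 5 points to fit, got {z.size}")
    if np.ptp(y) == 0:
        raise FitError("profile is constant; no peak to fit")

    b0 = float(y.min())
    A0 = float(y.max() - y.min())
    mu0 = float(z[np.argmax(y)])
    above = z[y >= b0 + A0 / 2.0]
    sigma0 = max(float(np.ptp(above)) / FWHM_PER_SIGMA, float(z[1] - z[0]))

    span = float(z[-1] - z[0])
    lower = (-np.inf, 0.0, z[0] - span, 1e-9)
    upper = (np.inf, np.inf, z[-1] + span, 10.0 * span)
    rng = np.random.default_rng(0)
    last_err = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = (b0, A0, mu0, sigma0)
        else:
            jitter = rng.uniform(0.5, 1.5, size=3)
            p0 = (b0, A0 * jitter[0], mu0, min(sigma0 * jitter[1] * 2**attempt, 5.0 * span))
        try:
            popt, _ = curve_fit(
                _gaussian_offset, z, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
            return FWHM_PER_SIGMA * float(popt[3])
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    raise FitError(
        "Gaussian fit did not converge",
        diagnostics={"p0": (b0, A0, mu0, sigma0), "n": int(z.size), "error": str(last_err)},
    )


def cnr(img: RenderedImage, disk: ROISpec, bg1: ROISpec, bg2: ROISpec) -> float:
    """Contrast-to-noise ratio from one disk ROI and two background ROIs.

    ``(mean(disk) - mean of the two background ROI means) / mean of the two
    background ROI sample standard deviations``.
    """
    shape = img.pixels.shape
    regions = {}
    for roi in (disk, bg1, bg2):
        rs, cs = roi.slices(shape)
        regions[id(roi)] = img.pixels[rs, cs]
    mu_disk = float(regions[id(disk)].mean())
    mu_bg = float((regions[id(bg1)].mean() + regions[id(bg2)].mean()) / 2.0)
    sigma_bg = float(
        (regions[id(bg1)].std(ddof=1) + regions[id(bg2)].std(ddof=1)) / 2.0
    )
    if sigma_bg == 0:
        raise UndefinedCNRError("background standard deviation is zero")
    return (mu_disk - mu_bg) / sigma_bg


def steyx(x: np.ndarray, y: np.ndarray) -> float:
    """Standard error of predicted y in simple linear regression of y on x.

    ``sqrt(SSE / (n - 2))`` with SSE the residual sum of squares about the
    ordinary least-squares line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"STEYX needs >= 3 points, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise DomainError("x values are all identical")
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sse = float(resid @ resid)
    return math.sqrt(max(sse, 0.0) / (n - 2))


def smoothness(profile: LineProfile, z_range: tuple[float, float] = (16.0, 24.0)) -> float:
    """Reciprocal STEYX of the profile restricted to ``z_range`` (mm).

    A perfectly collinear profile has zero residual variability; that is
    reported as :class:`InfiniteSmoothnessError` rather than a division
    crash.
    """
    lo, hi = z_range
    mask = (profile.z_mm >= lo) & (profile.z_mm <= hi)
    z, y = profile.z_mm[mask], profile.intensity[mask]
    if z.size < 3:
        raise InsufficientDataError(
            f"only {z.size} profile points inside z range {z_range}; need >= 3"
        )
    s = steyx(z, y)
    scale = max(float(np.abs(y).max()), 1.0)
    if s <= 1e-14 * scale:
        raise InfiniteSmoothnessError("profile is collinear inside the z window")
    return 1.0 / s
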