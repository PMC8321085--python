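"""Synthetic disk phantom emulating a DBT reconstruction.

The physical phantom being emulated is an acrylic slab (mimicking breast
tissue) with one column of aluminum disks of diameters 5.0, 3.0, 1.0, 0.5,
2.0, and 4.0 mm, each 1.0 mm thick.  Two features of real reconstructed DBT
data are reproduced because the downstream image-quality metrics depend on
them:

* anisotropic out-of-plane blur — high-intensity structures smear along z,
  so a 1 mm disk measures far wider than 1 mm in a 90° view.  The limited-
  angle reconstruction physics is out of scope; a 1-D Gaussian convolution
  along z reproduces the one property the metrics need.
* additive i.i.d. Gaussian noise.

Generation is deterministic under (spec, seed): one named RNG per phantom,
no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError, GeometryError
from .volume_io import Volume

#: Disk diameters (mm) of the emulated phantom column, in physical order.
DEFAULT_DISK_DIAMETERS = (5.0, 3.0, 1.0, 0.5, 2.0, 4.0)

#: Voxel spacing (mm) of the DBT reconstructions the phantom mimics.
DEFAULT_SPACING = (0.085, 0.085, 1.0)


def default_disk_centers(
    volume_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    diameters=DEFAULT_DISK_DIAMETERS,
    z_center: float = 26.0,
    first_gap: float = 2.0,
    gap: float = 0.2,
    left_margin: float = 1.8,
) -> tuple[tuple[float, float, float], ...]:
    """Lay the disk column out along x at a common (y, z) center.

    The first (largest-interest) disk is followed by a wider gap so that
    background ROIs flanking it at ±1.5 radii stay clear of its neighbor.
    """
    cy = (volume_shape[1] - 1) * spacing[1] / 2.0
    centers = []
    x = left_margin
    for i, d in enumerate(diameters):
        centers.append((x + d / 2.0, cy, z_center))
        x += d + (first_gap if i == 0 else gap)
    return tuple(centers)


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom realization.

    Intensities are in arbitrary reconstruction units; the defaults give the
    blurred disk cloud a peak roughly 100 units above background (the 1 mm
    thick disk's intensity is diluted ~10x by the default 4 mm z-spread).
    The default ``noise_sigma`` of 5.0 — 5% of that blurred-peak contrast —
    is calibrated so the rendered disk profile shows conspicuous variability
    before any low-pass interpolation, the premise of the blur-factor and
    window studies, while staying far below the aluminum-vs-acrylic contrast.
    """

    volume_shape: tuple[int, int, int] = (256, 160, 40)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    background_intensity: float = 100.0
    disk_intensity: float = 1100.0
    disk_diameters: tuple[float, ...] = DEFAULT_DISK_DIAMETERS
    disk_thickness: float = 1.0
    disk_centers: tuple[tuple[float, float, float], ...] | None = None
    z_spread_sigma: float = 4.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.disk_intensity <= self.background_intensity:
            raise DomainError("disk_intensity must exceed background_intensity")
        if self.z_spread_sigma < 0 or self.noise_sigma < 0:
            raise DomainError("sigma values must be >= 0")
        if len(self.disk_diameters) == 0:
            raise GeometryError("at least one disk is required")
        if self.disk_centers is None:
            self.disk_centers = default_disk_centers(
                self.volume_shape, self.spacing, self.disk_diameters
            )
        if len(self.disk_centers) != len(self.disk_diameters):
            raise GeometryError("disk_centers and disk_diameters length mismatch")
        self._check_bounds()

    def _check_bounds(self):
        nx, ny, nz = self.volume_shape
        sx, sy, sz = self.spacing
        hi = ((nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz)
        for d, (cx, cy, cz) in zip(self.disk_diameters, self.disk_centers):
            r = d / 2.0
            ht = self.disk_thickness / 2.0
            for lo_edge, hi_edge, axis_hi, label in (
                (cx - r, cx + r, hi[0], "x"),
                (cy - r, cy + r, hi[1], "y"),
                (cz - ht, cz + ht, hi[2], "z"),
            ):
                if lo_edge < 0 or hi_edge > axis_hi:
                    raise GeometryError(
                        f"disk d={d} mm at ({cx}, {cy}, {cz}) exceeds volume bounds on {label}"
                    )

    @property
    def contrast(self) -> float:
        return self.disk_intensity - self.background_intensity

    def expected_blurred_peak(self) -> float:
        """Peak intensity of a disk cloud after z-spread (noise-free).

        The 1 mm box profile convolved with a Gaussian of width
        ``z_spread_sigma`` peaks at ``erf(t/2 / (sigma*sqrt(2)))`` of the
        original disk contrast (t = disk thickness).
        """
        if self.z_spread_sigma == 0:
            return self.disk_intensity
        frac = math.erf(self.disk_thickness / 2.0 / (self.z_spread_sigma * math.sqrt(2.0)))
        return self.background_intensity + self.contrast * frac


def apply_z_spread(vol: Volume, sigma_z: float) -> Volume:
    """Convolve along z with a unit-sum discrete Gaussian truncated at 4 sigma.

    ``sigma_z`` is in mm; the discrete kernel is sampled at the volume's z
    spacing.  Reflective boundaries keep total intensity conserved.
    ``sigma_z == 0`` is the identity.
    """
    if sigma_z < 0:
        raise DomainError(f"sigma_z must be >= 0, got {sigma_z}")
    if sigma_z == 0:
        return vol.copy_with(vol.data.copy())
    sz = vol.spacing[2]
    radius = int(math.ceil(4.0 * sigma_z / sz))
    offsets = np.arange(-radius, radius + 1) * sz
    kernel = np.exp(-0.5 * (offsets / sigma_z) ** 2)
    kernel /= kernel.sum()
    data = ndimage.convolve1d(vol.data.astype(float), kernel, axis=2, mode="reflect")
    return vol.copy_with(data)


def gaussian_z_kernel(sigma_z: float, sz: float) -> np.ndarray:
    """The unit-sum discrete z-spread kernel used by :func:`apply_z_spread`."""
    if sigma_z <= 0:
        raise DomainError("sigma_z must be > 0 for an explicit kernel")
    radius = int(math.ceil(4.0 * sigma_z / sz))
    offsets = np.arange(-radius, radius + 1) * sz
    kernel = np.exp(-0.5 * (offsets / sigma_z) ** 2)
    return kernel / kernel.sum()


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Voxelize the disk column, apply z-spread, then add Gaussian noise.

    Voxelization is by voxel-center membership: a voxel gets the disk
    intensity iff its center lies inside the disk cylinder (axis along z,
    diameter in xy, thickness in z).  No antialiasing.
    """
    nx, ny, nz = spec.volume_shape
    sx, sy, sz = spec.spacing
    data = np.full((nx, ny, nz), float(spec.background_intensity))

    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    for d, (cx, cy, cz) in zip(spec.disk_diameters, spec.disk_centers):
        in_xy = ((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2) <= (d / 2.0) ** 2
        in_z = np.abs(z - cz) < spec.disk_thickness / 2.0
        mask = in_xy[:, :, None] & in_z[None, None, :]
        data[mask] = float(spec.disk_intensity)

    vol = Volume(data, spec.spacing)
    vol = apply_z_spread(vol, spec.z_spread_sigma)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol.data += rng.normal(0.0, spec.noise_sigma, size=vol.data.shape)
    return vol
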