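"""Volume, image, and results-table I/O.

All in-memory volumes use axis order ``(x, y, z)`` with z the between-slice
axis; readers permute file layouts into this order so the rest of the
pipeline never has to care about on-disk conventions.  Supported volume
formats: MetaImage (.mha/.mhd) via SimpleITK, NIfTI (.nii/.nii.gz) via
nibabel, and raw binary with a JSON sidecar.  Rendered images are written as
16-bit TIFF/PNG after linear scaling, with the scale recorded in a JSON
sidecar; metrics are always computed on the in-memory float image, never the
quantized file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DimensionalityError, FormatError, UsageError

log = logging.getLogger(__name__)

_RAW_SIDECAR_SUFFIX = ".json"


@dataclass
class Volume:
    """A 3D scalar grid with per-axis spacing and origin, both in mm.

    ``data`` is indexed ``(i, j, k)`` for ``(x, y, z)``; the world coordinate
    of voxel ``(i, j, k)`` is ``origin + (i*sx, j*sy, k*sz)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume data contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent(self, axis: int) -> float:
        """Distance in mm from the first to the last voxel center along axis."""
        return (self.data.shape[axis] - 1) * self.spacing[axis]

    def copy_with(self, data: np.ndarray, spacing=None) -> "Volume":
        return Volume(data, spacing or self.spacing, self.origin)


@dataclass
class RenderedImage:
    """A composited orthographic projection.

    ``pixels``/``alpha`` are indexed by the two spanned world axes in order,
    e.g. ``axes == ("x", "z")`` means ``pixels[i, k]`` sits at world
    ``(i * pixel_spacing[0], k * pixel_spacing[1])`` relative to ``origin``.
    """

    pixels: np.ndarray
    alpha: np.ndarray
    axes: tuple[str, str]
    pixel_spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.pixels.shape != self.alpha.shape:
            raise FormatError("pixels and alpha must have identical shapes")
        for name, arr in (("pixels", self.pixels), ("alpha", self.alpha)):
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise FormatError(f"{name} values outside [0, 1]")


def _permute_to_xyz(arr: np.ndarray, order: str) -> np.ndarray:
    """Permute a file-layout array into (x, y, z); log the permutation."""
    perms = {"xyz": (0, 1, 2), "zyx": (2, 1, 0)}
    perm = perms[order]
    if perm != (0, 1, 2):
        log.info("permuting axes %s -> (x, y, z)", perm)
        arr = np.transpose(arr, perm)
    return arr


def read_volume(path, format: str | None = None) -> Volume:
    """Read a volume from MetaImage, NIfTI, or raw + JSON sidecar.

    ``format`` is one of ``{"metaimage", "nifti", "raw"}``; when omitted it
    is inferred from the file suffix.  Spacing is taken verbatim from the
    header; a raw file requires a sidecar ``<path>.json`` holding ``shape``,
    ``dtype``, ``spacing``, and optionally ``origin``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        suffixes = "".join(path.suffixes)
        if suffixes.endswith((".mha", ".mhd")):
            format = "metaimage"
        elif suffixes.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif suffixes.endswith(".raw"):
            format = "raw"
        else:
            raise FormatError(f"cannot infer format from suffix of {path.name}")

    if format == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise DimensionalityError(f"expected 3D image, got {img.GetDimension()}D")
        # SimpleITK arrays come back (z, y, x)
        data = _permute_to_xyz(sitk.GetArrayFromImage(img), "zyx")
        return Volume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))

    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise DimensionalityError(f"expected 3D image, got {data.ndim}D")
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise FormatError(f"invalid spacing in NIfTI header: {zooms}")
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume(_permute_to_xyz(data, "xyz"), zooms, origin)

    if format == "raw":
        sidecar = path.with_suffix(path.suffix + _RAW_SIDECAR_SUFFIX)
        if not sidecar.exists():
            raise FormatError(f"raw volume {path.name} requires sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        for key in ("shape", "dtype", "spacing"):
            if key not in meta:
                raise FormatError(f"raw sidecar missing required key '{key}'")
        shape = tuple(int(n) for n in meta["shape"])
        if len(shape) != 3:
            raise DimensionalityError(f"raw sidecar shape must be 3D, got {shape}")
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        if data.size != int(np.prod(shape)):
            raise FormatError(
                f"raw file holds {data.size} values, sidecar shape implies {int(np.prod(shape))}"
            )
        data = data.reshape(shape)  # stored C-order in (x, y, z) index order
        return Volume(data, tuple(meta["spacing"]), tuple(meta.get("origin", (0.0, 0.0, 0.0))))

    raise FormatError(f"unknown volume format '{format}'")


def write_volume(vol: Volume, path) -> None:
    """Write a volume; format chosen from suffix (mirror of :func:`read_volume`)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(vol.data, (2, 1, 0)))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        # NIfTI-2: float64 header fields, so spacing/origin round-trip exactly
        nib.save(nib.Nifti2Image(vol.data, affine), str(path))
    elif suffixes.endswith(".raw"):
        vol.data.tofile(path)
        meta = {
            "shape": list(vol.data.shape),
            "dtype": vol.data.dtype.name,
            "spacing": list(vol.spacing),
            "origin": list(vol.origin),
        }
        path.with_suffix(path.suffix + _RAW_SIDECAR_SUFFIX).write_text(json.dumps(meta, indent=2))
    else:
        raise FormatError(f"cannot infer format from suffix of {path.name}")


def write_image(img: RenderedImage, path, bits: int = 16) -> None:
    """Write a rendered image as 16-bit TIFF/PNG plus a JSON scale sidecar.

    Pixels in [0, 1] are scaled linearly to the integer range; the sidecar
    records the scale so the float image can be recovered to quantization
    precision.  Quantitative metrics must use the in-memory float image.
    """
    path = Path(path)
    scale = float(2**bits - 1)
    quantized = np.round(np.clip(img.pixels, 0.0, 1.0) * scale).astype(np.uint16)
    # rows of the written raster = second spanned axis, for conventional display
    raster = quantized.T
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), raster)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(raster).save(str(path))
    else:
        raise FormatError(f"unsupported image suffix {path.suffix}")
    sidecar = {
        "scale": scale,
        "axes": list(img.axes),
        "pixel_spacing": list(img.pixel_spacing),
        "origin": list(img.origin),
    }
    path.with_suffix(path.suffix + _RAW_SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=2))


def write_results_csv(records: Sequence, path) -> None:
    """Write metric records to RFC-4180 CSV, one header row + one row per record.

    Records must be non-empty and homogeneous (identical field sets).  Floats
    are written with enough digits that a re-parse reproduces values to at
    least 6 significant digits.
    """
    import pandas as pd
    from dataclasses import asdict, is_dataclass

    if not records:
        raise UsageError("cannot write an empty record list")
    dicts = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
    fields = set(dicts[0])
    for d in dicts[1:]:
        if set(d) != fields:
            raise UsageError("records have mixed field sets")
    pd.DataFrame(dicts).to_csv(path, index=False, float_format="%.10g", lineterminator="\r\n")


def read_results_csv(path):
    """Parse a results CSV back into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path)
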