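"""Pixel calibration and working-range rules for calibrated micrographs.

A CCD camera with an ``n × n`` pixel sensor imaging a field of view of
``F`` nm resolves ``F / n`` nm per pixel.  Three rules of thumb define
the size working range of a magnification in quantitative TEM particle
sizing:

* the limit of detection (LOD) is one pixel edge — below that nothing
  can be resolved by image analysis regardless of microscope optics;
* particles are quantified only if their minimal Feret diameter spans
  at least 10 pixels (lower limit of quantification, LLOQ), because
  digitisation bias dominates for smaller objects;
* particles larger than one tenth of the field of view are rejected
  (upper limit of quantification, ULOQ) as too likely to be truncated
  or under-sampled.

The ratio ULOQ/LLOQ = n/100 is independent of magnification — about 40
for a 4k camera — so a single magnification covers a 40-fold size span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class QuantificationLimits:
    """Working range of one magnification, all lengths in nm."""

    lod_nm: float
    lloq_nm: float
    uloq_nm: float
    fov_nm: float

    def __post_init__(self):
        if not (0 < self.lod_nm < self.lloq_nm < self.uloq_nm):
            raise ValueError("limits must satisfy 0 < LOD < LLOQ < ULOQ")

    @property
    def working_range_factor(self) -> float:
        return self.uloq_nm / self.lloq_nm

    def rounded(self) -> dict:
        """Limits rounded to report precision (LOD 2 decimals, LLOQ/ULOQ 1)."""
        return {
            "lod_nm": round(self.lod_nm, 2),
            "lloq_nm": round(self.lloq_nm, 1),
            "uloq_nm": round(self.uloq_nm, 1),
        }


@dataclass
class Micrograph:
    """A calibrated 2-D intensity grid with acquisition identifiers."""

    data: np.ndarray
    pixel_size_nm: float
    material: str | None = None
    day: int | None = None
    replicate: int | None = None
    image_index: int | None = None
    magnification: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("micrograph data must be a non-empty 2-D grid")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_pixels(self) -> int:
        return max(self.data.shape)

    @property
    def fov_nm(self) -> float:
        return self.n_pixels * self.pixel_size_nm

    @property
    def image_id(self) -> str:
        parts = [
            str(p)
            for p in (self.material, self.day, self.replicate, self.image_index)
            if p is not None
        ]
        return "/".join(parts) if parts else "image"

    def limits(self) -> QuantificationLimits:
        return quantification_limits(self.fov_nm, self.n_pixels)


def pixel_size(fov_nm: float, n_pixels: int) -> float:
    """Pixel edge length in nm for a field of view imaged on n pixels."""
    if fov_nm <= 0 or n_pixels <= 0:
        raise ValueError("fov_nm and n_pixels must be positive")
    return fov_nm / n_pixels


def quantification_limits(fov_nm: float, n_pixels: int) -> QuantificationLimits:
    """LOD (1 px), LLOQ (10 px) and ULOQ (FOV/10) for one magnification."""
    px = pixel_size(fov_nm, n_pixels)
    return QuantificationLimits(
        lod_nm=px, lloq_nm=10.0 * px, uloq_nm=fov_nm / 10.0, fov_nm=fov_nm
    )


def working_range_factor(n_pixels: int) -> float:
    """ULOQ/LLOQ ratio, n_pixels/100, independent of the field of view."""
    if n_pixels < 100:
        raise ValueError("camera must have at least 100 pixels per edge")
    return n_pixels / 100.0


def load_micrograph(
    path: str | Path,
    *,
    pixel_size_nm: float | None = None,
    fov_nm: float | None = None,
    **identifiers,
) -> Micrograph:
    """Read a TIFF/PNG micrograph; calibrate by pixel size *or* FOV."""
    if (pixel_size_nm is None) == (fov_nm is None):
        raise ValueError("give exactly one of pixel_size_nm or fov_nm")
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    if data.ndim == 3:  # collapse any color axis
        data = data.mean(axis=-1)
    if pixel_size_nm is None:
        pixel_size_nm = fov_nm / max(data.shape)
    return Micrograph(data=data, pixel_size_nm=pixel_size_nm, **identifiers)


def save_micrograph(mg: Micrograph, path: str | Path) -> None:
    """Write a micrograph as 16-bit grayscale TIFF (pixel size in tags)."""
    import tifffile

    data = mg.data
    if data.dtype != np.uint16:
        lo, hi = float(data.min()), float(data.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        data = ((data - lo) * scale).astype(np.uint16)
    tifffile.imwrite(
        path, data, metadata={"pixel_size_nm": mg.pixel_size_nm}
    )
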