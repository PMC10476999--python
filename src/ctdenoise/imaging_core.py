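"""Image data model, value-domain conversions and raster/array I/O.

The package works on 2-D grayscale CT-like images.  A :class:`CTImage`
carries its pixel grid together with a *value-domain* tag so that
operations can check they are applied on the right scale:

``HU``
    Hounsfield units (water = 0, air = -1000).
``NORMALIZED``
    z-scored pixels, ``(HU - mean) / std``; this is the domain the
    denoiser trains in.
``ATTENUATION``
    linear attenuation coefficient in mm^-1, the physical quantity the
    ray transform integrates.
``COUNTS``
    photon counts (only meaningful for sinograms, kept here for
    completeness of the enum).

All internal computation is double precision; the training harness may
down-cast at its own boundary.  Coordinates are row-major, 0-based,
``(row, col)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Domain",
    "CTImage",
    "NormalizationStats",
    "MIN_SIZE",
    "normalize",
    "denormalize",
    "apply_display_window",
    "read_image",
    "write_image",
]

#: Minimum height/width: anything smaller cannot host the default patch
#: grid or an SSIM window.
MIN_SIZE = 8

#: Stored value in 16-bit rasters is HU + this offset, clipped to uint16.
RASTER_HU_OFFSET = 1024


class Domain(enum.Enum):
    """Value domain of a :class:`CTImage` pixel grid."""

    HU = "HU"
    NORMALIZED = "NORMALIZED"
    ATTENUATION = "ATTENUATION"
    COUNTS = "COUNTS"


@dataclass(frozen=True)
class CTImage:
    """A 2-D real-valued image with a value-domain tag.

    Parameters
    ----------
    pixels
        2-D float array, all values finite, at least ``MIN_SIZE`` on
        each side.
    domain
        value domain of ``pixels``.
    pixel_spacing
        isotropic pixel size in mm (metadata; used by the simulator to
        give line integrals physical units).
    """

    pixels: np.ndarray
    domain: Domain = Domain.HU
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError(f"CTImage requires a 2-D array, got shape {px.shape}")
        if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
            raise ValueError(
                f"CTImage must be at least {MIN_SIZE}x{MIN_SIZE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("CTImage pixels must be finite (no NaN/Inf)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, domain: Domain | None = None) -> "CTImage":
        """Return a copy with new pixels (and optionally a new domain)."""
        return CTImage(
            pixels=pixels,
            domain=self.domain if domain is None else domain,
            pixel_spacing=self.pixel_spacing,
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Affine normalization parameters (dataset-level pixel mean/std)."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.std):
            raise ValueError("normalization stats must be finite")
        if self.std <= 0:
            raise ValueError(f"std must be positive, got {self.std}")

    @classmethod
    def from_images(cls, images: "list[CTImage]") -> "NormalizationStats":
        """Dataset-level stats pooled over all pixels of ``images``."""
        if not images:
            raise ValueError("need at least one image to compute stats")
        stacked = np.concatenate([im.pixels.ravel() for im in images])
        std = float(stacked.std())
        if std == 0.0:
            raise ValueError("cannot normalize a dataset with zero pixel variance")
        return cls(mean=float(stacked.mean()), std=std)

    @classmethod
    def from_image(cls, image: CTImage) -> "NormalizationStats":
        """Per-image stats (alternative mode)."""
        return cls.from_images([image])


def normalize(image: CTImage, stats: NormalizationStats) -> CTImage:
    """Map an HU image to the normalized training domain.

    ``out = (pixels - mean) / std``; exact inverse via :func:`denormalize`.
    """
    if image.domain is not Domain.HU:
        raise ValueError(f"normalize expects an HU image, got {image.domain}")
    return image.with_pixels(
        (image.pixels - stats.mean) / stats.std, domain=Domain.NORMALIZED
    )


def denormalize(image: CTImage, stats: NormalizationStats) -> CTImage:
    """Exact affine inverse of :func:`normalize`."""
    if image.domain is not Domain.NORMALIZED:
        raise ValueError(f"denormalize expects a NORMALIZED image, got {image.domain}")
    return image.with_pixels(
        image.pixels * stats.std + stats.mean, domain=Domain.HU
    )


def apply_display_window(image: CTImage, low: float, high: float) -> CTImage:
    """Linear HU -> [0, 1] display mapping over ``[low, high]``, clipped.

    Only used for report figures; the abdominal window used throughout
    the figures is ``[-160, 240]`` HU.  The window is stored as
    ``(low, high)`` rather than center/width to avoid ambiguity.
    """
    if image.domain is not Domain.HU:
        raise ValueError("display windowing operates on HU images")
    if not high > low:
        raise ValueError(f"window must have high > low, got [{low}, {high}]")
    mapped = np.clip((image.pixels - low) / (high - low), 0.0, 1.0)
    return image.with_pixels(mapped, domain=Domain.NORMALIZED)


# ---------------------------------------------------------------------------
# I/O
#
# Reference lossless format: NumPy ``.npy`` (self-describing shape+dtype
# header).  16-bit TIFF/PNG store HU + 1024 clipped to [0, 65535]
# (documented quantization).  DICOM is read-only convenience.
# ---------------------------------------------------------------------------


def write_image(image: CTImage, path, format: str | None = None) -> None:
    """Write an image; format inferred from extension unless given.

    Supported: ``npy`` (lossless), ``tiff``/``png`` (16-bit, HU+1024
    integer quantization; HU domain required).
    """
    fmt = _resolve_format(path, format)
    if fmt == "npy":
        np.save(str(path), image.pixels)
        return
    if fmt in ("tiff", "png"):
        if image.domain is not Domain.HU:
            raise ValueError("16-bit raster output is defined for HU images only")
        stored = np.clip(np.rint(image.pixels + RASTER_HU_OFFSET), 0, 65535)
        arr = stored.astype(np.uint16)
        if fmt == "tiff":
            import tifffile

            tifffile.imwrite(str(path), arr)
        else:
            import imageio.v3 as iio

            iio.imwrite(str(path), arr)
        return
    raise ValueError(f"unsupported output format {fmt!r}")


def read_image(path, format: str | None = None, pixel_spacing: float = 1.0) -> CTImage:
    """Read an image written by :func:`write_image` (or a DICOM file).

    Raster formats are mapped back to HU via the HU+1024 convention;
    DICOM applies RescaleSlope/Intercept.  Errors carry the path.
    """
    fmt = _resolve_format(path, format)
    try:
        if fmt == "npy":
            px = np.load(str(path))
            domain = Domain.HU
        elif fmt == "tiff":
            import tifffile

            px = tifffile.imread(str(path)).astype(np.float64) - RASTER_HU_OFFSET
            domain = Domain.HU
        elif fmt == "png":
            import imageio.v3 as iio

            px = iio.imread(str(path)).astype(np.float64) - RASTER_HU_OFFSET
            domain = Domain.HU
        elif fmt == "dicom":
            import pydicom

            ds = pydicom.dcmread(str(path))
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            px = ds.pixel_array.astype(np.float64) * slope + intercept
            spacing = getattr(ds, "PixelSpacing", None)
            if spacing is not None:
                pixel_spacing = float(spacing[0])
            domain = Domain.HU
        else:
            raise ValueError(f"unsupported input format {fmt!r}")
        return CTImage(pixels=px, domain=domain, pixel_spacing=pixel_spacing)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path!r}: {exc}") from exc


def _resolve_format(path, format: str | None) -> str:
    if format is not None:
        return format.lower().lstrip(".")
    suffix = str(path).rsplit(".", 1)[-1].lower()
    aliases = {"tif": "tiff", "dcm": "dicom"}
    return aliases.get(suffix, suffix)
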