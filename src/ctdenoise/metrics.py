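"""PSNR and SSIM image-quality metrics, global and ROI-restricted.

PSNR = 10 log10(data_range^2 / MSE) in dB, with a +inf sentinel for
identical images.  SSIM is the standard windowed luminance/contrast/
structure index (Gaussian window sigma=1.5, size 11, K1=0.01, K2=0.03).
``data_range`` defaults to max - min of the reference image; fixed CT
ranges can be passed explicitly, and metrics can be computed in HU or
normalized units — both conventions appear in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .imaging_core import CTImage

__all__ = ["Rectangle", "MetricResult", "psnr", "ssim", "roi_metrics"]

SSIM_WIN_SIZE = 11
SSIM_SIGMA = 1.5


@dataclass(frozen=True)
class Rectangle:
    """0-based half-open ROI: rows [row0, row0+height), cols alike."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must have positive height and width")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass(frozen=True)
class MetricResult:
    psnr: float
    ssim: float
    roi: Rectangle | None = None


def _arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa = x.pixels if isinstance(x, CTImage) else np.asarray(x, dtype=np.float64)
    ya = y.pixels if isinstance(y, CTImage) else np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError(f"image shapes differ: {xa.shape} vs {ya.shape}")
    return xa.astype(np.float64), ya.astype(np.float64)


def _default_range(ref: np.ndarray) -> float:
    rng = float(ref.max() - ref.min())
    if rng <= 0:
        raise ValueError(
            "reference image is constant; pass data_range explicitly"
        )
    return rng


def psnr(x, y, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB (y is the reference).

    Returns ``np.inf`` when the images are identical (MSE = 0).
    """
    xa, ya = _arrays(x, y)
    rng = _default_range(ya) if data_range is None else float(data_range)
    if rng <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((xa - ya) ** 2))
    if mse == 0.0:
        return np.inf
    return 10.0 * np.log10(rng**2 / mse)


def ssim(x, y, data_range: float | None = None) -> float:
    """Mean structural similarity index over the image.

    Gaussian window (sigma 1.5, 11x11), C1 = (0.01 * range)^2,
    C2 = (0.03 * range)^2, population (not sample) covariance —
    the constants and window of the original SSIM formulation.
    """
    xa, ya = _arrays(x, y)
    if min(xa.shape) < SSIM_WIN_SIZE:
        raise ValueError(
            f"image min dimension {min(xa.shape)} is below the "
            f"{SSIM_WIN_SIZE}-pixel SSIM window"
        )
    rng = _default_range(ya) if data_range is None else float(data_range)
    if rng <= 0:
        raise ValueError("data_range must be positive")
    return float(
        _sk_ssim(
            xa,
            ya,
            data_range=rng,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            win_size=SSIM_WIN_SIZE,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def roi_metrics(x, y, rois: list[Rectangle], data_range: float | None = None) -> list[MetricResult]:
    """PSNR/SSIM on cropped sub-images, one result per ROI, input order."""
    xa, ya = _arrays(x, y)
    h, w = xa.shape
    results = []
    for i, roi in enumerate(rois):
        if roi.row0 + roi.height > h or roi.col0 + roi.width > w:
            raise ValueError(f"ROI {i} {roi} exceeds image bounds {xa.shape}")
        if min(roi.height, roi.width) < SSIM_WIN_SIZE:
            raise ValueError(f"ROI {i} smaller than the SSIM window")
        sl = (slice(roi.row0, roi.row0 + roi.height), slice(roi.col0, roi.col0 + roi.width))
        xs, ys = xa[sl], ya[sl]
        rng = _default_range(ys) if data_range is None else data_range
        results.append(MetricResult(psnr=psnr(xs, ys, rng), ssim=ssim(xs, ys, rng), roi=roi))
    return results
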