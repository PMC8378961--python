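"""Full-reference image-quality metrics under pinned evaluation conventions.

Scoring follows the common super-resolution benchmark protocol: grayscale
(luma) channel, 8-bit quantization, a border shave equal to the scale factor,
PSNR as 10*log10(L^2/MSE), SSIM with the original 11x11 Gaussian window
(sigma 1.5, K1=0.01, K2=0.03).  Entropy and average gradient use the standard
definitions (256-bin Shannon entropy; mean RMS of forward differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .data import ImageGray
from .errors import ParameterError, ShapeError

__all__ = [
    "EvalConvention",
    "MetricsReport",
    "psnr",
    "ssim",
    "shannon_entropy",
    "average_gradient",
    "evaluate_pair",
]


@dataclass(frozen=True)
class EvalConvention:
    """How image pairs are prepared and scored."""

    data_range: int = 255
    border_shave: int = 2
    histogram_bins: int = 256

    def __post_init__(self):
        if self.border_shave < 0:
            raise ParameterError("border_shave must be >= 0")
        if self.data_range <= 0:
            raise ParameterError("data_range must be positive")


@dataclass(frozen=True)
class MetricsReport:
    """Scores for one reference/test image pair (entropy/gradient of the test)."""

    psnr_db: float
    ssim: float
    entropy_bits: float
    avg_gradient: float

    def to_dict(self) -> dict:
        return asdict(self)


def _quantize(img: ImageGray, conv: EvalConvention) -> np.ndarray:
    return np.rint(np.clip(img.pixels, 0.0, 1.0) * conv.data_range)


def _shave(arr: np.ndarray, border: int) -> np.ndarray:
    if border == 0:
        return arr
    if arr.shape[0] - 2 * border < 8 or arr.shape[1] - 2 * border < 8:
        raise ShapeError(
            f"border shave {border} leaves fewer than 8x8 pixels of {arr.shape}"
        )
    return arr[border:-border, border:-border]


def _prep_pair(
    ref: ImageGray, test: ImageGray, conv: EvalConvention
) -> tuple[np.ndarray, np.ndarray]:
    if (ref.height, ref.width) != (test.height, test.width):
        raise ShapeError(
            f"shape mismatch: ref {ref.height}x{ref.width}, "
            f"test {test.height}x{test.width}"
        )
    return (
        _shave(_quantize(ref, conv), conv.border_shave),
        _shave(_quantize(test, conv), conv.border_shave),
    )


def psnr(ref: ImageGray, test: ImageGray, conv: EvalConvention = EvalConvention()) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a, b = _prep_pair(ref, test, conv)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(conv.data_range**2 / mse)


def ssim(ref: ImageGray, test: ImageGray, conv: EvalConvention = EvalConvention()) -> float:
    """Mean structural similarity over 11x11 Gaussian windows (sigma 1.5)."""
    a, b = _prep_pair(ref, test, conv)
    if min(a.shape) < 11:
        raise ShapeError(f"image {a.shape} smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            a,
            b,
            data_range=float(conv.data_range),
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def shannon_entropy(img: ImageGray, conv: EvalConvention = EvalConvention()) -> float:
    """Shannon entropy (bits) of the quantized gray-level histogram."""
    q = _quantize(img, conv)
    hist, _ = np.histogram(q, bins=conv.histogram_bins, range=(0, conv.data_range + 1))
    p = hist[hist > 0] / q.size
    return float(-(p * np.log2(p)).sum())


def average_gradient(img: ImageGray | np.ndarray) -> float:
    """Mean of sqrt((dx^2 + dy^2)/2) over forward differences (sharpness proxy)."""
    px = img.pixels if isinstance(img, ImageGray) else np.asarray(img, dtype=np.float64)
    if px.shape[0] < 2 or px.shape[1] < 2:
        raise ShapeError("average_gradient needs at least 2x2 pixels")
    dx = px[:-1, 1:] - px[:-1, :-1]
    dy = px[1:, :-1] - px[:-1, :-1]
    return float(np.mean(np.sqrt((dx * dx + dy * dy) / 2.0)))


def evaluate_pair(
    ref: ImageGray, test: ImageGray, conv: EvalConvention = EvalConvention()
) -> MetricsReport:
    """All four metrics for one pair under one convention (pure function)."""
    a, b = _prep_pair(ref, test, conv)
    mse = float(np.mean((a - b) ** 2))
    psnr_db = math.inf if mse == 0.0 else 10.0 * math.log10(conv.data_range**2 / mse)
    ssim_val = float(
        structural_similarity(
            a,
            b,
            data_range=float(conv.data_range),
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )
    hist, _ = np.histogram(b, bins=conv.histogram_bins, range=(0, conv.data_range + 1))
    p = hist[hist > 0] / b.size
    entropy = float(-(p * np.log2(p)).sum())
    return MetricsReport(
        psnr_db=psnr_db,
        ssim=ssim_val,
        entropy_bits=entropy,
        avg_gradient=average_gradient(b),
    )
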