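"""ROI-based two-channel colocalization analysis.

Colocalization of a presynaptic marker channel with a second signal channel
is quantified by the Pearson product-moment correlation of pixel intensities
within a region of interest, after a flat background subtraction.  Line-scan
profiles (bilinear interpolation along a segment) and ROI mean-intensity
ratios support the qualitative overlap and signal-to-background analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "LineSegment",
    "PearsonResult",
    "UndefinedCorrelationError",
    "subtract_background",
    "pearson",
    "line_profile",
    "roi_mean_ratio",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance in a channel)."""


@dataclass(frozen=True)
class LineSegment:
    """A line in pixel coordinates, endpoints given as (row, col)."""

    start: tuple[float, float]
    end: tuple[float, float]
    length_um: float | None = None

    def __post_init__(self):
        if self.start == self.end:
            raise ValueError("line segment must have nonzero length")

    @property
    def length_px(self) -> float:
        return math.dist(self.start, self.end)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    n_pixels: int


def subtract_background(image: np.ndarray, value: float = 16.0) -> np.ndarray:
    """Pixelwise max(intensity - value, 0); flat background subtraction."""
    if value < 0:
        raise ValueError("background value must be non-negative")
    img = np.asarray(image, dtype=float)
    return np.clip(img - value, 0.0, None)


def pearson(
    ch_a: np.ndarray, ch_b: np.ndarray, mask: np.ndarray | None = None,
    min_pixels: int = 10,
) -> PearsonResult:
    """Pearson correlation of two channels over the masked pixels.

    Raises :class:`UndefinedCorrelationError` rather than propagating NaN when
    either channel has zero variance within the mask.
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have identical shape")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("mask must be congruent with the channels")
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < min_pixels:
        raise ValueError(f"need at least {min_pixels} pixels, got {a.size}")
    a = a - a.mean()
    b = b - b.mean()
    va, vb = float(np.dot(a, a)), float(np.dot(b, b))
    if va == 0.0 or vb == 0.0:
        raise UndefinedCorrelationError("zero variance within the ROI")
    r = float(np.dot(a, b) / math.sqrt(va * vb))
    return PearsonResult(r=r, n_pixels=int(a.size))


def line_profile(image: np.ndarray, segment: LineSegment, n_samples: int) -> np.ndarray:
    """Intensities sampled at equally spaced points along a segment.

    Bilinear interpolation (1-pixel-wide sampling); both endpoints must lie
    inside the image.
    """
    img = np.asarray(image, dtype=float)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    (r0, c0), (r1, c1) = segment.start, segment.end
    for r, c in (segment.start, segment.end):
        if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
            raise ValueError(f"segment endpoint ({r}, {c}) outside the image")
    rows = np.linspace(r0, r1, n_samples)
    cols = np.linspace(c0, c1, n_samples)
    return map_coordinates(img, np.vstack([rows, cols]), order=1, mode="nearest")


def roi_mean_ratio(image: np.ndarray, roi_a: np.ndarray, roi_b: np.ndarray) -> float:
    """Ratio of mean intensities mean(ROI A)/mean(ROI B), e.g. signal:background."""
    img = np.asarray(image, dtype=float)
    ma = np.asarray(roi_a, dtype=bool)
    mb = np.asarray(roi_b, dtype=bool)
    if not ma.any() or not mb.any():
        raise ValueError("both ROIs must be non-empty")
    denom = float(img[mb].mean())
    if denom <= 0:
        raise ValueError("denominator ROI mean must be positive")
    return float(img[ma].mean()) / denom
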