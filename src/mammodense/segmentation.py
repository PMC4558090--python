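"""Dense-tissue segmentation by moment-preserving global thresholding.

A mammogram is dichotomized into *dense* (fibroglandular, radio-opaque) and
*lucent* (fatty) tissue by a single global gray-level threshold chosen so that
the binarized image preserves the first three gray-level moments of the
original masked image.  The fraction of breast area classified dense is the
percent density (PD), the quantity this whole package quantifies.

The moment-preserving ("Moments") threshold works on the 256-bin histogram of
the masked pixels: from the normalized histogram compute moments
``m1, m2, m3``; solve for the unique two-level image ``(z0, z1)`` with
below-threshold fraction ``p0`` that has the same three moments; the threshold
is then the p0-tile of the histogram — the smallest gray level whose
cumulative fraction reaches ``p0``.  Pixels strictly above the threshold are
dense, so exactly the below-or-equal fraction ``p0`` is non-dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MammogramImage",
    "SegmentationResult",
    "DegenerateHistogramError",
    "to_uint8",
    "masked_histogram",
    "moments_threshold",
    "apply_threshold",
    "area_metrics",
    "segment",
]

# Cumulative-fraction comparisons tolerate this much float error so that an
# exactly attained p0 (e.g. 0.5 on a symmetric histogram) selects the bin that
# attains it rather than the next one.
_CUM_TOL = 1e-9


class DegenerateHistogramError(ValueError):
    """Histogram cannot support a two-level moment fit (single gray value,
    zero variance, or complex two-level solution)."""


@dataclass
class MammogramImage:
    """One grayscale mammogram with physical calibration and identity.

    Parameters
    ----------
    pixels
        2-D uint8 array of gray levels in [0, 255].  Higher = more
        radio-opaque.  Images from deeper bit depths must be normalized
        first (see :func:`to_uint8`).
    pixel_spacing_cm
        Physical side length of one pixel in centimetres.
    laterality
        ``"L"`` or ``"R"``.
    timepoint
        ``"entry"`` or ``"exit"``.
    subject_id
        Identifier linking images of the same woman.
    """

    pixels: np.ndarray
    pixel_spacing_cm: float
    laterality: str = "L"
    timepoint: str = "entry"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_spacing_cm <= 0:
            raise ValueError("pixel_spacing_cm must be positive")
        if self.laterality not in ("L", "R"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass
class SegmentationResult:
    """Threshold, dense map and pixel-calibrated area metrics for one image.

    ``dense_area_cm2 + lucent_area_cm2 == breast_area_cm2`` holds exactly in
    pixel counts, and ``overall_pd = 100 * dense / breast``.
    """

    threshold: int
    dense_map: np.ndarray
    breast_px: int
    dense_px: int
    breast_area_cm2: float
    dense_area_cm2: float
    lucent_area_cm2: float
    overall_pd: float

    @property
    def lucent_px(self) -> int:
        return self.breast_px - self.dense_px


def to_uint8(pixels: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Min–max normalize an image to the 8-bit range.

    Deeper-bit-depth images (e.g. 12/16-bit DICOM) are linearly rescaled so
    that the masked minimum maps to 0 and the masked maximum to 255; the
    moments method then always operates on a fixed 256-bin domain.  uint8
    input is returned unchanged.
    """
    pixels = np.asarray(pixels)
    if pixels.dtype == np.uint8:
        return pixels
    ref = pixels[mask] if mask is not None else pixels
    if ref.size == 0:
        raise ValueError("empty mask: cannot normalize")
    lo, hi = float(ref.min()), float(ref.max())
    if hi <= lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    scaled = (pixels.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def masked_histogram(image: MammogramImage | np.ndarray, mask: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram over masked pixels only.

    Restricting the histogram to the breast mask prevents radio-dense
    objects outside the breast (labels, pectoral muscle) from influencing
    the threshold.
    """
    pixels = image.pixels if isinstance(image, MammogramImage) else np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError("mask shape does not match image shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = pixels[mask]
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("gray levels outside [0, 255]; normalize with to_uint8 first")
    return np.bincount(vals.astype(np.intp).ravel(), minlength=256)[:256]


def moments_threshold(hist: np.ndarray) -> int:
    """Moment-preserving automatic threshold of a 256-bin histogram.

    Solves the two-level moment-matching problem and returns the p0-tile of
    the histogram: the smallest gray level ``g`` with cumulative fraction
    ``>= p0``, where ``p0`` is the moment-preserving below-threshold
    fraction.

    Raises
    ------
    DegenerateHistogramError
        If the histogram has fewer than two occupied gray levels, zero
        variance, or the two-level solution is not real.  Degenerate input
        is always an explicit error, never a silent mid-scale fallback.
    """
    counts = np.asarray(hist, dtype=np.float64)
    if counts.ndim != 1 or counts.shape[0] != 256:
        raise ValueError("histogram must have 256 bins")
    if (counts < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("single occupied gray level")

    p = counts / total
    z = np.arange(256, dtype=np.float64)
    m1 = float(p @ z)
    m2 = float(p @ z**2)
    m3 = float(p @ z**3)

    var = m2 - m1 * m1
    if var <= 1e-12:
        raise DegenerateHistogramError("zero gray-level variance")

    # Two-point moment match: z0, z1 are roots of z^2 + c1*z + c0 = 0.
    c0 = (m1 * m3 - m2 * m2) / var
    c1 = (m1 * m2 - m3) / var
    disc = c1 * c1 - 4.0 * c0
    if disc <= 0:
        raise DegenerateHistogramError("two-level solution is not real")
    root = np.sqrt(disc)
    z0 = 0.5 * (-c1 - root)
    z1 = 0.5 * (-c1 + root)
    p0 = (z1 - m1) / (z1 - z0)
    if not (0.0 < p0 < 1.0):
        raise DegenerateHistogramError(f"below-threshold fraction p0={p0} outside (0,1)")

    cum = np.cumsum(p)
    return int(np.argmax(cum >= p0 - _CUM_TOL))


def apply_threshold(
    image: MammogramImage | np.ndarray, mask: np.ndarray, threshold: int
) -> np.ndarray:
    """Binary dense map: masked pixels strictly above the threshold.

    Tie pixels at the threshold gray level belong to the non-dense class
    (the p0-tile is a below-or-equal fraction); everything outside the mask
    is non-dense regardless of gray level.
    """
    pixels = image.pixels if isinstance(image, MammogramImage) else np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return (pixels > threshold) & mask


def area_metrics(
    dense_map: np.ndarray, mask: np.ndarray, pixel_spacing_cm: float, threshold: int = -1
) -> SegmentationResult:
    """Pixel-calibrated breast/dense/lucent areas and overall percent density.

    ``breast_area = |mask| * spacing^2`` etc.; the dense/lucent split is
    exact in pixel counts, so areas conserve by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    dense_map = np.asarray(dense_map, dtype=bool)
    if pixel_spacing_cm <= 0:
        raise ValueError("pixel_spacing_cm must be positive")
    if (dense_map & ~mask).any():
        raise ValueError("dense_map must be a subset of the mask")
    breast_px = int(mask.sum())
    if breast_px == 0:
        raise ValueError("empty mask")
    dense_px = int(dense_map.sum())
    px_area = pixel_spacing_cm**2
    breast_area = breast_px * px_area
    dense_area = dense_px * px_area
    return SegmentationResult(
        threshold=int(threshold),
        dense_map=dense_map,
        breast_px=breast_px,
        dense_px=dense_px,
        breast_area_cm2=breast_area,
        dense_area_cm2=dense_area,
        lucent_area_cm2=(breast_px - dense_px) * px_area,
        overall_pd=100.0 * dense_px / breast_px,
    )


def segment(image: MammogramImage, mask: np.ndarray) -> SegmentationResult:
    """Full single-image segmentation: histogram → threshold → areas."""
    hist = masked_histogram(image, mask)
    t = moments_threshold(hist)
    dense = apply_threshold(image, mask, t)
    return area_metrics(dense, mask, image.pixel_spacing_cm, threshold=t)
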