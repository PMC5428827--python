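"""The four feature-specific image-preprocessing variants.

Every variant starts by restricting the ROI mask to voxels within the
[-100, 200] HU soft-tissue window (normal lung and bone are excluded from
the contour that way; image values are never clipped). The optional steps are
a 2D per-slice low-pass Butterworth filter and an 8-bit dynamic-range
resample, applied in that order:

    raw              threshold only
    smooth           threshold + Butterworth (order 2, cutoff 125)
    resample8        threshold + 8-bit resample
    smooth_resample8 threshold + Butterworth + 8-bit resample

Smoothing operates on the full image before masking so boundary voxels see
their true neighbors. The Butterworth cutoff is interpreted as an index on a
512-sample DFT axis (the reconstruction matrix), i.e. f_c = 125/256 of the
Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HU_LO_DEFAULT = -100.0
HU_HI_DEFAULT = 200.0

#: 12-bit CT HU dynamic range mapped by the bit-depth resample.
HU_RANGE = (-1024.0, 3071.0)


class EmptyRoiError(ValueError):
    """Thresholding removed every voxel of the ROI."""


@dataclass(frozen=True)
class PreprocessingVariant:
    id: str
    smooth: bool
    resample: bool
    butterworth_order: int = 2
    butterworth_cutoff: float = 125.0
    bit_depth: int = 8

    def __post_init__(self):
        if self.butterworth_order < 1:
            raise ValueError("Butterworth order must be >= 1")
        if self.butterworth_cutoff <= 0:
            raise ValueError("Butterworth cutoff must be positive")


VARIANTS = {
    "raw": PreprocessingVariant("raw", smooth=False, resample=False),
    "smooth": PreprocessingVariant("smooth", smooth=True, resample=False),
    "resample8": PreprocessingVariant("resample8", smooth=False, resample=True),
    "smooth_resample8": PreprocessingVariant("smooth_resample8", smooth=True, resample=True),
}

#: Fixed variant order used for deterministic tie-breaks downstream.
VARIANT_ORDER = ("raw", "smooth", "resample8", "smooth_resample8")


def threshold_roi(image, mask, lo_hu: float = HU_LO_DEFAULT, hi_hu: float = HU_HI_DEFAULT,
                  context: str = "") -> np.ndarray:
    """Restrict the mask to voxels with lo_hu <= HU <= hi_hu (bounds inclusive)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = mask & (image >= lo_hu) & (image <= hi_hu)
    if not out.any():
        raise EmptyRoiError(f"thresholding emptied the ROI{f' ({context})' if context else ''}")
    return out


def butterworth_smooth(image, order: int = 2, cutoff: float = 125.0) -> np.ndarray:
    """Low-pass radial Butterworth filter, applied slice by slice in 2D.

    The transfer function H(f) = 1/sqrt(1 + (f/f_c)^(2*order)) multiplies the
    2D DFT of each axial slice; DC gain is exactly 1 so the slice mean is
    preserved. Slices are the trailing two axes (axis 0 = slice direction is
    the coarse axis in this package's (z, y, x) convention).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape[-2:]
    fy = np.fft.fftfreq(ny)[:, None]  # cycles/sample in [-0.5, 0.5)
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    f_c = (cutoff / 256.0) * 0.5  # cutoff index on a 512-sample axis -> normalized
    H = 1.0 / np.sqrt(1.0 + (f / f_c) ** (2 * order))
    spec = np.fft.fft2(image, axes=(-2, -1))
    out = np.fft.ifft2(spec * H, axes=(-2, -1)).real
    return out


def resample_bit_depth(image, bits: int = 8) -> np.ndarray:
    """Quantize the 12-bit HU dynamic range [-1024, 3071] to 2**bits levels.

    level = floor((HU + 1024) / bin_width) clamped to [0, 2**bits - 1], with
    bin_width = 4096 / 2**bits (16 HU at 8 bits).
    """
    if not 1 <= bits <= 16:
        raise ValueError("bits must be in 1..16")
    image = np.asarray(image, dtype=float)
    bin_width = (HU_RANGE[1] - HU_RANGE[0] + 1.0) / (2**bits)
    levels = np.floor((image - HU_RANGE[0]) / bin_width)
    return np.clip(levels, 0, 2**bits - 1).astype(np.int64)


def apply_variant(image, mask, variant: PreprocessingVariant | str, context: str = ""):
    """Run one preprocessing variant: threshold -> smooth -> resample.

    Returns (processed image, thresholded mask). The mask is thresholded on
    the original HU values; smoothing and quantization act on the full image.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    roi = threshold_roi(image, mask, context=context)
    out = np.asarray(image, dtype=float)
    if variant.smooth:
        out = butterworth_smooth(out, variant.butterworth_order, variant.butterworth_cutoff)
    if variant.resample:
        out = resample_bit_depth(out, variant.bit_depth)
    return out, roi
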