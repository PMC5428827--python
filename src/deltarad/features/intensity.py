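"""First-order intensity-histogram features inside the thresholded ROI."""

from __future__ import annotations

import numpy as np
from scipy import stats

INTENSITY_FEATURE_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "std",
    "variance",
    "skewness",
    "kurtosis",
    "hist_energy",
    "hist_entropy",
)

#: Histogram bins for un-quantized (HU-valued) variants: 16-HU bins over the
#: thresholded range [-100, 200] HU (19 bins).
HU_BIN_EDGES = np.arange(-100.0, 200.0 + 16.0, 16.0)


def _hist_probs(values, binning):
    if binning == "hu16":
        counts, _ = np.histogram(np.clip(values, -100.0, 200.0), bins=HU_BIN_EDGES)
    elif binning == "native":
        v = np.round(values).astype(int)
        counts = np.bincount(v - v.min())
    else:
        raise ValueError(f"unknown binning {binning!r}")
    p = counts[counts > 0] / counts.sum()
    return p


def intensity_features(image, mask, binning="hu16") -> dict:
    """Eleven first-order statistics of the masked voxel values.

    `binning` controls only the histogram energy/entropy axis: "hu16" uses
    16-HU bins over the thresholded range, "native" uses the integer
    quantization levels themselves (for bit-depth-resampled variants).
    Skewness and kurtosis of a constant region are recorded as 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(image, dtype=float)[mask]
    sd = float(v.std())
    p = _hist_probs(v, binning)
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "std": sd,
        "variance": float(v.var()),
        "skewness": float(stats.skew(v, bias=True)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v, fisher=False, bias=True)) if sd > 0 else 0.0,
        "hist_energy": float((p**2).sum()),
        "hist_entropy": float(-(p * np.log2(p)).sum()),
    }
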