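"""Gray-level co-occurrence matrix (GLCM) construction and its 22 features.

Pairs are counted symmetrically (each ordered pair contributes to (i, j) and
(j, i)) over the requested direction offsets, summed into a single matrix and
normalized, so the result is a joint probability with equal marginals.
"""

from __future__ import annotations

import numpy as np

from .matrices import DIRECTIONS_13, DegenerateMatrixError, TextureMatrix, _shifted_views, as_levels

_EPS = 1e-12


def build_glcm(levels, mask, offsets=DIRECTIONS_13, n_levels: int | None = None) -> TextureMatrix:
    """Count symmetric co-occurrences of gray tones at distance-1 offsets.

    Both voxels of a pair must lie inside the mask. Tones must be integers
    >= 1; `n_levels` defaults to the maximum tone present.
    """
    levels = as_levels(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if n_levels is None:
        if not mask.any():
            raise DegenerateMatrixError("empty mask")
        n_levels = int(levels[mask].max())
    if mask.any() and (levels[mask].min() < 1 or levels[mask].max() > n_levels):
        raise ValueError("tones must lie in 1..n_levels inside the mask")

    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for off in offsets:
        off = tuple(off) + (0,) * (levels.ndim - len(off)) if len(off) < levels.ndim else tuple(off)
        a, b = _shifted_views(levels.shape, off)
        valid = mask[a] & mask[b]
        if not valid.any():
            continue
        ga = levels[a][valid] - 1
        gb = levels[b][valid] - 1
        np.add.at(counts, (ga, gb), 1)
        np.add.at(counts, (gb, ga), 1)

    total = counts.sum()
    if total < 2:
        raise DegenerateMatrixError("fewer than 2 in-mask neighbor pairs")
    return TextureMatrix("GLCM", n_levels, counts / total, float(total), {"counts": counts})


#: Registry order of the 22 co-occurrence features.
GLCM_FEATURE_NAMES = (
    "energy",
    "entropy",
    "contrast",
    "correlation",
    "homogeneity",
    "inverse_diff_moment",
    "dissimilarity",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "cluster_tendency",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "difference_entropy",
    "difference_variance",
    "imc1",
    "imc2",
    "variance",
    "inverse_diff_normalized",
    "inverse_diff_moment_normalized",
)


def _plogp(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(tm: TextureMatrix) -> dict:
    """The canonical 22-feature co-occurrence set on a normalized matrix.

    Gray tones i, j run over 1..K. The matrix is symmetric, so the two
    marginals coincide (px == py).
    """
    P = np.asarray(tm.matrix, dtype=float)
    if P.sum() <= 0:
        raise DegenerateMatrixError("zero-sum matrix")
    P = P / P.sum()
    K = P.shape[0]
    i = np.arange(1, K + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2K and p_{x-y}(k), k = 0..K-1
    psum = np.zeros(2 * K + 1)
    np.add.at(psum, (ii + jj).ravel(), P.ravel())
    pdiff = np.zeros(K)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), P.ravel())
    ks = np.arange(2 * K + 1)
    kd = np.arange(K)

    sum_avg = float((ks * psum).sum())
    diff_avg = float((kd * pdiff).sum())

    hx = _plogp(px)
    hxy = _plogp(P.ravel())
    # joint entropies of the independence surrogate
    pxy = np.outer(px, py)
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxy[nz] + _EPS)).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    if sd_x * sd_y > _EPS:
        correlation = float((((ii - mu_x) * (jj - mu_y) * P).sum()) / (sd_x * sd_y))
    else:
        correlation = 1.0  # single-tone matrix: perfectly dependent by convention

    imc1 = (hxy - hxy1) / max(hx, hx, _EPS) if hx > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    feats = {
        "energy": float((P**2).sum()),
        "entropy": hxy,
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": correlation,
        "homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_diff_moment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "autocorrelation": float((ii * jj * P).sum()),
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        "cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * P).sum()),
        "max_probability": float(P.max()),
        "sum_average": sum_avg,
        "sum_entropy": _plogp(psum),
        "sum_variance": float(((ks - sum_avg) ** 2 * psum).sum()),
        "difference_entropy": _plogp(pdiff),
        "difference_variance": float(((kd - diff_avg) ** 2 * pdiff).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "variance": float(((ii - mu_x) ** 2 * P).sum()),
        "inverse_diff_normalized": float((P / (1.0 + np.abs(ii - jj) / K)).sum()),
        "inverse_diff_moment_normalized": float((P / (1.0 + (ii - jj) ** 2 / K**2)).sum()),
    }
    return feats
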