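"""Neighborhood gray-tone difference matrix (NGTDM) and its five features.

For every in-mask voxel with at least one 26-connected in-mask neighbor, the
absolute difference between its tone and the mean tone of its in-mask
neighborhood is accumulated per tone: per tone i the matrix carries the
occupancy n_i, probability p_i = n_i / N and summed difference
s_i = sum |i - mean(neighborhood)|.
"""

from __future__ import annotations

import numpy as np

from .matrices import NEIGHBORS_26, DegenerateMatrixError, TextureMatrix, _shifted_views, as_levels

#: Guard used in denominators; a flat region saturates coarseness at 1/EPS.
EPS = 1e-6

NGTDM_FEATURE_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def build_ngtdm(levels, mask, n_levels: int | None = None) -> TextureMatrix:
    levels = as_levels(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if not mask.any():
        raise DegenerateMatrixError("empty mask")
    if n_levels is None:
        n_levels = int(levels[mask].max())

    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    lv = np.where(mask, levels, 0)
    for off in NEIGHBORS_26:
        a, b = _shifted_views(levels.shape, off)
        nb_sum[a] += lv[b]
        nb_cnt[a] += mask[b]

    valid = mask & (nb_cnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateMatrixError("no voxel has an in-mask neighbor")
    mean_nb = nb_sum[valid] / nb_cnt[valid]
    tone = levels[valid]
    diff = np.abs(tone - mean_nb)

    n_i = np.bincount(tone - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(tone - 1, weights=diff, minlength=n_levels)
    p_i = n_i / n_valid
    mat = np.column_stack([n_i, p_i, s_i])
    return TextureMatrix("NGTDM", n_levels, mat, float(n_valid))


def ngtdm_features(tm: TextureMatrix) -> dict:
    """Coarseness, contrast, busyness, complexity and strength.

    Degenerate conventions: a single-tone region has all s_i = 0, which
    saturates coarseness at 1/EPS and zeroes contrast and strength; busyness
    and complexity are 0 when their sums are empty.
    """
    mat = np.asarray(tm.matrix, dtype=float)
    if mat[:, 0].sum() <= 0:
        raise DegenerateMatrixError("empty NGTDM")
    n_i, p_i, s_i = mat[:, 0], mat[:, 1], mat[:, 2]
    N = tm.norm
    i = tm.levels.astype(float)
    present = p_i > 0
    ng = int(present.sum())

    coarseness = 1.0 / (EPS + float((p_i * s_i).sum()))

    if ng > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ii_, jj_ = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float((pi_ * pj_ * (ii_ - jj_) ** 2).sum()) / (ng * (ng - 1)) * float(s_i.sum()) / N
        busy_den = float(np.abs(ii_ * pi_ - jj_ * pj_).sum())
        busyness = float((p_i * s_i).sum()) / busy_den if busy_den > EPS else 0.0
        ps = (p_i * s_i)[present]
        psi_, psj_ = np.meshgrid(ps, ps, indexing="ij")
        complexity = float((np.abs(ii_ - jj_) * (psi_ + psj_) / (N * (pi_ + pj_))).sum())
        strength_num = float((pi_ * pj_ * (ii_ - jj_) ** 2).sum())
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength_num = 0.0

    strength = strength_num / (EPS + float(s_i.sum()))

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
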