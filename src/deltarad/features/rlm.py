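"""Gray-level run-length matrix (RLM) and its eleven features.

Runs are maximal collinear sequences of equal-tone in-mask voxels, traced
along the 13 unique 3D directions and accumulated into one matrix of counts
r(g, l); runs break at the mask boundary.
"""

from __future__ import annotations

import numpy as np

from .matrices import DIRECTIONS_13, DegenerateMatrixError, TextureMatrix, as_levels

RLM_FEATURE_NAMES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
)


def _runs_one_direction(coords, tones, direction):
    """Run-length encode in-mask voxels along one direction.

    Voxels lie on the same line iff their coordinate difference is an integer
    multiple of `direction`; because every component of the direction is in
    {-1, 0, 1}, the step index along the line equals the (signed) coordinate
    along the first nonzero component.
    """
    d = np.asarray(direction)
    a0 = int(np.nonzero(d)[0][0])
    step = coords[:, a0] * int(np.sign(d[a0]))
    origin = coords - step[:, None] * d
    # sort voxels by line then by position along the line
    order = np.lexsort((step, origin[:, 2], origin[:, 1], origin[:, 0]))
    o = origin[order]
    s = step[order]
    t = tones[order]
    same_line = np.all(o[1:] == o[:-1], axis=1)
    contiguous = s[1:] == s[:-1] + 1
    same_tone = t[1:] == t[:-1]
    extend = same_line & contiguous & same_tone
    # run starts where extension breaks
    starts = np.flatnonzero(np.concatenate([[True], ~extend]))
    lengths = np.diff(np.concatenate([starts, [len(t)]]))
    return t[starts], lengths


def build_rlm(levels, mask, directions=DIRECTIONS_13, n_levels: int | None = None) -> TextureMatrix:
    levels = as_levels(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if not mask.any():
        raise DegenerateMatrixError("no runs: empty mask")
    if n_levels is None:
        n_levels = int(levels[mask].max())

    coords = np.argwhere(mask)
    tones = levels[tuple(coords.T)]
    max_len = int(max(levels.shape))
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    for d in directions:
        g, l = _runs_one_direction(coords, tones, d)
        np.add.at(counts, (g - 1, l - 1), 1)

    if counts.sum() == 0:
        raise DegenerateMatrixError("no runs")
    return TextureMatrix("RLM", n_levels, counts, float(counts.sum()))


def rlm_features(tm: TextureMatrix) -> dict:
    """Galloway/Chu run-length statistics.

    Run percentage uses the total voxel traversals sum_{g,l} l * r(g, l) as
    the denominator, so it stays in (0, 1] under multi-direction accumulation.
    """
    R = np.asarray(tm.matrix, dtype=float)
    nr = R.sum()
    if nr <= 0:
        raise DegenerateMatrixError("no runs")
    g = np.arange(1, R.shape[0] + 1, dtype=float)
    l = np.arange(1, R.shape[1] + 1, dtype=float)
    gg, ll = np.meshgrid(g, l, indexing="ij")
    r_g = R.sum(axis=1)
    r_l = R.sum(axis=0)
    n_vox = float((R * ll).sum())

    return {
        "sre": float((r_l / l**2).sum() / nr),
        "lre": float((r_l * l**2).sum() / nr),
        "gln": float((r_g**2).sum() / nr),
        "rln": float((r_l**2).sum() / nr),
        "rp": float(nr / n_vox),
        "lgre": float((r_g / g**2).sum() / nr),
        "hgre": float((r_g * g**2).sum() / nr),
        "srlge": float((R / (gg**2 * ll**2)).sum() / nr),
        "srhge": float((R * gg**2 / ll**2).sum() / nr),
        "lrlge": float((R * ll**2 / gg**2).sum() / nr),
        "lrhge": float((R * gg**2 * ll**2).sum() / nr),
    }
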