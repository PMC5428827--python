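"""Texture-matrix containers and the shared 3D direction set.

All three matrix builders (GLCM, NGTDM, RLM) operate on integer gray-tone
arrays (tones start at 1) with an aligned boolean mask, and aggregate over
the 13 unique 3D directions at Chebyshev distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 13 unique direction offsets in 3D at distance 1 (one per antipodal pair).
DIRECTIONS_13 = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

#: All 26 neighbor offsets (both signs), used by the NGTDM neighborhood.
NEIGHBORS_26 = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)


class DegenerateMatrixError(ValueError):
    """Raised when a texture matrix cannot be formed (empty / no pairs / no runs)."""


@dataclass
class TextureMatrix:
    """A built texture matrix plus its normalization constant.

    kind : "GLCM", "NGTDM" or "RLM".
    n_levels : size of the gray-tone axis (tones are 1..n_levels).
    matrix : GLCM -> (n_levels, n_levels) normalized joint probabilities;
             RLM -> (n_levels, max_run_length) integer run counts;
             NGTDM -> (n_levels, 3) columns (n_i, p_i, s_i).
    norm : GLCM -> total symmetric pair count; RLM -> total run count;
           NGTDM -> number of voxels with at least one in-mask neighbor.
    """

    kind: str
    n_levels: int
    matrix: np.ndarray
    norm: float
    meta: dict = field(default_factory=dict)

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.n_levels + 1)


def _shifted_views(shape, offset):
    """Index slices (a, b) such that arr[a] and arr[b] are offset by `offset`."""
    a, b = [], []
    for dim, off in zip(shape, offset):
        if off >= 0:
            a.append(slice(0, dim - off))
            b.append(slice(off, dim))
        else:
            a.append(slice(-off, dim))
            b.append(slice(0, dim + off))
    return tuple(a), tuple(b)


def as_levels(arr) -> np.ndarray:
    levels = np.asarray(arr)
    if not np.issubdtype(levels.dtype, np.integer):
        if not np.allclose(levels, np.round(levels)):
            raise ValueError("gray-tone array must contain integers")
        levels = np.round(levels).astype(np.int64)
    return levels.astype(np.int64, copy=False)
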