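"""Tiny deterministic image fixtures used as oracle substrates.

Values in these grids are small integers intended to be used directly as
gray tones by the texture-matrix builders; masks and isotropic unit spacing
accompany each grid. The 4x4x1 four-tone grid and the two-tone checkerboard
are stored verbatim so hand-enumerated oracle values cannot drift.
"""

from __future__ import annotations

import numpy as np

# fmt: off
_HARALICK_4X4 = np.array(
    [[1, 1, 2, 2],
     [1, 1, 2, 2],
     [1, 3, 3, 3],
     [3, 3, 4, 4]], dtype=np.int64,
)

_CHECKER_2 = np.array(
    [[[1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1]],
     [[2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2]],
     [[1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1]],
     [[2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2]]], dtype=np.int64,
)
# fmt: on


def _ball(radius: int, value: int = 1):
    n = 2 * radius + 3
    c = n // 2
    zz, yy, xx = np.indices((n, n, n))
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return np.where(mask, value, 0).astype(np.int64), mask


def _cube(side: int, value: int = 1):
    n = side + 4
    img = np.zeros((n, n, n), dtype=np.int64)
    sl = slice(2, 2 + side)
    img[sl, sl, sl] = value
    return img, img > 0


def _registry():
    return {
        "const8": lambda: (np.full((8, 8, 8), 5, dtype=np.int64), np.ones((8, 8, 8), bool)),
        "checker2": lambda: (_CHECKER_2.copy(), np.ones_like(_CHECKER_2, bool)),
        "haralick4x4": lambda: (
            _HARALICK_4X4.copy()[None, :, :],
            np.ones((1, 4, 4), bool),
        ),
        "sphere_r10": lambda: _ball(10),
        "cube_s10": lambda: _cube(10),
    }


FIXTURE_NAMES = tuple(_registry().keys())


def generate_fixture(name: str):
    """Return (image, mask, spacing) for a named deterministic fixture."""
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    img, mask = reg[name]()
    return img, mask, (1.0, 1.0, 1.0)
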