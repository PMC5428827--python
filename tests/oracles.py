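"""Independent brute-force oracles for the texture-matrix builders.

Everything here is deliberately naive — explicit Python loops over voxels,
O(V * offsets) — and shares no code with the package implementations.
"""

import numpy as np


def brute_glcm_counts(levels, mask, offsets, n_levels):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    counts = np.zeros((n_levels, n_levels), dtype=int)
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, shape)) and mask[nb]:
                a, b = levels[idx] - 1, levels[nb] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def brute_ngtdm(levels, mask, n_levels):
    """(n_i, p_i, s_i) per tone via explicit 26-neighborhood enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    shape = levels.shape
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    n_valid = 0
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb_vals = []
        for off in offs:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, shape)) and mask[nb]:
                nb_vals.append(levels[nb])
        if not nb_vals:
            continue
        n_valid += 1
        tone = levels[idx]
        n_i[tone - 1] += 1
        s_i[tone - 1] += abs(tone - np.mean(nb_vals))
    p_i = n_i / n_valid if n_valid else n_i
    return n_i, p_i, s_i, n_valid


def brute_rlm_counts(levels, mask, directions, n_levels, max_len):
    """Run counts by walking every line in every direction."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    shape = levels.shape
    counts = np.zeros((n_levels, max_len), dtype=int)
    for d in directions:
        d = np.asarray(d)
        starts = []
        for idx in np.ndindex(shape):
            prev = tuple(np.asarray(idx) - d)
            inside = all(0 <= p < s for p, s in zip(prev, shape))
            # a line starts where stepping backwards leaves the grid
            if not inside:
                starts.append(idx)
        for start in starts:
            pos = np.asarray(start)
            run_level, run_len = None, 0
            while all(0 <= p < s for p, s in zip(pos, shape)):
                here = tuple(pos)
                if mask[here]:
                    lv = levels[here]
                    if lv == run_level:
                        run_len += 1
                    else:
                        if run_level is not None:
                            counts[run_level - 1, run_len - 1] += 1
                        run_level, run_len = lv, 1
                else:
                    if run_level is not None:
                        counts[run_level - 1, run_len - 1] += 1
                    run_level, run_len = None, 0
                pos = pos + d
            if run_level is not None:
                counts[run_level - 1, run_len - 1] += 1
    return counts


def direct_glcm_features(P):
    """A handful of co-occurrence statistics by direct double summation."""
    P = np.asarray(P, float)
    P = P / P.sum()
    K = P.shape[0]
    out = {"energy": 0.0, "entropy": 0.0, "contrast": 0.0, "dissimilarity": 0.0,
           "autocorrelation": 0.0, "max_probability": P.max(), "homogeneity": 0.0}
    mu = sum((i + 1) * P[i, j] for i in range(K) for j in range(K))
    var = 0.0
    for i in range(K):
        for j in range(K):
            p = P[i, j]
            out["energy"] += p * p
            if p > 0:
                out["entropy"] -= p * np.log2(p)
            out["contrast"] += (i - j) ** 2 * p
            out["dissimilarity"] += abs(i - j) * p
            out["autocorrelation"] += (i + 1) * (j + 1) * p
            out["homogeneity"] += p / (1 + abs(i - j))
            var += (i + 1 - mu) ** 2 * p
    out["variance"] = var
    return out
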