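"""Full-registry feature extraction for single scans and longitudinal series.

Gray-tone axis for texture matrices:
  * bit-depth-resampled variants use the native 8-bit levels, shifted so the
    level containing -100 HU becomes tone 1 (20 possible tones over the
    thresholded window);
  * un-resampled variants use 16-HU-wide bins over the thresholded range
    [-100, 200] HU (19 tones) — the same bin width as the 8-bit resample, so
    tone transitions reflect density changes rather than 1-HU image noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..preprocessing import VARIANT_ORDER, VARIANTS, EmptyRoiError, apply_variant, resample_bit_depth
from .glcm import build_glcm, glcm_features
from .intensity import intensity_features
from .matrices import DegenerateMatrixError
from .ngtdm import build_ngtdm, ngtdm_features
from .registry import SHAPE_FEATURES, TEXTURE_FEATURES
from .rlm import build_rlm, rlm_features
from .shape import shape_features

#: 8-bit level containing -100 HU: floor((-100 + 1024)/16) = 57.
_LEVEL_AT_LO = int(resample_bit_depth(np.array([-100.0]))[0])
_N_TONES_8BIT = int(resample_bit_depth(np.array([200.0]))[0]) - _LEVEL_AT_LO + 1  # 20
_N_TONES_HU = 19  # ceil(300 / 16)


def texture_tones(processed, mask, variant) -> tuple[np.ndarray, int]:
    """Map a processed image to integer gray tones (1..K) for texture matrices."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    arr = np.asarray(processed, dtype=float)
    if variant.resample:
        tones = arr - (_LEVEL_AT_LO - 1)
        k = _N_TONES_8BIT
    else:
        tones = np.floor((arr + 100.0) / 16.0) + 1
        k = _N_TONES_HU
    tones = np.clip(tones, 1, k).astype(np.int64)
    return tones, k


def extract_scan_features(image, mask, spacing, variants=VARIANT_ORDER, context="") -> dict:
    """All registry features for one scan.

    Returns {"shape": {...}, "<variant>": {texture+intensity features}}.
    Texture/intensity features are computed per preprocessing variant; shape
    once from the raw contour. Raises EmptyRoiError if thresholding empties
    the ROI.
    """
    out = {"shape": shape_features(mask, spacing)}
    mask = np.asarray(mask, dtype=bool)
    for vid in variants:
        variant = VARIANTS[vid] if isinstance(vid, str) else vid
        processed, roi = apply_variant(image, mask, variant, context=context)
        # texture/intensity only see the ROI: crop to its bounding box (+1)
        idx = np.argwhere(roi)
        lo = np.maximum(idx.min(axis=0) - 1, 0)
        hi = np.minimum(idx.max(axis=0) + 2, roi.shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        processed, roi = processed[box], roi[box]
        vals = {}
        binning = "native" if variant.resample else "hu16"
        vals.update({f"int_{k}": v for k, v in intensity_features(processed, roi, binning).items()})
        tones, k = texture_tones(processed, roi, variant)
        try:
            vals.update({f"glcm_{k2}": v for k2, v in glcm_features(build_glcm(tones, roi, n_levels=k)).items()})
            vals.update({f"ngtdm_{k2}": v for k2, v in ngtdm_features(build_ngtdm(tones, roi, n_levels=k)).items()})
            vals.update({f"rlm_{k2}": v for k2, v in rlm_features(build_rlm(tones, roi, n_levels=k)).items()})
        except DegenerateMatrixError:
            for name in TEXTURE_FEATURES:
                vals.setdefault(name, np.nan)
        out[variant.id] = vals
    return out


def extract_all(series_by_patient, spacing, selected: dict | None = None,
                dose_by_patient_week=None) -> pd.DataFrame:
    """Longitudinal feature table over a cohort of image series.

    series_by_patient : {patient_id: [(week, image, mask), ...]}
    selected : optional {feature_name: variant_id} manifest. When given
        ("selected mode") each texture feature is computed only under its
        assigned variant and columns are plain feature names; when None
        ("screening mode") all four variants are computed and texture columns
        are "<feature>@<variant>". Shape features always appear once.
    dose_by_patient_week : optional {(patient, week): cumulative Gy}.

    A scan whose thresholded ROI is empty yields a row of NaNs (flagged via
    the "missing" column), not a failure.
    """
    rows = []
    for pid, scans in series_by_patient.items():
        for week, image, mask in scans:
            row = {"patient": pid, "week": week}
            if dose_by_patient_week is not None:
                row["dose_Gy"] = dose_by_patient_week.get((pid, week), np.nan)
            try:
                feats = extract_scan_features(image, mask, spacing, context=f"{pid} wk{week}")
                row["missing"] = False
                for name, val in feats["shape"].items():
                    row[f"shape_{name}"] = val
                row["volume_cm3"] = feats["shape"]["volume_cm3"]
                if selected is None:
                    for vid in VARIANT_ORDER:
                        for name, val in feats[vid].items():
                            row[f"{name}@{vid}"] = val
                else:
                    for name, vid in selected.items():
                        if name in SHAPE_FEATURES:
                            continue  # already present
                        row[name] = feats[vid].get(name, np.nan)
            except EmptyRoiError:
                row["missing"] = True
            rows.append(row)
    return pd.DataFrame(rows)
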