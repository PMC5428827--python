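"""Table-level emulation of the extracted feature tables.

For replicate-level statistical studies the voxel images are unnecessary:
what the downstream pipeline consumes is (a) a pretreatment feature vector
per patient and (b) a longitudinal (patient, week, dose) x feature table.
This generator produces both directly from the same latent variables that
drive the image generator — the planted shape covariate (compactness2) and
the latent response score — with random per-patient intercepts and weekly
measurement noise, so parameter-recovery behavior matches the image path at
a tiny fraction of its cost.

Evolving features (texture_strength, glcm_entropy, rlm_gln, volume) change
linearly with cumulative dose at a rate proportional to the latent score;
glcm_energy is static and serves as the built-in negative control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort
from .exclusions import apply_exclusions

#: per-Gy trend at unit latent score, per-patient intercept SD, weekly noise SD
FEATURE_MODEL = {
    "texture_strength": {"base": 5.0, "trend": -0.040, "intercept_sd": 0.8, "noise_sd": 0.25},
    "glcm_entropy": {"base": 6.0, "trend": -0.020, "intercept_sd": 0.5, "noise_sd": 0.15},
    "rlm_gln": {"base": 120.0, "trend": -0.60, "intercept_sd": 15.0, "noise_sd": 5.0},
    "glcm_energy": {"base": 0.05, "trend": 0.0, "intercept_sd": 0.01, "noise_sd": 0.004},
}

EVOLVING_FEATURES = tuple(n for n, m in FEATURE_MODEL.items() if m["trend"] != 0.0)
STATIC_FEATURES = tuple(n for n, m in FEATURE_MODEL.items() if m["trend"] == 0.0)

#: measurement noise on the pretreatment compactness2 readout
_C2_NOISE_SD = 0.015


def generate_cohort_tables(config: CohortConfig, exclusions: bool = True):
    """Generate (records, clinical_df, pretx_df, longitudinal_df).

    clinical_df: encoded clinical covariates + outcomes, indexed by patient.
    pretx_df: pretreatment ("Week0") feature values per patient, including
        compactness2 and volume_cm3.
    longitudinal_df: rows (patient, week, dose_Gy, features...) for week >= 1.
    """
    from .cohort import cohort_frame

    records, scores = generate_cohort(config)
    score_by_pid = {r.patient: s for r, s in zip(records, scores)}
    if exclusions:
        records, _ = apply_exclusions(records)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]).spawn(1)[0])

    clinical = cohort_frame(records)

    pre_rows, long_rows = [], []
    for r in records:
        score = score_by_pid[r.patient]
        c2 = r.shape_params["compactness2_true"] + rng.normal(0.0, _C2_NOISE_SD)
        intercepts = {n: rng.normal(0.0, m["intercept_sd"]) for n, m in FEATURE_MODEL.items()}
        values_at = {}
        for w in r.weeks:
            d = r.cumulative_dose[w]
            vals = {}
            for name, m in FEATURE_MODEL.items():
                vals[name] = (m["base"] + intercepts[name] + m["trend"] * score * d
                              + rng.normal(0.0, m["noise_sd"]))
            vol = r.pretx_volume_cm3 * np.exp(-config.shrink_rate_per_gy * score * d)
            vals["volume_cm3"] = vol * (1.0 + rng.normal(0.0, 0.01))
            values_at[w] = vals
        pre = {"patient": r.patient, "compactness2": c2}
        pre.update(values_at[r.weeks[0]])
        pre_rows.append(pre)
        for w in r.weeks[1:] if 0 in r.weeks else r.weeks:
            row = {"patient": r.patient, "week": w, "dose_Gy": r.cumulative_dose[w]}
            row.update(values_at[w])
            long_rows.append(row)

    pretx = pd.DataFrame(pre_rows).set_index("patient")
    longitudinal = pd.DataFrame(long_rows)
    return records, clinical, pretx, longitudinal
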