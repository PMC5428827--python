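"""Cohort exclusion rules applied before any modeling.

A patient is removed for (in this fixed order, counted once under the first
matching rule): pretreatment ROI volume < 5 cm^3 (strict), a non-conforming
imaging protocol, or occurrence of any endpoint event before the landmark day.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cohort import ENDPOINTS, CohortConfig, PatientRecord, generate_cohort


class ExclusionDataError(ValueError):
    pass


def apply_exclusions(records, min_volume_cm3: float = 5.0, landmark_day: int = 90):
    """Filter a cohort; returns (retained records, tally dict).

    Tally keys: small_volume, protocol, early_event, retained.
    """
    tally = {"small_volume": 0, "protocol": 0, "early_event": 0, "retained": 0}
    kept = []
    for r in records:
        vol = r.pretx_volume_cm3
        if vol is None or (isinstance(vol, float) and np.isnan(vol)):
            raise ExclusionDataError(f"missing pretreatment ROI volume for {r.patient}")
        if vol < min_volume_cm3:
            tally["small_volume"] += 1
        elif not r.protocol_conforming:
            tally["protocol"] += 1
        elif any(r.event[ep] and r.outcome_day[ep] - r.entry_day <= landmark_day
                 for ep in ENDPOINTS):
            tally["early_event"] += 1
        else:
            tally["retained"] += 1
            kept.append(r)
    return kept, tally


def exclusion_demo_cohort(seed: int = 0):
    """A deterministic 137-patient cohort with 18 small-ROI, 9 protocol and 3
    early-event patients planted disjointly (so 107 are retained)."""
    cfg = CohortConfig(n_patients=137, seed=seed, censoring_rate=0.0)
    records, _ = generate_cohort(cfg)
    out = []
    for i, r in enumerate(records):
        vol = max(r.pretx_volume_cm3, 6.0)
        conforming = True
        outcome_day = {ep: max(d, r.entry_day + 120) for ep, d in r.outcome_day.items()}
        if i < 18:
            vol = 2.0 + 0.1 * i  # small-ROI block
        elif i < 27:
            conforming = False  # protocol block
        elif i < 30:
            outcome_day = dict(outcome_day)
            outcome_day["OS"] = r.entry_day + 40  # early-event block
        out.append(replace(r, pretx_volume_cm3=vol, protocol_conforming=conforming,
                           outcome_day=outcome_day,
                           event=dict(r.event, OS=1) if 27 <= i < 30 else r.event))
    return out
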