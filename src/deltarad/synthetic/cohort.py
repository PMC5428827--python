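"""Synthetic longitudinal NSCLC-like cohorts with planted outcome structure.

Clinical factors are drawn from the marginal frequencies of a 107-patient
stage-III cohort (sex, age band, T/N stage, stage group, histology, smoking,
pack-years, performance status, prescription). Event times for the three
endpoints follow an exponential proportional-hazards model whose log hazard
is a stated linear function of planted covariates:

    OS: beta_shape * z(compactness2) + beta_delta * z(latent response) + clinical terms
    DM: beta_shape * z(compactness2) + clinical terms
    LR: beta_delta * z(latent response)

The latent response score r > 0 scales how fast a patient's tumor shrinks and
its texture homogenizes per delivered Gy; a faster-responding tumor here
carries *higher* hazard through beta_delta > 0 (the sign is arbitrary — the
pipeline only needs a recoverable monotone association). Censoring is
independent exponential, calibrated to the configured censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Table-1-like marginal frequencies (107-patient stage III cohort).
CLINICAL_MARGINALS = {
    "sex_male": 62 / 107,
    "age_ge65": 62 / 107,
    "t34": 58 / 107,
    "n23": 83 / 107,
    "stage": {"II": 12 / 107, "IIIa": 44 / 107, "IIIb": 49 / 107, "IV": 2 / 107},
    "histology_squamous": 46 / 107,
    "smoking": {"current": 34 / 107, "former": 64 / 107, "never": 9 / 107},
    "packyears_band": {"0-24": 20 / 107, "25-49": 37 / 107, "50-74": 28 / 107, "75+": 22 / 107},
    "kps_90_100": 52 / 107,
    "dose_gt70": 72 / 107,
}

#: Modest clinical log-hazard effects on OS/DM (zero on LR), so the clinical
#: model has genuine but limited prognostic value.
CLINICAL_EFFECTS = {"t34": 0.35, "sex_male": 0.20, "dose_gt70": -0.25, "age_ge65": 0.15}

#: Baseline median event times (days) at zero log-hazard, and the Weibull
#: shape shared by all endpoints. Shape 1.5 gives an increasing hazard, so
#: pre-landmark (<90 d) events stay rare (~3%), as in a stage-III cohort.
BASELINE_MEDIAN_DAYS = {"OS": 638.0, "DM": 900.0, "LR": 2000.0}
WEIBULL_SHAPE = 1.5

ENDPOINTS = ("OS", "DM", "LR")


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the package's reference study conditions."""

    n_patients: int = 60
    n_weeks: int = 7               # weekly intra-treatment scans (a week-0 scan is added)
    dose_per_week: float = 10.0    # Gy delivered per treatment week
    scanner_fraction: float = 0.5  # proportion of patients on scanner A
    shape_coef: float = 0.8        # OS/DM log-hazard per SD of compactness2
    delta_coef: float = 0.8        # OS/LR log-hazard per SD of latent response
    scanner_offset_hu: float = 20.0  # additive HU offset of scanner B
    censoring_rate: float = 0.2
    clinical_effect_scale: float = 1.0  # multiplies the fixed clinical log-hazards
    missing_scan_rate: float = 0.05
    protocol_nonconforming_rate: float = 0.0
    shrink_rate_per_gy: float = 0.006     # volume log-reduction per Gy at unit response
    homogenize_rate_per_gy: float = 0.008  # texture-amplitude log-reduction per Gy
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise CohortConfigError("n_patients must be >= 2")
        if self.n_weeks < 2:
            raise CohortConfigError("n_weeks must be >= 2")
        for name in ("scanner_fraction", "censoring_rate", "missing_scan_rate",
                     "protocol_nonconforming_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1]")

    def to_dict(self):
        return asdict(self)


@dataclass
class PatientRecord:
    patient: str
    clinical: dict                    # encoded Table-1 factors
    prescription_gy: float            # 66 or 74
    entry_day: int
    scanner: str                      # "A" or "B", constant across this patient's scans
    weeks: list                       # week indices with a scan (0 = pretreatment)
    cumulative_dose: dict             # week -> Gy delivered by that scan
    outcome_day: dict                 # endpoint -> days from entry to event/censor
    event: dict                       # endpoint -> 1 event / 0 censored
    pretx_volume_cm3: float
    protocol_conforming: bool = True
    shape_params: dict = field(default_factory=dict)  # ellipsoid axes etc.


def _ellipsoid_surface_area(a, b, c):
    """Thomsen's approximation for a triaxial ellipsoid (p ~ 1.6075)."""
    p = 1.6075
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def ellipsoid_compactness2(a, b, c):
    v = 4.0 / 3.0 * np.pi * a * b * c
    s = _ellipsoid_surface_area(a, b, c)
    return 36.0 * np.pi * v**2 / s**3


def _draw_categorical(rng, table, size):
    names = list(table.keys())
    probs = np.array(list(table.values()))
    probs = probs / probs.sum()
    return rng.choice(names, size=size, p=probs)


def generate_cohort(config: CohortConfig):
    """Generate the cohort: returns (list of PatientRecord, latent response scores).

    The latent response score is Gamma(4, 1/4)-distributed (mean 1, positive),
    so a zero score — and hence zero image evolution — occurs only if planted
    explicitly. Event times are exponential PH draws per endpoint.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n = cfg.n_patients

    sex = rng.random(n) < CLINICAL_MARGINALS["sex_male"]
    age = rng.random(n) < CLINICAL_MARGINALS["age_ge65"]
    t34 = rng.random(n) < CLINICAL_MARGINALS["t34"]
    n23 = rng.random(n) < CLINICAL_MARGINALS["n23"]
    stage = _draw_categorical(rng, CLINICAL_MARGINALS["stage"], n)
    hist = rng.random(n) < CLINICAL_MARGINALS["histology_squamous"]
    smoking = _draw_categorical(rng, CLINICAL_MARGINALS["smoking"], n)
    packyears = _draw_categorical(rng, CLINICAL_MARGINALS["packyears_band"], n)
    kps = rng.random(n) < CLINICAL_MARGINALS["kps_90_100"]
    dose_gt70 = rng.random(n) < CLINICAL_MARGINALS["dose_gt70"]
    prescription = np.where(dose_gt70, 74.0, 66.0)
    scanner = np.where(rng.random(n) < cfg.scanner_fraction, "A", "B")
    entry_day = rng.integers(0, 365, size=n)

    # latent tumor geometry: baseline volume (cm^3) and ellipsoid axis ratios
    volume_cm3 = np.exp(rng.normal(np.log(30.0), 0.5, size=n))
    ratio_b = rng.uniform(0.45, 1.0, size=n)
    ratio_c = rng.uniform(0.45, 1.0, size=n)
    # semi-axes in mm from volume and ratios
    a3 = 3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi * ratio_b * ratio_c)
    axis_a = a3 ** (1.0 / 3.0)
    c2 = ellipsoid_compactness2(axis_a, axis_a * ratio_b, axis_a * ratio_c)
    z_c2 = (c2 - c2.mean()) / c2.std() if c2.std() > 0 else np.zeros(n)

    score = rng.gamma(4.0, 0.25, size=n)  # mean 1, sd 0.5, strictly positive
    z_score = (score - score.mean()) / score.std() if score.std() > 0 else np.zeros(n)

    clin_lp = cfg.clinical_effect_scale * (
        CLINICAL_EFFECTS["t34"] * t34
        + CLINICAL_EFFECTS["sex_male"] * sex
        + CLINICAL_EFFECTS["dose_gt70"] * dose_gt70
        + CLINICAL_EFFECTS["age_ge65"] * age
    )
    lp = {
        "OS": clin_lp + cfg.shape_coef * z_c2 + cfg.delta_coef * z_score,
        "DM": clin_lp + cfg.shape_coef * z_c2,
        "LR": cfg.delta_coef * z_score,
    }

    records = []
    q = cfg.censoring_rate
    for i in range(n):
        weeks = [0] + [w for w in range(1, cfg.n_weeks + 1)
                       if rng.random() >= cfg.missing_scan_rate or w in (1, cfg.n_weeks)]
        dose = {w: min(w * cfg.dose_per_week, prescription[i]) for w in weeks}
        outcome_day, event = {}, {}
        for ep in ENDPOINTS:
            # Weibull PH: S(t) = exp(-(t/lam)^k * e^lp)
            k = WEIBULL_SHAPE
            lam = BASELINE_MEDIAN_DAYS[ep] / np.log(2) ** (1.0 / k)
            t_event = lam * (rng.exponential(1.0) / np.exp(lp[ep][i])) ** (1.0 / k)
            if q > 0:
                # same-shape Weibull censoring scaled so P(censor) = q, plus a
                # 120-day minimum follow-up (keeps censoring past the landmark)
                lam_c = lam * np.exp(-lp[ep][i] / k) * (q / (1.0 - q)) ** (-1.0 / k)
                t_cens = 120.0 + lam_c * rng.exponential(1.0) ** (1.0 / k)
            else:
                t_cens = np.inf
            tt = min(t_event, t_cens)
            # outcome days are absolute (calendar) days, like trial records
            outcome_day[ep] = int(entry_day[i]) + int(np.ceil(tt)) + 1
            event[ep] = int(t_event <= t_cens)
        records.append(
            PatientRecord(
                patient=f"P{i:03d}",
                clinical={
                    "sex_male": int(sex[i]),
                    "age_ge65": int(age[i]),
                    "t34": int(t34[i]),
                    "n23": int(n23[i]),
                    "stage_iiib_iv": int(stage[i] in ("IIIb", "IV")),
                    "histology_squamous": int(hist[i]),
                    "smoker_current": int(smoking[i] == "current"),
                    "smoker_former": int(smoking[i] == "former"),
                    "packyears_ord": ["0-24", "25-49", "50-74", "75+"].index(packyears[i]),
                    "kps_90_100": int(kps[i]),
                    "dose_gt70": int(dose_gt70[i]),
                },
                prescription_gy=float(prescription[i]),
                entry_day=int(entry_day[i]),
                scanner=str(scanner[i]),
                weeks=weeks,
                cumulative_dose={w: float(d) for w, d in dose.items()},
                outcome_day=outcome_day,
                event=event,
                pretx_volume_cm3=float(volume_cm3[i]),
                protocol_conforming=bool(rng.random() >= cfg.protocol_nonconforming_rate),
                shape_params={
                    "axis_a_mm": float(axis_a[i]),
                    "ratio_b": float(ratio_b[i]),
                    "ratio_c": float(ratio_c[i]),
                    "compactness2_true": float(c2[i]),
                    "z_compactness2": float(z_c2[i]),
                },
            )
        )
    return records, score


CLINICAL_COVARIATES = (
    "sex_male",
    "age_ge65",
    "t34",
    "n23",
    "stage_iiib_iv",
    "histology_squamous",
    "smoker_current",
    "smoker_former",
    "packyears_ord",
    "kps_90_100",
    "dose_gt70",
)


def cohort_frame(records) -> pd.DataFrame:
    """Flatten records into a clinical table (one row per patient)."""
    rows = []
    for r in records:
        row = {"patient": r.patient, "entry_day": r.entry_day, "scanner": r.scanner,
               "prescription_gy": r.prescription_gy,
               "pretx_volume_cm3": r.pretx_volume_cm3,
               "protocol_conforming": int(r.protocol_conforming)}
        row.update(r.clinical)
        for ep in ENDPOINTS:
            row[f"{ep}_day"] = r.outcome_day[ep]
            row[f"{ep}_event"] = r.event[ep]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient")
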