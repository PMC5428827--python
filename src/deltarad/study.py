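"""Replicate-cohort recovery studies over the full modeling pipeline.

Each replicate generates a fresh synthetic cohort (table-level feature
emulation; planted baseline-shape and delta-slope effects at the generator's
reference settings), runs exclusions, the dose-response delta stage, nested
LOOCV covariate selection, model finalization and leave-one-out evaluation,
and records whether the planted covariates were recovered and how the nested
models compare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delta import compute_delta_features, delta_significance
from .survival import (
    build_survival_table,
    concordance_index,
    finalize_models,
    loocv_predict,
    median_split_km,
    nested_loocv_selection,
)
from .synthetic import CLINICAL_COVARIATES, CohortConfig, generate_cohort_tables
from .synthetic.tables import EVOLVING_FEATURES

#: The planted pretreatment covariate is the shape score (compactness2). The
#: planted longitudinal effect acts through the shared latent response score,
#: so *every* evolving feature's delta covariates are planted proxies of it;
#: recovery means any of them crosses the selection threshold.
PLANTED_PRETX = "compactness2_Week0"
PLANTED_DELTA_FAMILY = tuple(
    f"{feat}_{s}"
    for feat in EVOLVING_FEATURES + ("volume_cm3",)
    for s in ("netPercentChange", "Slope", "WeekLast")
)


def _zscore(df):
    out = df.astype(float)
    sd = out.std(ddof=0)
    return (out - out.mean()) / sd.replace(0.0, 1.0)


@dataclass
class ReplicateResult:
    n_patients: int
    pretx_frequency: dict      # pretx covariate -> selection fraction
    delta_frequency: dict
    c_index: dict              # level -> c (None if the level has no covariates)
    logrank_p: dict
    planted_pretx_selected: bool
    planted_delta_selected: bool


def run_replicate(seed: int, n_patients: int = 60, endpoint: str = "OS",
                  delta_alpha: float = 0.05, **cohort_kwargs) -> ReplicateResult:
    """One synthetic cohort through delta screen, nested LOOCV and evaluation."""
    cfg = CohortConfig(n_patients=n_patients, seed=seed, **cohort_kwargs)
    records, clinical, pretx_raw, longitudinal = generate_cohort_tables(cfg)
    surv = build_survival_table(clinical, endpoint)

    features = [c for c in longitudinal.columns if c not in ("patient", "week", "dose_Gy")]
    sig = delta_significance(longitudinal, features, alpha=delta_alpha)
    passing = list(sig.index[sig["passed"]])
    deltas = compute_delta_features(longitudinal, passing)

    pretx = _zscore(pretx_raw).fillna(0.0)
    pretx.columns = [f"{c}_Week0" for c in pretx.columns]
    dz = _zscore(deltas).fillna(0.0)
    clin_cols = [c for c in CLINICAL_COVARIATES if c in clinical.columns]
    X = pd.concat([clinical[clin_cols], pretx, dz], axis=1).loc[surv.index]

    freq = nested_loocv_selection(surv, X, pretx.loc[surv.index], dz.loc[surv.index],
                                  clinical_covariates=clin_cols)
    total = freq.total
    pre_f = {c: n / total for c, n in freq.counts[2].items()}
    del_f = {c: n / total for c, n in freq.counts[3].items()}

    models = finalize_models(freq, surv, X)
    covariate_sets = {lvl: list(m.covariates) for lvl, m in models.items()}
    preds = loocv_predict(surv, X, covariate_sets)
    c_index, logrank_p = {}, {}
    for lvl in (1, 2, 3):
        if not covariate_sets[lvl]:
            c_index[lvl], logrank_p[lvl] = None, None
            continue
        p = preds[lvl].dropna()
        c_index[lvl] = concordance_index(p, surv.loc[p.index, "time"],
                                         surv.loc[p.index, "event"])
        try:
            logrank_p[lvl] = median_split_km(p, surv.loc[p.index]).logrank_p
        except ValueError:
            logrank_p[lvl] = None

    return ReplicateResult(
        n_patients=len(surv),
        pretx_frequency=pre_f,
        delta_frequency=del_f,
        c_index=c_index,
        logrank_p=logrank_p,
        planted_pretx_selected=pre_f.get(PLANTED_PRETX, 0.0) > 0.5,
        planted_delta_selected=any(del_f.get(c, 0.0) > 0.5 for c in PLANTED_DELTA_FAMILY),
    )


def replicate_study(n_replicates: int = 25, seed: int = 0, n_patients: int = 60,
                    **cohort_kwargs) -> dict:
    """Planted-effect recovery summary over replicate cohorts.

    Returns fractions over replicates: planted pretreatment / delta covariates
    exceeding the 50% LOOCV selection threshold, level-2 c-index beating
    level 1, and the delta-including model stratifying Kaplan-Meier risk
    groups at log-rank p < 0.05; plus the mean c-index per level.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    results = [run_replicate(int(s), n_patients, **cohort_kwargs) for s in seeds]
    c2_beats_c1 = [
        r.c_index[2] is not None and r.c_index[1] is not None and r.c_index[2] > r.c_index[1]
        for r in results
    ]
    delta_km_sig = []
    for r in results:
        p = r.logrank_p[3] if r.logrank_p[3] is not None else r.logrank_p[2]
        delta_km_sig.append(p is not None and p < 0.05)
    mean_c = {
        lvl: float(np.mean([r.c_index[lvl] for r in results if r.c_index[lvl] is not None]))
        for lvl in (1, 2, 3)
    }
    return {
        "n_replicates": n_replicates,
        "frac_planted_pretx_selected": float(np.mean([r.planted_pretx_selected for r in results])),
        "frac_planted_delta_selected": float(np.mean([r.planted_delta_selected for r in results])),
        "frac_c2_gt_c1": float(np.mean(c2_beats_c1)),
        "frac_delta_km_significant": float(np.mean(delta_km_sig)),
        "mean_c_index": mean_c,
        "results": results,
    }


def lmm_type_i_error(n_replicates: int = 500, seed: int = 0, n_patients: int = 30,
                     n_weeks: int = 7, alpha: float = 0.05,
                     intercept_sd: float = 1.0, noise_sd: float = 1.0) -> float:
    """Monte-Carlo type-I error of the dose-term LRT in the random-intercept model.

    Data are generated under the null (no dose effect): a patient intercept
    with the given SD plus iid noise over `n_weeks` weekly doses.
    """
    from .delta import fit_dose_lmm

    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]).spawn(1)[0])
    doses = np.arange(1, n_weeks + 1) * 10.0
    rejections = 0
    for _ in range(n_replicates):
        rows = []
        for i in range(n_patients):
            b = rng.normal(0.0, intercept_sd)
            for d in doses:
                rows.append({"patient": i, "dose_Gy": d,
                             "f": b + rng.normal(0.0, noise_sd)})
        p = fit_dose_lmm(pd.DataFrame(rows), "f")
        rejections += p < alpha
    return rejections / n_replicates


def null_study(n_replicates: int = 10, seed: int = 0, n_patients: int = 60) -> dict:
    """False-discovery control: cohorts with all planted effects zeroed.

    With ~18 noise candidates, *some* covariate wins a full-cohort AIC admit
    in most cohorts and then propagates through the highly correlated LOOCV
    iterations — that is a property of the selection procedure, not a false
    discovery of a particular feature. The discovery-control statement is
    therefore per covariate: each individual radiomics covariate should stay
    below the 50% threshold in the large majority of replicate cohorts.

    Returns the per-covariate fraction of replicates over 50%, the mean
    below-50% fraction across covariates, and (for context) the fraction of
    replicates where any covariate crossed.
    """
    seeds = np.random.SeedSequence([seed, 1]).generate_state(n_replicates) % (2**31)
    over = {}
    any_flags = []
    for s in seeds:
        r = run_replicate(int(s), n_patients, shape_coef=0.0, delta_coef=0.0,
                          clinical_effect_scale=0.0)
        freqs = {**r.pretx_frequency, **r.delta_frequency}
        for cov, f in freqs.items():
            over.setdefault(cov, 0)
            over[cov] += f > 0.5
        any_flags.append(any(f > 0.5 for f in freqs.values()))
    frac_over = {cov: cnt / n_replicates for cov, cnt in over.items()}
    return {
        "n_replicates": n_replicates,
        "frac_over_50_per_covariate": frac_over,
        "mean_frac_below_50": float(np.mean([1.0 - v for v in frac_over.values()])),
        "frac_any_radiomics_over_50": float(np.mean(any_flags)),
    }
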