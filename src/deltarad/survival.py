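"""Landmark survival tables and the nested LOOCV model-building procedure.

Model levels are nested by construction: level 1 is a stepwise-AIC Cox model
over clinical factors; level 2 adds pretreatment radiomics candidates with
level 1's selections forced; level 3 adds delta-radiomics candidates with
level 2's covariates forced. The whole three-level search runs inside a
leave-one-out loop, covariates selected in more than half of the iterations
(strict) are retained, final models are refit on everyone, and a second
leave-one-out pass with frozen covariate sets produces unbiased per-patient
risk predictions for the concordance index and median-split Kaplan-Meier
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, fit_cox


# ---------------------------------------------------------------- survival table

def build_survival_table(clinical: pd.DataFrame, endpoint: str,
                         landmark_days: int = 90) -> pd.DataFrame:
    """time = outcome day - entry day - landmark; event indicator per patient.

    Pre-landmark events must have been excluded upstream; a non-positive time
    is an error here.
    """
    day = clinical[f"{endpoint}_day"].to_numpy(dtype=float)
    if "entry_day" in clinical.columns:
        entry = clinical["entry_day"].to_numpy(dtype=float)
    else:
        entry = np.zeros_like(day)
    time = day - entry - landmark_days
    if (time <= 0).any():
        bad = clinical.index[time <= 0].tolist()
        raise ValueError(f"non-positive landmark-adjusted time for {bad}; exclusions missing")
    return pd.DataFrame(
        {"time": time, "event": clinical[f"{endpoint}_event"].to_numpy(dtype=int)},
        index=clinical.index,
    )


# ---------------------------------------------------------------- stepwise AIC

def _fit(X: pd.DataFrame, surv: pd.DataFrame, cols) -> CoxFit:
    return fit_cox(X[list(cols)].to_numpy(dtype=float), surv["time"].to_numpy(),
                   surv["event"].to_numpy(), covariates=tuple(cols))


def stepwise_aic_cox(X: pd.DataFrame, surv: pd.DataFrame, candidates,
                     forced=()) -> CoxFit:
    """Bidirectional stepwise AIC starting from the full scope model.

    At each step the single add/drop move with the largest AIC decrease is
    applied; forced covariates are never droppable. Ties on AIC prefer drops
    over adds, then the order covariates appear in `candidates`/`forced`
    (deterministic). Moves whose Cox fit fails or diverges are skipped.
    """
    from .cox import PreparedCox

    forced = [c for c in forced]
    candidates = [c for c in candidates if c not in forced]
    current = forced + candidates
    all_cols = forced + candidates
    rank = {c: i for i, c in enumerate(all_cols)}
    prep = PreparedCox(X[all_cols].to_numpy(dtype=float),
                       surv["time"].to_numpy(), surv["event"].to_numpy())

    def try_fit(cols, warm=None):
        beta0 = None
        if warm is not None:
            # warm start from the incumbent: reuse shared coefficients
            lookup = dict(zip(warm.covariates, warm.coef))
            beta0 = np.array([lookup.get(c, 0.0) for c in cols])
        try:
            f = prep.fit([rank[c] for c in cols], covariates=tuple(cols), beta0=beta0)
        except Exception:
            return None
        if not f.converged or f.diverged or not np.isfinite(f.loglik):
            return None
        return f

    best = try_fit(current)
    if best is None:  # fall back: forced-only model must exist
        current = list(forced)
        best = _fit(X, surv, current)
    while True:
        moves = []  # (aic, prefer_add, rank, cols, fit)
        for c in current:
            if c in forced:
                continue
            cols = [x for x in current if x != c]
            f = try_fit(cols, warm=best)
            if f is not None:
                moves.append((f.aic, 0, rank[c], cols, f))
        for c in candidates:
            if c in current:
                continue
            cols = current + [c]
            f = try_fit(cols, warm=best)
            if f is not None:
                moves.append((f.aic, 1, rank[c], cols, f))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        if moves[0][0] < best.aic - 1e-10:
            current, best = moves[0][3], moves[0][4]
        else:
            break
    return best


# ---------------------------------------------------------------- nested LOOCV

@dataclass
class SelectionFrequencyTable:
    counts: dict          # level -> {covariate: count of LOOCV iterations}
    total: int
    forced_base: tuple = ()

    def frame(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "covariate": cov, "count": cnt, "total": self.total,
             "frequency": cnt / self.total}
            for lvl, d in self.counts.items()
            for cov, cnt in d.items()
        ]
        return pd.DataFrame(rows)


def nested_loocv_selection(surv: pd.DataFrame, clinical: pd.DataFrame,
                           pretx: pd.DataFrame, delta: pd.DataFrame,
                           clinical_covariates=None) -> SelectionFrequencyTable:
    """Leave-one-out covariate-selection frequencies for the three model levels.

    All tables must be aligned on patients. An iteration whose fit fails
    records no selections at the failing level.
    """
    if clinical_covariates is None:
        clinical_covariates = list(clinical.columns)
    X = pd.concat([clinical[clinical_covariates], pretx, delta], axis=1)
    X = X.loc[surv.index]
    pretx_cands = [c for c in pretx.columns]
    delta_cands = [c for c in delta.columns]
    counts = {1: {c: 0 for c in clinical_covariates},
              2: {c: 0 for c in pretx_cands},
              3: {c: 0 for c in delta_cands}}
    patients = list(surv.index)
    for left_out in patients:
        keep = [p for p in patients if p != left_out]
        Xi, si = X.loc[keep], surv.loc[keep]
        try:
            m1 = stepwise_aic_cox(Xi, si, clinical_covariates)
            sel1 = list(m1.covariates)
            for c in sel1:
                counts[1][c] += 1
            m2 = stepwise_aic_cox(Xi, si, pretx_cands, forced=sel1)
            sel2 = list(m2.covariates)
            for c in sel2:
                if c in counts[2]:
                    counts[2][c] += 1
            m3 = stepwise_aic_cox(Xi, si, delta_cands, forced=sel2)
            for c in m3.covariates:
                if c in counts[3]:
                    counts[3][c] += 1
        except Exception:
            continue
    return SelectionFrequencyTable(counts, len(patients))


def finalize_models(freq: SelectionFrequencyTable, surv: pd.DataFrame,
                    covariate_table: pd.DataFrame, threshold: float = 0.5) -> dict:
    """Final nested models from the high-performing covariates.

    Per level, covariates selected in strictly more than `threshold` of the
    iterations are kept (cumulatively across levels, preserving nesting) and
    the model is refit on all patients; a level that adds nothing reuses the
    previous level's covariate set (the null model if nothing was ever kept).
    Returns {level: CoxFit}.
    """
    kept_by_level, running = {}, []
    for lvl in (1, 2, 3):
        new = [c for c, cnt in freq.counts[lvl].items() if cnt / freq.total > threshold]
        running = running + [c for c in new if c not in running]
        kept_by_level[lvl] = list(running)
    models = {}
    for lvl, cols in kept_by_level.items():
        models[lvl] = _fit(covariate_table, surv, cols)
    return models


def likelihood_ratio_test(small: CoxFit, large: CoxFit) -> float:
    """Chi-squared LRT p-value between nested Cox fits on the same data."""
    if not set(small.covariates) <= set(large.covariates):
        raise ValueError("models are not nested")
    df = len(large.coef) - len(small.coef)
    if df == 0:
        return 1.0 if small.covariates == large.covariates else np.nan
    stat = max(0.0, 2.0 * (large.loglik - small.loglik))
    return float(stats.chi2.sf(stat, df=df))


# ---------------------------------------------------------------- evaluation

def loocv_predict(surv: pd.DataFrame, covariate_table: pd.DataFrame,
                  covariate_sets: dict) -> pd.DataFrame:
    """Unbiased leave-one-out linear-predictor risk scores per model level.

    Covariate sets are frozen; only coefficients are refit on each iteration.
    A failed refit leaves that prediction missing. An empty covariate set
    yields identically-zero predictions (the null model).
    """
    patients = list(surv.index)
    out = pd.DataFrame(index=surv.index, columns=list(covariate_sets), dtype=float)
    for lvl, cols in covariate_sets.items():
        cols = list(cols)
        if not cols:
            out[lvl] = 0.0
            continue
        for left_out in patients:
            keep = [p for p in patients if p != left_out]
            try:
                f = _fit(covariate_table.loc[keep], surv.loc[keep], cols)
                if f.diverged or not f.converged:
                    continue
                out.loc[left_out, lvl] = float(
                    f.predict(covariate_table.loc[[left_out], cols].to_numpy(dtype=float))[0]
                )
            except Exception:
                continue
    return out


def concordance_index(predictions, time, event) -> float:
    """Harrell's c-index for risk scores (higher score = earlier event)."""
    from lifelines.utils import concordance_index as _ci

    predictions = np.asarray(predictions, dtype=float)
    ok = np.isfinite(predictions)
    if ok.sum() < 2:
        raise ValueError("not enough predictions")
    # lifelines scores concordance for *survival-time-like* predictions
    return float(_ci(np.asarray(time)[ok], -predictions[ok], np.asarray(event)[ok]))


@dataclass
class KMStratification:
    high_risk: pd.Index
    low_risk: pd.Index
    logrank_stat: float
    logrank_p: float
    km_high: object = field(repr=False, default=None)
    km_low: object = field(repr=False, default=None)


def median_split_km(predictions: pd.Series, surv: pd.DataFrame) -> KMStratification:
    """Median risk split + Kaplan-Meier curves + two-group log-rank test.

    High risk = prediction strictly above the median; ties at the median go to
    the low-risk stratum. All-identical predictions are an error.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    pred = predictions.astype(float)
    if pred.nunique() <= 1:
        raise ValueError("all predictions identical; stratification undefined")
    med = pred.median()
    hi = pred.index[pred > med]
    lo = pred.index[pred <= med]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("fewer than 2 patients in a stratum")
    sh, sl = surv.loc[hi], surv.loc[lo]
    res = logrank_test(sh["time"], sl["time"], sh["event"], sl["event"])
    kmh = KaplanMeierFitter().fit(sh["time"], sh["event"], label="high risk")
    kml = KaplanMeierFitter().fit(sl["time"], sl["event"], label="low risk")
    return KMStratification(hi, lo, float(res.test_statistic), float(res.p_value), kmh, kml)
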