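"""Dose-response screening and per-patient delta-radiomics features.

Stage one asks, per feature, whether the weekly values change with delivered
dose: a linear mixed-effects model

    Feature_w = b0 + b1 * Dose_w + u_patient + noise,   u ~ N(0, tau^2)

is fitted by maximum likelihood and compared by likelihood ratio (chi^2, 1 df)
to the nested model without the dose term; p-values across features are
Benjamini-Hochberg corrected. Stage two condenses each surviving feature into
three per-patient summaries:

    relativeNetChange = (F_weekFinal - F_week1) / F_week1
    Slope             = OLS slope of F on cumulative dose (feature units / Gy)
    WeekLast          = F_weekFinal

"Week 1" is the first weekly intra-treatment scan — distinct from the
pretreatment scan ("Week0"), which supplies the pretreatment covariates.
One-sample two-tailed t-tests (BH-corrected) check that the cohort's net
changes and slopes differ from zero; a feature passes the delta stage only if
the LMM LRT and both t-tests are BH-significant at 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


def fit_dose_lmm(rows: pd.DataFrame, feature: str, dose_col: str = "dose_Gy",
                 patient_col: str = "patient") -> float:
    """LRT p-value for the dose term in a random-intercept mixed model (ML fit).

    A boundary fit (zero between-patient variance) is still a valid ML
    solution for the LRT, so convergence warnings are tolerated.
    """
    df = rows[[patient_col, dose_col, feature]].dropna()
    if df[patient_col].nunique() < 2:
        raise ValueError("need >= 2 patients")
    y = df[feature].to_numpy(dtype=float)
    d = df[dose_col].to_numpy(dtype=float)
    g = df[patient_col].to_numpy()
    if np.std(y) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = MixedLM(y, np.column_stack([np.ones_like(d), d]), groups=g).fit(reml=False)
        null = MixedLM(y, np.ones((len(d), 1)), groups=g).fit(reml=False)
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    return float(stats.chi2.sf(stat, df=1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compute_delta_features(longitudinal: pd.DataFrame, features,
                           dose_col: str = "dose_Gy",
                           patient_col: str = "patient",
                           week_col: str = "week") -> pd.DataFrame:
    """Per-patient delta summaries for each feature.

    Output columns: "<feature>_netPercentChange", "<feature>_Slope",
    "<feature>_WeekLast". Missing weeks are simply absent from the slope fit;
    a zero week-1 value flags the net change as missing, fewer than two weeks
    flags the slope.
    """
    rows = []
    for pid, grp in longitudinal.groupby(patient_col, sort=False):
        grp = grp.sort_values(week_col)
        row = {"patient": pid}
        for feat in features:
            sub = grp[[dose_col, feat]].dropna()
            vals = sub[feat].to_numpy(dtype=float)
            dose = sub[dose_col].to_numpy(dtype=float)
            if len(vals) == 0:
                row[f"{feat}_netPercentChange"] = np.nan
                row[f"{feat}_Slope"] = np.nan
                row[f"{feat}_WeekLast"] = np.nan
                continue
            first, last = vals[0], vals[-1]
            row[f"{feat}_netPercentChange"] = (last - first) / first if first != 0 else np.nan
            if len(vals) >= 2 and np.ptp(dose) > 0:
                row[f"{feat}_Slope"] = float(np.polyfit(dose, vals, 1)[0])
            else:
                row[f"{feat}_Slope"] = np.nan
            row[f"{feat}_WeekLast"] = last
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient")


def delta_significance(longitudinal: pd.DataFrame, features, alpha: float = 0.05,
                       **kw) -> pd.DataFrame:
    """Full delta-stage decision per feature.

    Returns a frame indexed by feature with the LMM LRT p, the t-test p-values
    on net change and slope, their BH-adjusted versions (each family adjusted
    across features) and a boolean "passed".
    """
    features = list(features)
    lmm_p = np.array([fit_dose_lmm(longitudinal, f, **kw) for f in features])
    deltas = compute_delta_features(longitudinal, features, **kw)

    def _t_p(col):
        v = deltas[col].dropna().to_numpy()
        if len(v) < 2:
            return 1.0
        if np.std(v) == 0:
            return 0.0 if v.mean() != 0 else 1.0
        return float(stats.ttest_1samp(v, 0.0).pvalue)

    net_p = np.array([_t_p(f"{f}_netPercentChange") for f in features])
    slope_p = np.array([_t_p(f"{f}_Slope") for f in features])
    out = pd.DataFrame(
        {
            "lmm_p": lmm_p,
            "lmm_p_bh": bh_adjust(lmm_p),
            "net_change_p": net_p,
            "net_change_p_bh": bh_adjust(net_p),
            "slope_p": slope_p,
            "slope_p_bh": bh_adjust(slope_p),
        },
        index=pd.Index(features, name="feature"),
    )
    out["passed"] = (
        (out["lmm_p_bh"] < alpha) & (out["net_change_p_bh"] < alpha) & (out["slope_p_bh"] < alpha)
    )
    return out
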