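"""Feature-specific preprocessing selection.

Three screens run on pretreatment data for every (feature, variant) pair:
a univariate Cox likelihood-ratio screen for overall survival, a Wilcoxon
rank-sum scanner-dependence screen on first-week values, and Spearman
correlation with gross tumor volume as the tie-break. A variant survives if
it is prognostic (Cox p < 0.10) and scanner-independent (rank-sum p > 0.05);
among survivors the one least correlated (in |rho|) with volume is kept, and
a feature with no surviving variant is dropped. No multiplicity correction is
applied at this stage: the p-values steer selection, they are not hypothesis
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import cox_lrt_pvalue
from .preprocessing import VARIANT_ORDER


@dataclass
class ScreenResult:
    feature: str
    variant: str
    cox_p: float
    scanner_p: float
    volume_rho: float


def univariate_cox_screen(features: pd.DataFrame, time, event) -> pd.Series:
    """Likelihood-ratio p per feature column (features z-scored before fitting).

    Constant or divergent features get p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        sd = np.nanstd(x)
        if sd == 0 or not np.isfinite(x).all():
            out[col] = 1.0
            continue
        z = (x - np.nanmean(x)) / sd
        out[col] = cox_lrt_pvalue(z, time, event)
    return pd.Series(out, name="cox_p")


def scanner_dependence_test(values, scanner_labels) -> float:
    """Two-sided Wilcoxon rank-sum p for scanner A vs B first-week values.

    Exact distribution for combined n <= 20, normal approximation with tie
    correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(scanner_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly two scanner groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty scanner group")
    method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def volume_correlation(values, volumes) -> float:
    """Spearman rank correlation with tumor volume; constant input yields 0."""
    values = np.asarray(values, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 patients")
    if np.std(values) == 0 or np.std(volumes) == 0:
        return 0.0
    rho = stats.spearmanr(values, volumes).statistic
    return float(rho)


def screen_feature_table(pretx: pd.DataFrame, week1: pd.DataFrame, scanner_labels,
                         volumes, time, event,
                         feature_variants: dict) -> pd.DataFrame:
    """Run all three screens; returns one row per (feature, variant).

    feature_variants: {feature: [variant ids]} — shape features list a single
    pseudo-variant. Columns in `pretx`/`week1` are "<feature>@<variant>" (or
    the bare name for single-variant features).
    """
    rows = []
    cox_p = univariate_cox_screen(pretx, time, event)
    for feat, variants in feature_variants.items():
        for vid in variants:
            col = f"{feat}@{vid}" if f"{feat}@{vid}" in pretx.columns else feat
            sp = scanner_dependence_test(week1[col].to_numpy(), scanner_labels)
            rho = volume_correlation(pretx[col].to_numpy(), volumes)
            rows.append(ScreenResult(feat, vid, float(cox_p[col]), sp, rho))
    return pd.DataFrame([r.__dict__ for r in rows])


def select_variants(screen: pd.DataFrame, cox_alpha: float = 0.10,
                    scanner_alpha: float = 0.05) -> dict:
    """Pick one preprocessing variant per surviving feature.

    Keep variants with cox_p < cox_alpha and scanner_p > scanner_alpha; drop
    the feature if none survive; among several survivors take the smallest
    |volume rho|, ties broken by the fixed variant order.
    """
    order = {v: i for i, v in enumerate(VARIANT_ORDER)}
    selected = {}
    for feat, grp in screen.groupby("feature", sort=False):
        ok = grp[(grp["cox_p"] < cox_alpha) & (grp["scanner_p"] > scanner_alpha)]
        if ok.empty:
            continue
        ok = ok.assign(abs_rho=ok["volume_rho"].abs(),
                       vorder=ok["variant"].map(lambda v: order.get(v, 99)))
        best = ok.sort_values(["abs_rho", "vorder"], kind="stable").iloc[0]
        selected[feat] = best["variant"]
    return selected
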