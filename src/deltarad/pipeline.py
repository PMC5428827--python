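"""End-to-end pipeline: simulate -> exclude -> extract -> screen -> delta ->
model -> evaluate, with per-stage CSV caching and a run manifest.

Two simulation modes share the whole downstream path:
  * "image": voxel image series are generated per patient, features are
    extracted under all four preprocessing variants, and the feature-specific
    variant screen runs (screening mode, 49*4 + 16 combinations).
  * "table": the feature tables are emulated directly at the statistical
    level (single variant, no variant screen) — orders of magnitude faster,
    used for replicate-level studies.

Each stage writes its outputs under the run directory and can be re-run from
the cached outputs of earlier stages; the single global seed is expanded into
per-stage substreams so a re-run of any stage reproduces its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .delta import compute_delta_features, delta_significance
from .features.extract import extract_all
from .features.registry import SHAPE_FEATURES
from .selection import screen_feature_table, select_variants
from .survival import (
    build_survival_table,
    concordance_index,
    finalize_models,
    likelihood_ratio_test,
    loocv_predict,
    median_split_km,
    nested_loocv_selection,
)
from .synthetic import (
    CLINICAL_COVARIATES,
    CohortConfig,
    apply_exclusions,
    cohort_frame,
    generate_cohort,
    generate_cohort_tables,
    generate_image_series,
)
from .synthetic.images import SPACING, save_series_nifti

STAGES = ("simulate", "extract", "screen", "delta", "model", "evaluate")


@dataclass
class PipelineConfig:
    mode: str = "table"              # "table" or "image"
    endpoint: str = "OS"
    seed: int = 0
    landmark_days: int = 90
    cox_alpha: float = 0.10
    scanner_alpha: float = 0.05
    delta_alpha: float = 0.05
    selection_threshold: float = 0.5
    min_volume_cm3: float = 5.0
    write_nifti: bool = False        # image mode: persist volumes for debugging
    km_plot: bool = False
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**{"seed": self.seed, **self.cohort})

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _read(outdir, name):
    p = Path(outdir) / name
    if not p.exists():
        raise StageError(name.split("_")[0], f"missing cached input {p}")
    if name.endswith(".json"):
        return json.loads(p.read_text())
    return pd.read_csv(p)


def _manifest_update(outdir, stage, outputs, cfg):
    mpath = Path(outdir) / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": cfg.hash(), "seed": cfg.seed, "config": asdict(cfg),
        "stages": {}, "outputs": [],
    }
    manifest["stages"][stage] = {"completed_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    manifest["outputs"] = sorted(set(manifest["outputs"]) | {str(o) for o in outputs})
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest


# ------------------------------------------------------------------ stages

def stage_simulate(cfg: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ccfg = cfg.cohort_config()
    outputs = [outdir / "config_echo.yaml", outdir / "feature_registry.csv"]
    with open(outputs[0], "w") as fh:
        yaml.safe_dump({"pipeline": asdict(cfg), "cohort": ccfg.to_dict()}, fh)
    from .features.registry import registry_frame

    registry_frame().to_csv(outputs[1], index=False)

    if cfg.mode == "table":
        records, clinical, pretx, longitudinal = generate_cohort_tables(ccfg, exclusions=False)
        clinical.to_csv(outdir / "clinical.csv")
        pretx.to_csv(outdir / "pretx_features_raw.csv")
        longitudinal.to_csv(outdir / "longitudinal_raw.csv", index=False)
        outputs += [outdir / "clinical.csv", outdir / "pretx_features_raw.csv",
                    outdir / "longitudinal_raw.csv"]
    else:
        records, scores = generate_cohort(ccfg)
        clinical = cohort_frame(records)
        clinical.to_csv(outdir / "clinical.csv")
        outputs.append(outdir / "clinical.csv")
        schedule = pd.DataFrame(
            [{"patient": r.patient, "week": w, "dose_Gy": r.cumulative_dose[w]}
             for r in records for w in r.weeks]
        )
        schedule.to_csv(outdir / "scan_schedule.csv", index=False)
        outputs.append(outdir / "scan_schedule.csv")
        series = {}
        for rec, sc in zip(records, scores):
            s = generate_image_series(rec, sc, ccfg)
            series[rec.patient] = s
            if cfg.write_nifti:
                outputs += save_series_nifti(s, outdir / "images")
        # kept in memory for the extract stage within the same run
        stage_simulate._series_cache = series  # type: ignore[attr-defined]
    _manifest_update(outdir, "simulate", outputs, cfg)
    return {"clinical": clinical}


def stage_exclude_and_extract(cfg: PipelineConfig, outdir) -> dict:
    """Apply exclusions and produce the (screening or selected-mode) tables."""
    outdir = Path(outdir)
    clinical = _read(outdir, "clinical.csv").set_index("patient")
    ccfg = cfg.cohort_config()

    # exclusions on the clinical table
    vol = clinical["pretx_volume_cm3"]
    if vol.isna().any():
        raise StageError("extract", "missing pretreatment ROI volume")
    small = vol < cfg.min_volume_cm3
    protocol = (clinical["protocol_conforming"] == 0) & ~small
    day_cols = [c for c in clinical.columns if c.endswith("_day")]
    early = pd.Series(False, index=clinical.index)
    for ep in ("OS", "DM", "LR"):
        early |= (clinical[f"{ep}_event"] == 1) & (
            clinical[f"{ep}_day"] - clinical["entry_day"] <= cfg.landmark_days
        )
    early &= ~small & ~protocol
    tally = pd.DataFrame(
        {"reason": ["small_volume", "protocol", "early_event", "retained"],
         "count": [int(small.sum()), int(protocol.sum()), int(early.sum()),
                   int((~(small | protocol | early)).sum())]}
    )
    tally.to_csv(outdir / "exclusion_tally.csv", index=False)
    keep = clinical.index[~(small | protocol | early)]
    clinical.loc[keep].to_csv(outdir / "clinical_included.csv")

    if cfg.mode == "table":
        pretx = _read(outdir, "pretx_features_raw.csv").set_index("patient").loc[keep]
        longitudinal = _read(outdir, "longitudinal_raw.csv")
        longitudinal = longitudinal[longitudinal["patient"].isin(keep)]
    else:
        series = getattr(stage_simulate, "_series_cache", None)
        if series is None:
            raise StageError("extract", "image series unavailable; re-run simulate in-process")
        schedule = _read(outdir, "scan_schedule.csv")
        dose = {(r.patient, int(r.week)): float(r.dose_Gy) for r in schedule.itertuples()}
        spacing = SPACING
        by_patient = {}
        for pid in keep:
            s = series[pid]
            by_patient[pid] = [(w, img, msk) for w, img, msk in zip(s.weeks, s.images, s.masks)]
        table = extract_all(by_patient, spacing, dose_by_patient_week=dose)
        table.to_csv(outdir / "features_screening.csv", index=False)
        pre = table[table["week"] == 0].set_index("patient")
        pretx = pre
        longitudinal = table[table["week"] >= 1]
    pretx.to_csv(outdir / "pretx_features.csv")
    longitudinal.to_csv(outdir / "longitudinal_features.csv", index=False)
    _manifest_update(outdir, "extract",
                     [outdir / n for n in ("exclusion_tally.csv", "clinical_included.csv",
                                           "pretx_features.csv", "longitudinal_features.csv")], cfg)
    return {"clinical": clinical.loc[keep], "pretx": pretx, "longitudinal": longitudinal,
            "tally": tally}


def stage_screen(cfg: PipelineConfig, outdir) -> dict:
    """Feature-specific preprocessing selection (image mode only)."""
    outdir = Path(outdir)
    clinical = _read(outdir, "clinical_included.csv").set_index("patient")
    pretx = _read(outdir, "pretx_features.csv").set_index("patient")
    if cfg.mode == "table":
        # single-variant tables: every feature column is its own selection
        skip = {"week", "dose_Gy", "missing"}
        selected = {c: "raw" for c in pretx.columns if c not in skip}
        manifest = pd.DataFrame({"feature": list(selected), "variant": list(selected.values())})
        manifest.to_csv(outdir / "selected_features.csv", index=False)
        _manifest_update(outdir, "screen", [outdir / "selected_features.csv"], cfg)
        return {"selected": selected}

    surv = build_survival_table(clinical, "OS", cfg.landmark_days)
    longitudinal = _read(outdir, "longitudinal_features.csv")
    week1 = longitudinal[longitudinal["week"] == longitudinal["week"].min()].set_index("patient")
    scanner = clinical.loc[week1.index, "scanner"].to_numpy()
    volumes = pretx["volume_cm3"].to_numpy()

    feature_variants = {}
    for col in pretx.columns:
        if "@" in col:
            feat, vid = col.split("@", 1)
            feature_variants.setdefault(feat, []).append(vid)
    for feat in SHAPE_FEATURES:
        if feat in pretx.columns:
            feature_variants[feat] = ["raw"]

    feat_cols = [c for c in pretx.columns if "@" in c or c in SHAPE_FEATURES]
    screen = screen_feature_table(pretx[feat_cols], week1, scanner, volumes,
                                  surv["time"], surv["event"], feature_variants)
    screen.to_csv(outdir / "screen_results.csv", index=False)
    selected = select_variants(screen, cfg.cox_alpha, cfg.scanner_alpha)
    pd.DataFrame({"feature": list(selected), "variant": list(selected.values())}).to_csv(
        outdir / "selected_features.csv", index=False)
    _manifest_update(outdir, "screen",
                     [outdir / "screen_results.csv", outdir / "selected_features.csv"], cfg)
    return {"selected": selected, "screen": screen}


def _selected_columns(outdir):
    sel = _read(outdir, "selected_features.csv")
    return dict(zip(sel["feature"], sel["variant"]))


def stage_delta(cfg: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    selected = _selected_columns(outdir)
    longitudinal = _read(outdir, "longitudinal_features.csv")
    cols = []
    for feat, vid in selected.items():
        col = f"{feat}@{vid}" if f"{feat}@{vid}" in longitudinal.columns else feat
        if col in longitudinal.columns and feat not in SHAPE_FEATURES:
            if longitudinal[col].notna().any():
                cols.append((feat, col))
    ren = longitudinal.rename(columns={c: f for f, c in cols})
    features = [f for f, _ in cols if f not in ("volume_cm3",)]
    sig = delta_significance(ren, features, alpha=cfg.delta_alpha)
    sig.to_csv(outdir / "delta_significance.csv")
    passing = list(sig.index[sig["passed"]])
    deltas = compute_delta_features(ren, passing)
    deltas.to_csv(outdir / "delta_features.csv")
    _manifest_update(outdir, "delta",
                     [outdir / "delta_significance.csv", outdir / "delta_features.csv"], cfg)
    return {"significance": sig, "deltas": deltas, "passing": passing}


def _assemble_covariates(cfg, outdir):
    clinical = _read(outdir, "clinical_included.csv").set_index("patient")
    pretx = _read(outdir, "pretx_features.csv").set_index("patient")
    deltas = _read(outdir, "delta_features.csv").set_index("patient")
    selected = _selected_columns(outdir)
    surv = build_survival_table(clinical, cfg.endpoint, cfg.landmark_days)

    clin_cols = [c for c in CLINICAL_COVARIATES if c in clinical.columns]
    pre_cols = {}
    for feat, vid in selected.items():
        col = f"{feat}@{vid}" if f"{feat}@{vid}" in pretx.columns else feat
        if col in pretx.columns:
            pre_cols[f"{feat}_Week0"] = col
    pre = pretx[list(pre_cols.values())].copy()
    pre.columns = list(pre_cols.keys())

    def _z(df):
        out = df.astype(float)
        sd = out.std(ddof=0)
        return (out - out.mean()) / sd.replace(0.0, 1.0)

    pre = _z(pre).fillna(0.0)
    dz = _z(deltas).fillna(0.0)
    X = pd.concat([clinical[clin_cols], pre, dz], axis=1).loc[surv.index]
    return surv, clinical, X, clin_cols, list(pre.columns), list(dz.columns)


def stage_model(cfg: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    surv, clinical, X, clin_cols, pre_cols, delta_cols = _assemble_covariates(cfg, outdir)
    freq = nested_loocv_selection(surv, X, X[pre_cols], X[delta_cols],
                                  clinical_covariates=clin_cols)
    freq.frame().to_csv(outdir / "selection_frequency.csv", index=False)
    models = finalize_models(freq, surv, X, threshold=cfg.selection_threshold)
    rows = []
    for lvl, m in models.items():
        for c, b in zip(m.covariates, m.coef):
            rows.append({"level": lvl, "covariate": c, "coef": b,
                         "loglik": m.loglik, "aic": m.aic})
        if len(m.coef) == 0:
            rows.append({"level": lvl, "covariate": "(null)", "coef": 0.0,
                         "loglik": m.loglik, "aic": m.aic})
    pd.DataFrame(rows).to_csv(outdir / "final_models.csv", index=False)
    lrt = {}
    for a, b in ((1, 2), (2, 3), (1, 3)):
        if set(models[a].covariates) == set(models[b].covariates):
            lrt[f"model{a}_vs_model{b}"] = None
        else:
            lrt[f"model{a}_vs_model{b}"] = likelihood_ratio_test(models[a], models[b])
    (outdir / "model_lrt.json").write_text(json.dumps(lrt, indent=2))
    _manifest_update(outdir, "model",
                     [outdir / n for n in ("selection_frequency.csv", "final_models.csv",
                                           "model_lrt.json")], cfg)
    return {"frequency": freq, "models": models, "lrt": lrt}


def stage_evaluate(cfg: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    surv, clinical, X, *_ = _assemble_covariates(cfg, outdir)
    fm = _read(outdir, "final_models.csv")
    covariate_sets = {}
    for lvl in (1, 2, 3):
        cols = fm.loc[(fm["level"] == lvl) & (fm["covariate"] != "(null)"), "covariate"]
        covariate_sets[lvl] = list(cols)
    preds = loocv_predict(surv, X, covariate_sets)
    preds.to_csv(outdir / "predictions.csv")
    results = {}
    for lvl in (1, 2, 3):
        key = f"model{lvl}"
        if not covariate_sets[lvl]:
            results[key] = {"c_index": None, "logrank_p": None, "covariates": []}
            continue
        p = preds[lvl].dropna()
        c = concordance_index(p, surv.loc[p.index, "time"], surv.loc[p.index, "event"])
        try:
            km = median_split_km(p, surv.loc[p.index])
            logrank_p = km.logrank_p
            if cfg.km_plot:
                _km_plot(km, outdir / f"km_model{lvl}.png", cfg.endpoint, lvl)
        except ValueError:
            logrank_p = None
        results[key] = {"c_index": c, "logrank_p": logrank_p,
                        "covariates": covariate_sets[lvl]}
    (outdir / "evaluation.json").write_text(json.dumps(results, indent=2))
    _manifest_update(outdir, "evaluate",
                     [outdir / "predictions.csv", outdir / "evaluation.json"], cfg)
    return {"predictions": preds, "results": results}


def _km_plot(km, path, endpoint, level):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    km.km_high.plot_survival_function(ax=ax)
    km.km_low.plot_survival_function(ax=ax)
    ax.set_xlabel("days from landmark")
    ax.set_ylabel("survival fraction")
    ax.set_title(f"{endpoint} model {level} (log-rank p={km.logrank_p:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order; returns the manifest dict.

    A stage failure is recorded in the manifest and downstream stages do not
    run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    try:
        results["simulate"] = stage_simulate(cfg, outdir)
        results["extract"] = stage_exclude_and_extract(cfg, outdir)
        results["screen"] = stage_screen(cfg, outdir)
        results["delta"] = stage_delta(cfg, outdir)
        results["model"] = stage_model(cfg, outdir)
        results["evaluate"] = stage_evaluate(cfg, outdir)
    except Exception as exc:  # record failure point, re-raise
        mpath = outdir / "manifest.json"
        manifest = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
        manifest["failed_stage"] = {"error": str(exc)}
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest = json.loads((outdir / "manifest.json").read_text())
    results["manifest"] = manifest
    return results
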