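"""Config-driven end-to-end runs: simulate/extract -> harmonize -> delta ->
signatures -> survival -> screening/prediction -> descriptive statistics.

A single global seed is expanded into independent per-stage streams
(``numpy.random.SeedSequence``); every table written carries enough of the
configuration in its manifest for the run to be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import describe, harmonization, prediction, signatures, survival, synthetic
from .io import write_json, write_table
from .radiomics import ExtractionConfig, extract_pair

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | real
    out_dir: str = "pnetrad_run"
    seed: int = 0
    # synthetic mode
    profile: synthetic.CohortProfile = field(default_factory=synthetic.CohortProfile)
    nuisance: synthetic.NuisanceModel = field(
        default_factory=lambda: synthetic.NuisanceModel(
            center_gamma={"C1": 0.0, "C2": 0.8}, center_delta={"C1": 1.0, "C2": 1.4}
        )
    )
    outcome_hazard: float = 0.012  # per month, exponential PH baseline
    outcome_effect: float = 0.7  # log-hazard per unit aggressiveness score
    censoring_window: float = 120.0  # months
    # real mode
    clinical_csv: str | None = None
    image_table_csv: str | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    # analysis settings
    harmonize: bool = True
    n_boot: int = 2000
    n_perm: int = 1000
    n_boot_loco: int = 1000
    k_grid: tuple[int, ...] = (2, 3, 5)
    classifiers: tuple[str, ...] = ("logistic", "random_forest", "gradient_boosting")
    targets: tuple[str, ...] = ("progression", "higher_grade")

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for p in (self.clinical_csv, self.image_table_csv):
                if p is None or not Path(p).exists():
                    raise ValueError(f"real mode requires existing input file, got {p!r}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if key == "profile":
            cfg.profile = synthetic.CohortProfile(**val)
        elif key == "nuisance":
            cfg.nuisance = synthetic.NuisanceModel(**val)
        elif key == "extraction":
            cfg.extraction = ExtractionConfig(**val)
        elif hasattr(cfg, key):
            setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _simulate(cfg: RunConfig, seeds):
    profile = dataclasses.replace(cfg.profile, seed=seeds[0])
    cohort = synthetic.generate_cohort(profile)
    lp = cfg.outcome_effect * synthetic.biology_score(cohort)
    cohort = synthetic.attach_outcomes(
        cohort, lp, baseline_hazard=cfg.outcome_hazard,
        censoring_window=cfg.censoring_window, seed=seeds[1],
    )
    features = synthetic.generate_feature_table(cohort, cfg.nuisance, seed=seeds[2])
    return cohort, features


def _extract_real(cfg: RunConfig):
    from .io import load_nifti

    cohort = pd.read_csv(cfg.clinical_csv)
    table = pd.read_csv(cfg.image_table_csv)
    frames = []
    for _, row in table.iterrows():
        vol, spacing = load_nifti(row["image"])
        les, _ = load_nifti(row["lesion_mask"])
        pan, _ = load_nifti(row["pancreas_mask"])
        frames.append(
            extract_pair(
                vol, les > 0, pan > 0, spacing=spacing, config=cfg.extraction,
                patient_id=str(row["patient_id"]), center=str(row["center"]),
            )
        )
    return cohort, pd.concat(frames, ignore_index=True)


def make_synthetic_inputs(cfg: RunConfig) -> dict:
    """Build the synthetic analysis inputs without writing anything.

    Returns a dict with the cohort, raw and harmonized feature tables, the
    delta table, the signature panel, and the patient-aligned predictor frame
    used by the prediction stage.
    """
    seeds = _stage_seeds(cfg.seed)
    cohort, features = _simulate(cfg, seeds)
    meta_cols = ["patient_id", "roi", "center"]
    feat_cols = [c for c in features.columns if c not in meta_cols]
    if cfg.harmonize:
        harmonized, _ = harmonization.harmonize(features[feat_cols], features["center"])
        features_h = pd.concat([features[meta_cols], harmonized], axis=1)
    else:
        features_h = features
    lesion = features_h[features_h["roi"] == "lesion"].drop(columns=["roi"])
    pancreas = features_h[features_h["roi"] == "pancreas"].drop(columns=["roi"])
    deltas = signatures.delta_features(lesion, pancreas)
    clin = signatures.encode_clinical(cohort)
    panel = signatures.compute_signatures(lesion, deltas, clin)
    return {
        "cohort": cohort,
        "features": features,
        "lesion": lesion,
        "pancreas": pancreas,
        "deltas": deltas,
        "panel": panel,
        "pred_data": _prediction_frame(cohort, panel),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest.

    Any stage failure aborts with the stage name recorded in the manifest and
    partial outputs left on disk.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {"mode": cfg.mode, "seed": cfg.seed, "stage_seeds": seeds, "stages": {}}
    metrics: dict = {}
    stage = "setup"
    try:
        stage = "simulate" if cfg.mode == "synthetic" else "extract"
        if cfg.mode == "synthetic":
            cohort, features = _simulate(cfg, seeds)
        else:
            cohort, features = _extract_real(cfg)
        write_table(cohort, out / "cohort.csv", {"seed": seeds[0], "profile": dataclasses.asdict(cfg.profile)})
        write_table(features, out / "features_raw.csv", {"seed": seeds[2]})
        manifest["stages"][stage] = "ok"

        stage = "balance_check"
        balance = harmonization.balance_check(
            cohort, [c for c in ("age", "ki67", "size_cm", "grade") if c in cohort.columns]
        )
        write_table(balance, out / "balance_check.csv")
        manifest["stages"][stage] = "ok"

        stage = "harmonize"
        meta_cols = ["patient_id", "roi", "center"]
        feat_cols = [c for c in features.columns if c not in meta_cols]
        if cfg.harmonize:
            harmonized, model = harmonization.harmonize(features[feat_cols], features["center"])
            features_h = pd.concat([features[meta_cols], harmonized], axis=1)
            (out / "combat_model.json").write_text(model.to_json())
            manifest["stages"][stage] = "ok"
        else:
            features_h = features.copy()
            manifest["stages"][stage] = "skipped (harmonization disabled: deltas use raw features)"
        write_table(features_h, out / "features_combat.csv")

        stage = "delta"
        lesion = features_h[features_h["roi"] == "lesion"].drop(columns=["roi"])
        pancreas = features_h[features_h["roi"] == "pancreas"].drop(columns=["roi"])
        deltas = signatures.delta_features(lesion, pancreas)
        write_table(deltas.reset_index(), out / "deltas.csv")
        manifest["stages"][stage] = "ok"

        stage = "signatures"
        clin = signatures.encode_clinical(cohort)
        panel = signatures.compute_signatures(lesion, deltas, clin)
        shape_cols = [c for c in lesion.columns if c.startswith("shape_")]
        if len(shape_cols) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pcs, var_frac = signatures.shape_pca(lesion[["patient_id"] + shape_cols])
            panel = panel.join(pcs)
            metrics["shape_pca_variance_explained"] = [float(v) for v in var_frac[:3]]
        write_table(panel.reset_index(), out / "signatures.csv")
        manifest["stages"][stage] = "ok"

        stage = "survival"
        cohort_idx = cohort.set_index("patient_id")
        sig_cols = [c for c in panel.columns if not c.startswith("shape_pc")]
        cox_table = survival.signature_survival_table(
            panel[sig_cols],
            cohort_idx["time_months"].reindex(panel.index),
            cohort_idx["event"].reindex(panel.index),
            n_boot=cfg.n_boot, n_perm=cfg.n_perm, seed=seeds[3],
        )
        write_table(cox_table, out / "cox_table.csv")
        metrics["cox"] = {
            r["signature"]: {"hr_per_sd": r["hr_per_sd"], "p": r["p"], "c_abs": r["c_abs"]}
            for _, r in cox_table.iterrows()
        }
        km_rows = []
        for sig in sig_cols:
            df = pd.DataFrame({
                "s": panel[sig],
                "t": cohort_idx["time_months"].reindex(panel.index),
                "e": cohort_idx["event"].reindex(panel.index),
            }).dropna()
            if df["s"].nunique() < 2 or df["e"].sum() < 1:
                continue
            try:
                low, high = survival.km_median_split(df["s"], df["t"], df["e"], label=sig)
            except ValueError:
                continue
            for res in (low, high):
                for t, s, bl, bh in zip(res.timeline, res.survival, res.band_low, res.band_high):
                    km_rows.append({
                        "signature": sig, "group": res.group, "time": t, "survival": s,
                        "band_low": bl, "band_high": bh, "logrank_p": res.logrank_p,
                    })
        write_table(pd.DataFrame(km_rows), out / "km_curves.csv")
        manifest["stages"][stage] = "ok"

        stage = "prediction"
        pred_data = _prediction_frame(cohort, panel)
        classifiers_all = prediction.DEFAULT_CLASSIFIERS(seeds[4])
        classifiers = {k: v for k, v in classifiers_all.items() if k in cfg.classifiers}
        table_rows, oof_rows, screening_rows = [], [], []
        metrics["prediction"] = {}
        for target in cfg.targets:
            y = _target_vector(cohort, target)
            blocks = prediction.assemble_blocks(target)
            # screening gate: which signatures add to the clinical baseline
            baseline_vars = [v for v in blocks["M0"].variables]
            candidates = pred_data[[v for v in blocks["MA"].variables + blocks["MB"].variables
                                    if v not in baseline_vars]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                screen = prediction.screen_candidates(candidates, pred_data[baseline_vars], y)
            screen["target"] = target
            screening_rows.append(screen)
            for bname, block in blocks.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    results = prediction.nested_cv(
                        block, pred_data, y, classifiers=classifiers,
                        k_grid=cfg.k_grid, seed=seeds[5], n_boot=cfg.n_boot,
                    )
                    best = max(results.values(), key=lambda r: r.auc)
                    loco_auc, loco_ci, _, _ = prediction.loco_cv(
                        block, pred_data, y, cohort["center"].to_numpy(),
                        classifier=classifiers.get("logistic"),
                        k_grid=cfg.k_grid, seed=seeds[6], n_boot=cfg.n_boot_loco,
                    )
                best.loco_auc, best.loco_auc_ci = loco_auc, loco_ci
                table_rows.append({
                    "target": target, "block": bname, "classifier": best.classifier,
                    "auc": best.auc, "auc_ci_low": best.auc_ci[0], "auc_ci_high": best.auc_ci[1],
                    "brier": best.brier, "calib_intercept": best.calib_intercept,
                    "calib_slope": best.calib_slope, "loco_auc": best.loco_auc,
                })
                keep = ~np.isnan(y)
                for pid, yy, pp in zip(cohort.loc[keep, "patient_id"], best.y, best.oof_probabilities):
                    oof_rows.append({"target": target, "block": bname, "patient_id": pid,
                                     "y": int(yy), "oof_probability": float(pp)})
                metrics["prediction"][f"{target}:{bname}"] = {
                    "auc": best.auc, "brier": best.brier, "calib_slope": best.calib_slope,
                    "loco_auc": best.loco_auc, "classifier": best.classifier,
                }
        write_table(pd.concat(screening_rows, ignore_index=True), out / "screening.csv")
        write_table(pd.DataFrame(table_rows), out / "prediction_table.csv")
        write_table(pd.DataFrame(oof_rows), out / "oof_predictions.csv")
        manifest["stages"][stage] = "ok"

        stage = "describe"
        feat_only = [c for c in feat_cols]
        volcano = describe.lesion_vs_pancreas(lesion[feat_only], pancreas[feat_only])
        write_table(volcano, out / "volcano.csv")
        clin_vars = cohort.set_index("patient_id")[["age", "ki67", "size_cm", "grade"]]
        corr = describe.radiomic_clinical_correlations(
            lesion.set_index("patient_id")[[c for c in feat_only if not c.startswith("shape_")]],
            clin_vars.reindex(lesion["patient_id"]).set_axis(lesion.set_index("patient_id").index),
        )
        write_table(corr, out / "correlations.csv")
        metrics["volcano_significant"] = int(volcano["significant"].sum()) if len(volcano) else 0
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        manifest["error"] = {"stage": stage, "traceback": traceback.format_exc()}
        write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    write_json(metrics, out / "metrics.json")
    write_json(manifest, out / "manifest.json")
    return manifest


def _target_vector(cohort: pd.DataFrame, target: str) -> np.ndarray:
    if target == "progression":
        return cohort["event"].to_numpy(float)
    if target == "higher_grade":
        return (cohort["grade"].to_numpy(float) >= 2).astype(float)
    raise ValueError(f"unknown target {target!r}")


def _prediction_frame(cohort: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Patient-aligned predictor matrix: encoded clinical variables + signatures."""
    df = cohort.set_index("patient_id").copy()
    df["sex"] = (df["sex"] == "M").astype(float)
    base = df[["age", "sex", "size_cm", "grade", "ki67", "functional"]]
    out = base.join(panel)
    return out.reset_index(drop=True)
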