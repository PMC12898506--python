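"""End-to-end pipeline orchestration and the sensitivity-analysis suite.

Stages: simulate → label → windows → features → train → evaluate → alerts.
Each stage writes delimited tables under the run directory; a manifest
records the configuration hash, seeds, and per-stage outputs so reruns with
the same config are byte-stable apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import alerts as alerts_mod
from . import features as features_mod
from . import kdigo, metrics, model as model_mod, windows as windows_mod
from .errors import ConfigurationError
from .synthetic_cohort import MissingnessPolicy, SimConfig, simulate_cohort, write_cohort

STAGES = ("simulate", "label", "windows", "features", "train", "evaluate", "alerts")


@dataclass
class RunConfig:
    """One pipeline run.  Defaults mirror the study constants: 12/2/24/6
    windowing, 10 patient-grouped folds, 2000 bootstrap resamples,
    operating threshold 0.125, 61 selected features, ages 18-88."""

    n_patients: int = 200
    seed: int = 0
    scheme: windows_mod.WindowScheme = field(default_factory=windows_mod.WindowScheme)
    sim: SimConfig = field(default_factory=SimConfig)
    k_folds: int = 10
    grid: Optional[list] = None
    use_constraints: bool = True
    feature_set: str = "selected61"        # {"all", "selected61"}
    n_selected: int = 61
    label_criteria: str = "full"           # {"full", "creatinine_only", "uo_only"}
    threshold: float = 0.125
    bootstrap_B: int = 2000
    missingness_injection: Optional[float] = None  # extra fraction of labs dropped

    def validate(self) -> None:
        if self.feature_set not in ("all", "selected61"):
            raise ConfigurationError(f"invalid feature_set {self.feature_set!r}")
        if self.label_criteria not in ("full", "creatinine_only", "uo_only"):
            raise ConfigurationError(f"invalid label_criteria {self.label_criteria!r}")
        self.scheme.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = dataclasses.asdict(self.scheme)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scheme = windows_mod.WindowScheme(**raw.pop("scheme", {}))
        sim_raw = raw.pop("sim", {})
        policy = MissingnessPolicy(**sim_raw.pop("missingness_policy", {}))
        sim = SimConfig(missingness_policy=policy, **sim_raw)
        return cls(scheme=scheme, sim=sim, **raw)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _inject_missingness(stays, fraction: float, seed: int):
    """Drop an extra fraction of every observation (labs, vitals, urine
    output) — the sensitivity knob for overall data sparsity."""
    rng = np.random.default_rng(seed)

    def _thin(t, v):
        keep = rng.random(np.asarray(t).size) >= fraction
        return (np.asarray(t)[keep], np.asarray(v)[keep])

    out = []
    for stay in stays:
        out.append(dataclasses.replace(
            stay,
            labs={k: _thin(t, v) for k, (t, v) in stay.labs.items()},
            vitals={k: _thin(t, v) for k, (t, v) in stay.vitals.items()},
            urine_output=_thin(*stay.urine_output)))
    return out


def run_pipeline(config: RunConfig, out_dir, write_outputs: bool = True) -> dict:
    """Run every stage; returns a results dict and writes a manifest.

    A stage failure raises with the failing stage named.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": _config_hash(config),
                "stages": {}, "versions": {
                    "numpy": np.__version__, "pandas": pd.__version__},
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    results = {}
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.sim, n_patients=config.n_patients,
                                      seed=config.seed)
        bundle = simulate_cohort(sim_cfg)
        stays = bundle.stays
        if write_outputs:
            write_cohort(bundle, out / "cohort")
        manifest["stages"][stage] = {"n_stays": len(stays)}

        stage = "label"
        onsets = kdigo.label_cohort(stays, criteria=config.label_criteria)
        onset_df = pd.DataFrame(
            [{"stay_id": sid, "onset": np.nan if t is None else t}
             for sid, t in onsets.items()])
        if write_outputs:
            onset_df.to_csv(out / "onsets.csv", index=False)
        manifest["stages"][stage] = {
            "n_onsets": int(onset_df["onset"].notna().sum())}

        stage = "windows"
        kept, excl = windows_mod.apply_exclusions(stays, onsets, scheme=config.scheme)
        win = windows_mod.build_cohort_windows(kept, onsets, scheme=config.scheme)
        if len(win) == 0:
            raise ConfigurationError("no prediction windows produced")
        folds = windows_mod.assign_folds(win, k=config.k_folds, seed=config.seed)
        win = win.assign(fold=folds)
        if write_outputs:
            win.to_csv(out / "windows.csv", index=False)
            excl.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"][stage] = {
            "n_windows": int(len(win)), "n_excluded": int(len(excl)),
            "prevalence": float(win["label"].mean())}

        stage = "features"
        # missingness injection degrades the model's inputs only; outcome
        # labeling always uses the intact streams
        feat_stays = kept
        if config.missingness_injection:
            feat_stays = _inject_missingness(
                kept, config.missingness_injection, seed=config.seed + 7)
        fm = features_mod.build_feature_matrix(feat_stays, win)
        train_mask = np.ones(len(fm), dtype=bool)
        fm = features_mod.encode_categoricals(fm, train_mask)
        retained, screen_report = features_mod.screen_features(fm, train_mask)
        if write_outputs:
            fm.to_csv(out / "features.csv", index=False)
            (out / "screening.json").write_text(json.dumps(
                {k: v for k, v in screen_report.items()}, indent=1, default=str))
        manifest["stages"][stage] = {"n_features": len(retained)}

        stage = "train"
        y = fm["label"].to_numpy()
        folds_arr = win["fold"].to_numpy()
        constraints = (features_mod.monotone_directions(retained)
                       if config.use_constraints else None)
        bundle_m, oof = model_mod.tune_and_train(
            fm[retained], y, folds_arr, grid=config.grid,
            constraints=constraints, seed=config.seed)
        if config.feature_set == "selected61" and config.n_selected < len(retained):
            _, bundle_m, oof, delta = model_mod.shap_select(
                fm[retained], y, folds_arr, bundle_m,
                k=config.n_selected, seed=config.seed)
            manifest["stages"]["train_shap_delta"] = {
                "delta": delta["delta"]}
        a, b = model_mod.platt_fit(oof["raw_risk"], oof["label"])
        bundle_m.platt = (a, b)
        recal = model_mod.platt_apply(oof["raw_risk"].to_numpy(), a, b)
        bundle_m.threshold = model_mod.choose_threshold(recal, y, beta=2.0)
        oof = oof.assign(recal_risk=recal, patient_id=win["patient_id"].to_numpy(),
                         stay_id=win["stay_id"].to_numpy(),
                         cutoff=win["cutoff"].to_numpy())
        if write_outputs:
            bundle_m.save(out / "model")
            oof.to_csv(out / "oof_predictions.csv", index=False)
        manifest["stages"][stage] = {
            "cv_mean_auc": getattr(bundle_m, "cv_mean_auc", None),
            "platt": [a, b], "threshold": bundle_m.threshold}

        stage = "evaluate"
        report = metrics.evaluation_report(
            recal, y, oof["patient_id"].to_numpy(), pt=config.threshold,
            B=config.bootstrap_B, seed=config.seed)
        calib = metrics.calibration_suite(recal, y)
        dca = metrics.dca_curve(recal, y, np.linspace(0.05, 0.5, 10))
        if write_outputs:
            (out / "evaluation.json").write_text(json.dumps(
                {"report": report,
                 "calibration": {k: v for k, v in calib.items() if k != "reliability"}},
                indent=1, default=float))
            calib["reliability"].to_csv(out / "reliability.csv", index=False)
            dca.to_csv(out / "dca.csv", index=False)
        manifest["stages"][stage] = {"auc": report["auc"]["estimate"]}

        stage = "alerts"
        alert_list = alerts_mod.extract_alerts(
            win, recal, onsets, pt=config.threshold,
            gap=config.scheme.gap, horizon=config.scheme.horizon)
        lead = alerts_mod.lead_time_detection(
            alert_list, {s.stay_id: onsets[s.stay_id] for s in kept})
        burden = alerts_mod.burden_metrics(
            alert_list, kept, gap=config.scheme.gap, horizon=config.scheme.horizon)
        if write_outputs:
            lead.to_csv(out / "lead_time.csv", index=False)
            (out / "burden.json").write_text(json.dumps(burden, indent=1))
        manifest["stages"][stage] = {"n_alerts": burden["total_alerts"]}
    except Exception as exc:
        manifest["failed_stage"] = stage
        if write_outputs:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                          default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if write_outputs:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    results.update({"manifest": manifest, "windows": win, "features": fm,
                    "retained": retained, "model": bundle_m, "oof": oof,
                    "report": report, "calibration": calib, "dca": dca,
                    "lead_time": lead, "burden": burden, "onsets": onsets,
                    "stays": kept})
    return results


def run_sensitivity_suite(config: RunConfig, out_dir,
                          missingness_fractions=(0.5, 0.9),
                          contrasts=("constraints", "feature_set",
                                     "label_criteria", "missingness")) -> pd.DataFrame:
    """Re-run train/evaluate under each contrast and tabulate AUC/AUPRC.

    Contrasts: monotone constraints on/off; all features vs the selected
    subset; full vs creatinine-only vs urine-output-only labeling; injected
    extra lab missingness.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    def _run(tag, **overrides):
        cfg = dataclasses.replace(config, **overrides)
        try:
            res = run_pipeline(cfg, out / tag, write_outputs=False)
        except Exception as exc:
            rows.append({"contrast": tag, "auc": np.nan, "auprc": np.nan,
                         "status": f"not_computable: {exc}"})
            return
        rep = res["report"]
        rows.append({"contrast": tag,
                     "auc": rep["auc"]["estimate"],
                     "auc_lo": rep["auc"]["ci_lo"], "auc_hi": rep["auc"]["ci_hi"],
                     "auprc": rep["auprc"]["estimate"],
                     "prevalence": float(res["windows"]["label"].mean()),
                     "n_events": sum(t is not None
                                     for t in res["onsets"].values()),
                     "status": "ok"})

    _run("base")
    if "constraints" in contrasts:
        _run("no_constraints", use_constraints=not config.use_constraints)
    if "feature_set" in contrasts:
        other = "all" if config.feature_set == "selected61" else "selected61"
        _run(f"features_{other}", feature_set=other)
    if "label_criteria" in contrasts:
        for crit in ("creatinine_only", "uo_only"):
            _run(f"labels_{crit}", label_criteria=crit)
    if "missingness" in contrasts:
        for frac in missingness_fractions:
            _run(f"missingness_{int(100 * frac)}", missingness_injection=frac)
    table = pd.DataFrame(rows)
    table.to_csv(out / "sensitivity.csv", index=False)
    return table
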