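"""Monotone-constrained gradient boosting with patient-grouped CV.

Training pipeline: grid search over a small hyperparameter grid using
patient-grouped k-fold cross-validation (the winning point maximizes the
mean per-fold out-of-fold AUC), monotone constraints from clinical priors,
SHAP-ranked selection down to a fixed feature budget, Platt recalibration
of the out-of-fold risks, and an F2-maximizing operating threshold.

SHAP values are computed with the booster's built-in TreeSHAP
(``pred_contribs=True``) and pooled over out-of-fold rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError, InputError


def default_grid() -> list:
    """Small default hyperparameter grid (depth, learning rate, subsampling,
    minimum child weight, boosting rounds)."""
    return [
        {"max_depth": 4, "eta": 0.1, "subsample": 0.8,
         "colsample_bytree": 0.8, "min_child_weight": 5, "num_boost_round": 150},
        {"max_depth": 6, "eta": 0.05, "subsample": 0.8,
         "colsample_bytree": 0.8, "min_child_weight": 10, "num_boost_round": 250},
    ]


@dataclass
class ModelBundle:
    booster: xgb.Booster
    params: dict
    feature_names: list
    constraint_map: dict
    selected_features: Optional[list] = None
    platt: Optional[tuple] = None          # (a, b)
    threshold: float = 0.125
    fold_map: Optional[dict] = None

    def predict_raw(self, X: pd.DataFrame) -> np.ndarray:
        cols = self.selected_features or self.feature_names
        dm = xgb.DMatrix(X[cols], missing=np.nan)
        return self.booster.predict(dm)

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.predict_raw(X)
        if self.platt is None:
            return raw
        return platt_apply(raw, *self.platt)

    def save(self, path) -> None:
        """Booster in its native portable JSON plus a sidecar manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(path / "booster.json")
        manifest = {
            "params": self.params,
            "feature_names": self.feature_names,
            "constraint_map": self.constraint_map,
            "selected_features": self.selected_features,
            "platt": None if self.platt is None else list(self.platt),
            "threshold": self.threshold,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(path / "booster.json")
        m = json.loads((path / "manifest.json").read_text())
        platt = None if m["platt"] is None else tuple(m["platt"])
        return cls(booster=booster, params=m["params"],
                   feature_names=m["feature_names"],
                   constraint_map=m["constraint_map"],
                   selected_features=m["selected_features"], platt=platt,
                   threshold=m["threshold"])


def _xgb_params(point: dict, constraints: Optional[dict], feature_names,
                seed: int, use_constraints: bool = True) -> tuple:
    params = {k: v for k, v in point.items() if k != "num_boost_round"}
    params.update({"objective": "binary:logistic", "eval_metric": "logloss",
                   "tree_method": "hist", "seed": seed, "nthread": 0,
                   "verbosity": 0})
    if constraints is not None and use_constraints:
        vec = tuple(int(constraints.get(f, 0)) for f in feature_names)
        params["monotone_constraints"] = "(" + ",".join(map(str, vec)) + ")"
    return params, int(point.get("num_boost_round", 150))


def _check_folds(y: np.ndarray, folds: np.ndarray) -> None:
    for f in np.unique(folds):
        tr = y[folds != f]
        if len(np.unique(tr)) < 2:
            raise InputError(f"single-class training split for fold {f}")


def tune_and_train(X: pd.DataFrame, y, folds, grid=None, constraints=None,
                   seed: int = 0, feature_names=None):
    """Grid search + patient-grouped CV; returns (ModelBundle, oof frame).

    The out-of-fold frame has one row per window: raw risk from the model
    not trained on its fold, fold id, and label.  The final booster is
    refit on all rows with the winning hyperparameters.
    """
    grid = grid or default_grid()
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    y = np.asarray(y, dtype=int)
    folds = np.asarray(folds, dtype=int)
    feature_names = list(feature_names or X.columns)
    Xm = X[feature_names]
    _check_folds(y, folds)
    dm_cache = {}
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        dm_cache[f] = (
            xgb.DMatrix(Xm[tr], label=y[tr], missing=np.nan),
            xgb.DMatrix(Xm[va], missing=np.nan), tr, va)

    best = None
    for gi, point in enumerate(grid):
        params, rounds = _xgb_params(point, constraints, feature_names, seed)
        oof = np.full(y.size, np.nan)
        fold_aucs = []
        for f, (dtr, dva, tr, va) in dm_cache.items():
            booster = xgb.train(params, dtr, num_boost_round=rounds)
            pred = booster.predict(dva)
            oof[va] = pred
            if len(np.unique(y[va])) == 2:
                fold_aucs.append(roc_auc_score(y[va], pred))
        mean_auc = float(np.mean(fold_aucs)) if fold_aucs else np.nan
        if best is None or mean_auc > best["auc"]:
            best = {"auc": mean_auc, "point": point, "oof": oof, "index": gi}

    params, rounds = _xgb_params(best["point"], constraints, feature_names, seed)
    dall = xgb.DMatrix(Xm, label=y, missing=np.nan)
    final = xgb.train(params, dall, num_boost_round=rounds)
    oof_df = pd.DataFrame({"raw_risk": best["oof"], "fold": folds, "label": y})
    bundle = ModelBundle(booster=final, params={**best["point"], "seed": seed},
                         feature_names=feature_names,
                         constraint_map=dict(constraints or {}),
                         fold_map={int(f): None for f in np.unique(folds)})
    bundle.cv_mean_auc = best["auc"]
    return bundle, oof_df


def enforce_monotone(bundle: ModelBundle, X_sample: pd.DataFrame,
                     n_grid: int = 20, tol: float = 1e-9) -> pd.DataFrame:
    """Sweep every constrained feature over its observed range on each
    sample row and report any direction violation (must be none)."""
    cols = bundle.selected_features or bundle.feature_names
    rows = []
    for feat, direction in bundle.constraint_map.items():
        if direction == 0 or feat not in cols:
            continue
        vals = X_sample[feat].dropna()
        if vals.empty:
            continue
        grid = np.linspace(vals.min(), vals.max(), n_grid)
        base = X_sample[cols].copy()
        preds = np.empty((n_grid, len(base)))
        for i, g in enumerate(grid):
            swept = base.copy()
            swept[feat] = g
            preds[i] = bundle.predict_raw(swept)
        diffs = np.diff(preds, axis=0) * direction
        bad = np.where(diffs < -tol)
        for i, j in zip(*bad):
            rows.append({"feature": feat, "row": int(j),
                         "grid_index": int(i), "violation": float(diffs[i, j])})
    return pd.DataFrame(rows, columns=["feature", "row", "grid_index", "violation"])


def shap_select(X: pd.DataFrame, y, folds, bundle: ModelBundle, k: int = 61,
                seed: int = 0, grid_point: Optional[dict] = None):
    """Rank features by mean |SHAP| pooled over out-of-fold rows, keep the
    top k, retrain, and report the OOF AUC delta.

    Per-fold models are refit with the bundle's winning hyperparameters;
    each row's SHAP contributions come from the model not trained on it.
    """
    feature_names = bundle.feature_names
    if k > len(feature_names):
        raise ConfigurationError(
            f"k={k} exceeds the {len(feature_names)} available features")
    y = np.asarray(y, dtype=int)
    folds = np.asarray(folds, dtype=int)
    point = grid_point or {kk: v for kk, v in bundle.params.items() if kk != "seed"}
    params, rounds = _xgb_params(point, bundle.constraint_map, feature_names, seed)
    Xm = X[feature_names]
    abs_shap = np.zeros(len(feature_names))
    oof_full = np.full(y.size, np.nan)
    n_rows = 0
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        dtr = xgb.DMatrix(Xm[tr], label=y[tr], missing=np.nan)
        dva = xgb.DMatrix(Xm[va], missing=np.nan)
        booster = xgb.train(params, dtr, num_boost_round=rounds)
        oof_full[va] = booster.predict(dva)
        contribs = booster.predict(dva, pred_contribs=True)  # (n, p+1), bias last
        abs_shap += np.abs(contribs[:, :-1]).sum(axis=0)
        n_rows += int(va.sum())
    mean_abs_shap = abs_shap / n_rows
    ranking = pd.Series(mean_abs_shap, index=feature_names).sort_values(ascending=False)
    top = set(ranking.index[:k])
    # keep the original column order so k = p reproduces the model exactly
    selected = [f for f in feature_names if f in top]

    sel_constraints = {f: bundle.constraint_map.get(f, 0) for f in selected}
    new_bundle, new_oof = tune_and_train(
        X[selected], y, folds, grid=[point], constraints=sel_constraints,
        seed=seed, feature_names=selected)
    new_bundle.selected_features = selected
    auc_full = roc_auc_score(y, oof_full)
    auc_sel = roc_auc_score(y, new_oof["raw_risk"])
    delta = {"oof_auc_full": float(auc_full), "oof_auc_selected": float(auc_sel),
             "delta": float(auc_sel - auc_full), "ranking": ranking}
    return selected, new_bundle, new_oof, delta


# ---------------------------------------------------------------------------
# Platt recalibration (on the logit of predicted probability, so a second
# fit on recalibrated output is a near-identity)

def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def platt_fit(raw_risks, labels) -> tuple:
    """Logistic fit of label on logit(raw risk); returns (a, b)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("Platt scaling needs both classes")
    lp = _logit(raw_risks).reshape(-1, 1)
    if np.ptp(lp) == 0:
        # constant risk: intercept-only fit, recalibrated value = prevalence
        prev = labels.mean()
        a = float(np.log(prev / (1 - prev)) - lp[0, 0])
        return a, 1.0
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(lp, labels)
    a, b = float(lr.intercept_[0]), float(lr.coef_[0, 0])
    if abs(b) > 50 or abs(a) > 50:
        warnings.warn("separable out-of-fold set: falling back to ridge-"
                      "penalized Platt fit")
        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        lr.fit(lp, labels)
        a, b = float(lr.intercept_[0]), float(lr.coef_[0, 0])
    return a, b


def platt_apply(raw_risks, a: float, b: float) -> np.ndarray:
    z = a + b * _logit(raw_risks)
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# operating threshold

def choose_threshold(risks, labels, beta: float = 2.0) -> float:
    """F-beta-maximizing threshold over the sorted unique predicted risks;
    ties break toward the smaller threshold (higher sensitivity)."""
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("threshold choice needs both classes")
    order = np.argsort(-risks, kind="mergesort")
    sorted_risks = risks[order]
    sorted_labels = labels[order]
    tp_cum = np.cumsum(sorted_labels)
    fp_cum = np.cumsum(1 - sorted_labels)
    n_pos = int(labels.sum())
    # candidate thresholds: each unique risk; alert rule is risk >= pt, so
    # taking pt = sorted_risks[i] alerts on positions 0..last index of that value
    uniq_last = np.nonzero(np.diff(sorted_risks, append=-np.inf) != 0)[0]
    tp = tp_cum[uniq_last]
    fp = fp_cum[uniq_last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    b2 = beta * beta
    with np.errstate(invalid="ignore", divide="ignore"):
        fbeta = (1 + b2) * precision * recall / (b2 * precision + recall)
    fbeta = np.nan_to_num(fbeta, nan=-1.0)
    best = np.max(fbeta)
    # among maximizers pick the smallest threshold value
    cand_vals = sorted_risks[uniq_last][fbeta == best]
    return float(cand_vals.min())
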