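"""Window-level trajectory features and training-set screening.

Continuous streams are summarized over lookbacks ending at the prediction
cutoff (last/mean/sd/min/max and OLS slopes over the 12 h feature window;
48-72 h slopes and piecewise slope changes for trend features).  Trend
lookbacks read history beyond the 12 h window but never at or beyond the
cutoff, preserving the leakage contract.  Missing values are preserved —
nothing is imputed; tree models treat absence as informative.

The piecewise slope change (PSC) of a trajectory is the difference between
the two slopes of the best continuous two-segment linear fit, with the
breakpoint chosen by exhaustive least squares over interior observed
timestamps.  A falling-then-stable or stable-then-falling pattern (e.g., in
mean arterial pressure) therefore shows up as a single signed number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

SUMMARY_REPS = ("last", "mean", "sd", "min", "max", "slope")


@dataclass(frozen=True)
class FeatureSpec:
    stream: str
    representation: str  # one of SUMMARY_REPS or "psc"
    lookback: float      # hours
    monotone_direction: int = 0

    @property
    def name(self) -> str:
        lb = int(self.lookback)
        return f"{self.stream}_{self.representation}{lb}"


def default_feature_specs() -> list:
    """The shipped stream-summary feature set.

    Short (12 h) summaries for every vital; 48-72 h slopes and piecewise
    slope changes for the trajectories that carry AKI precursor signal
    (hemodynamics, oxygenation, heart rate, renal chemistry); last observed
    value over 48 h for every lab.  Monotone directions encode clinical
    priors: rising creatinine/BUN must not lower predicted risk.
    """
    specs = []
    for v in ("hr", "map", "sbp", "dbp", "rr", "temp", "spo2"):
        for rep in ("last", "mean", "sd", "slope"):
            specs.append(FeatureSpec(v, rep, 12.0))
    for v in ("map", "spo2", "hr"):
        specs.append(FeatureSpec(v, "psc", 48.0))
    for v in ("map", "sbp", "dbp", "hr", "spo2"):
        specs.append(FeatureSpec(v, "delta", 48.0))
    specs.append(FeatureSpec("creatinine", "delta", 48.0, monotone_direction=+1))
    specs.append(FeatureSpec("bun", "delta", 48.0, monotone_direction=+1))
    specs.append(FeatureSpec("hr", "slope", 48.0))
    specs.append(FeatureSpec("temp", "slope", 48.0))
    specs.append(FeatureSpec("creatinine", "slope", 72.0, monotone_direction=+1))
    specs.append(FeatureSpec("bun", "slope", 72.0, monotone_direction=+1))
    specs.append(FeatureSpec("glucose", "slope", 72.0))
    for lab in ("creatinine", "bun", "bicarbonate", "anion_gap", "wbc", "glucose",
                "hemoglobin", "platelets", "sodium", "potassium", "chloride"):
        direction = +1 if lab in ("creatinine", "bun") else 0
        specs.append(FeatureSpec(lab, "last", 48.0, monotone_direction=direction))
    specs.append(FeatureSpec("creatinine", "mean", 48.0, monotone_direction=+1))
    specs.append(FeatureSpec("bun", "mean", 48.0, monotone_direction=+1))
    return specs


def summarize_window(times, values, cutoff: float, representation: str,
                     lookback: float) -> float:
    """One summary of the points with time in [cutoff − lookback, cutoff).

    Slope is the OLS slope of value on time (units per hour), missing with
    fewer than two distinct time points; sd is missing with fewer than two
    points.  Returns NaN for missing.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times >= cutoff - lookback) & (times < cutoff)
    t, y = times[mask], values[mask]
    return _summarize(t, y, representation)


def _summarize(t: np.ndarray, y: np.ndarray, representation: str) -> float:
    if t.size == 0:
        return np.nan
    if representation == "last":
        return float(y[-1])
    if representation == "mean":
        return float(y.mean())
    if representation == "sd":
        return float(y.std(ddof=1)) if t.size >= 2 else np.nan
    if representation == "min":
        return float(y.min())
    if representation == "max":
        return float(y.max())
    if representation == "slope":
        if t.size < 2 or np.ptp(t) == 0:
            return np.nan
        tc = t - t.mean()
        return float((tc @ (y - y.mean())) / (tc @ tc))
    if representation == "delta":
        # change from recent baseline: mean of the trailing 12 h minus the
        # mean of the earlier part of the lookback
        split = t.max() - 12.0 if t.size else 0.0
        recent, earlier = y[t >= split], y[t < split]
        if recent.size == 0 or earlier.size == 0:
            return np.nan
        return float(recent.mean() - earlier.mean())
    raise ConfigurationError(f"unknown representation {representation!r}")


def piecewise_slope_change(times, values, cutoff: float, lookback: float) -> float:
    """slope(second segment) − slope(first segment) of the best continuous
    two-segment fit to the visible points; NaN with fewer than 4 points."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times >= cutoff - lookback) & (times < cutoff)
    t, y = times[mask], values[mask]
    return _psc(t, y)


def _psc(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 4:
        return np.nan
    # candidate breakpoints: observed timestamps with >= 2 strictly on each side
    uniq = np.unique(t)
    cands = np.array([b for b in uniq
                      if (t < b).sum() >= 2 and (t > b).sum() >= 2])
    if cands.size == 0:
        return np.nan
    n = t.size
    # batched normal equations for y ~ 1 + t + max(t - b, 0)
    H = np.maximum(t[None, :] - cands[:, None], 0.0)     # (m, n)
    ones = np.ones(n)
    X0 = np.stack([np.broadcast_to(ones, H.shape),
                   np.broadcast_to(t, H.shape), H], axis=2)  # (m, n, 3)
    XtX = np.einsum("mni,mnj->mij", X0, X0)
    Xty = np.einsum("mni,n->mi", X0, y)
    try:
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]   # (m, 3)
    except np.linalg.LinAlgError:
        return np.nan
    resid = y[None, :] - np.einsum("mni,mi->mn", X0, beta)
    sse = (resid ** 2).sum(axis=1)
    best = int(np.argmin(sse))
    return float(beta[best, 2])  # hinge coefficient = slope2 - slope1


# ---------------------------------------------------------------------------
# feature-matrix construction

_STATIC_BINARY = ("ckd", "diabetes", "sepsis", "shock", "hypertension",
                  "cirrhosis", "ami", "ahf", "contrast", "covid")
_VASOPRESSORS = ("norepinephrine", "phenylephrine", "epinephrine",
                 "vasopressin", "dopamine")
META_COLUMNS = ("patient_id", "stay_id", "cutoff", "label")


def build_feature_matrix(stays, windows_df: pd.DataFrame,
                         specs=None) -> pd.DataFrame:
    """Feature matrix with one row per prediction window.

    Includes the stream-summary specs plus statics (age, admission weight,
    sex, unit type, comorbidity flags), urine-output summaries (12 h volume
    and weight-normalized 6/12 h rates, monotone-decreasing priors), and
    vasopressor exposure (on-pressor flag and pressor-hours in the last
    24 h, monotone-increasing priors).  Only data strictly before each
    window's cutoff is visible.
    """
    specs = default_feature_specs() if specs is None else specs
    by_stay = {s.stay_id: s for s in stays}
    # group stream specs by (stream, lookback) so each slice is cut once
    groups = {}
    for spec in specs:
        groups.setdefault((spec.stream, spec.lookback), []).append(spec)

    records = []
    for row in windows_df.itertuples():
        stay = by_stay[row.stay_id]
        cutoff = float(row.cutoff)
        feats = {}
        for (stream, lookback), group in groups.items():
            try:
                t_all, v_all = stay.stream(stream)
            except KeyError:
                t_all, v_all = np.array([]), np.array([])
            lo = np.searchsorted(t_all, cutoff - lookback, side="left")
            hi = np.searchsorted(t_all, cutoff, side="left")
            t, v = t_all[lo:hi], v_all[lo:hi]
            for spec in group:
                if spec.representation == "psc":
                    feats[spec.name] = _psc(t, v)
                else:
                    feats[spec.name] = _summarize(t, v, spec.representation)
        # urine output summaries
        uo_t, uo_v = stay.urine_output
        lo = np.searchsorted(uo_t, cutoff - 12.0, side="left")
        hi = np.searchsorted(uo_t, cutoff, side="left")
        vol12 = float(uo_v[lo:hi].sum()) if hi > lo else np.nan
        w_t, w_v = stay.weights
        w_idx = np.searchsorted(w_t, cutoff, side="right") - 1
        weight = float(w_v[w_idx]) if w_idx >= 0 else np.nan
        feats["uo_vol12"] = vol12
        lo6 = np.searchsorted(uo_t, cutoff - 6.0, side="left")
        vol6 = float(uo_v[lo6:hi].sum()) if hi > lo6 else np.nan
        feats["uo_rate6"] = vol6 / (6.0 * weight) if np.isfinite(weight) else np.nan
        feats["uo_rate12"] = vol12 / (12.0 * weight) if np.isfinite(weight) else np.nan
        # treatments: vasopressor exposure before the cutoff
        on_pressor = 0
        pressor_hours = 0.0
        for drug, start, end in stay.treatments:
            if drug in _VASOPRESSORS and start < cutoff:
                if end >= cutoff:
                    on_pressor = 1
                overlap = min(end, cutoff) - max(start, cutoff - 24.0)
                pressor_hours += max(overlap, 0.0)
        feats["on_vasopressor"] = on_pressor
        feats["vasopressor_hours24"] = pressor_hours
        # statics
        feats["age"] = np.nan if stay.age is None else float(stay.age)
        feats["admission_weight"] = float(w_v[0]) if len(w_t) else np.nan
        feats["sex"] = stay.sex
        feats["unit_type"] = stay.unit_type
        for flag in _STATIC_BINARY:
            feats[flag] = stay.comorbidities.get(flag, 0)
        rec = {"patient_id": row.patient_id, "stay_id": row.stay_id,
               "cutoff": cutoff, "label": row.label}
        rec.update(feats)
        records.append(rec)
    return pd.DataFrame(records)


def monotone_directions(columns) -> dict:
    """Clinical-prior monotone direction for each feature column."""
    spec_dirs = {s.name: s.monotone_direction for s in default_feature_specs()}
    out = {}
    for col in columns:
        if col in spec_dirs:
            out[col] = spec_dirs[col]
        elif col in ("uo_vol12", "uo_rate6", "uo_rate12"):
            out[col] = -1
        elif col in ("on_vasopressor", "vasopressor_hours24"):
            out[col] = +1
        else:
            out[col] = 0
    return out


# ---------------------------------------------------------------------------
# screening and encoding (training-derived, applied unchanged to validation)

def screen_features(matrix: pd.DataFrame, train_mask,
                    missing_threshold: float = 0.5,
                    nzv_share: float = 0.99,
                    corr_threshold: float = 0.95):
    """Drop >50%-missing and near-zero-variance columns; report collinear
    pairs (|Pearson| or |Spearman| above the threshold) without dropping.

    All statistics are computed on training rows only.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ConfigurationError("empty training mask")
    candidates = [c for c in matrix.columns if c not in META_COLUMNS]
    train = matrix.loc[train_mask, candidates]
    retained = []
    report = {"dropped_missing": [], "dropped_nzv": [], "collinear_pairs": []}
    for col in candidates:
        s = train[col]
        if s.isna().mean() > missing_threshold:
            report["dropped_missing"].append(col)
            continue
        non_missing = s.dropna()
        if non_missing.empty:
            report["dropped_nzv"].append(col)
            continue
        top_share = non_missing.value_counts(normalize=True).iloc[0]
        if top_share > nzv_share:
            report["dropped_nzv"].append(col)
            continue
        retained.append(col)
    numeric = [c for c in retained
               if pd.api.types.is_numeric_dtype(train[c])]
    sub = train[numeric]
    if len(numeric) >= 2:
        pear = sub.corr(method="pearson")
        spear = sub.corr(method="spearman")
        for i, a in enumerate(numeric):
            for b in numeric[i + 1:]:
                pc = pear.loc[a, b]
                sc = spear.loc[a, b]
                if (np.isfinite(pc) and abs(pc) > corr_threshold) or \
                        (np.isfinite(sc) and abs(sc) > corr_threshold):
                    report["collinear_pairs"].append(
                        {"a": a, "b": b, "pearson": float(pc), "spearman": float(sc)})
    return retained, report


def encode_categoricals(matrix: pd.DataFrame, train_mask,
                        columns=("sex", "unit_type")) -> pd.DataFrame:
    """One-hot encode with vocabularies learned on training rows; unseen
    validation levels map to all-zero indicators."""
    train_mask = np.asarray(train_mask, dtype=bool)
    out = matrix.copy()
    for col in columns:
        if col not in out.columns:
            continue
        levels = sorted(pd.Series(out.loc[train_mask, col]).dropna().unique())
        for level in levels:
            out[f"{col}__{level}"] = (out[col] == level).astype(int)
        out = out.drop(columns=[col])
    return out
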