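"""Discrimination, calibration, decision-curve, subgroup and balance metrics
with patient-clustered bootstrap confidence intervals.

Decision-analytic quantities follow the standard net-benefit calculus: at a
threshold probability pt, a false positive is weighted by w = pt/(1 − pt),
so NB = TP/N − w·FP/N; "treat all" gives π − (1 − π)·w and "treat none" 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import InputError

_EPS = 1e-6


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _clip_risks(risks, warn: bool = True):
    risks = np.asarray(risks, dtype=float)
    if np.any((risks < 0) | (risks > 1)):
        raise InputError("risks must lie in [0, 1]")
    if warn and np.any((risks <= 0) | (risks >= 1)):
        warnings.warn("risks of exactly 0/1 clipped for logit transforms")
    return np.clip(risks, _EPS, 1.0 - _EPS)


# ---------------------------------------------------------------------------
# threshold (confusion-matrix) metrics

def fbeta_score_from_pr(precision: float, recall: float, beta: float) -> float:
    if precision + recall == 0:
        return np.nan
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def confusion_metrics(risks, labels, pt: float) -> dict:
    """Threshold metrics at alert rule risk >= pt.

    Undefined ratios on single-class inputs are returned as NaN and listed
    under 'undefined' rather than silently zeroed.
    """
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any((risks < 0) | (risks > 1)):
        raise InputError("risks must lie in [0, 1]")
    alert = risks >= pt
    tp = int(np.sum(alert & (labels == 1)))
    fp = int(np.sum(alert & (labels == 0)))
    fn = int(np.sum(~alert & (labels == 1)))
    tn = int(np.sum(~alert & (labels == 0)))
    n_pos, n_neg = tp + fn, fp + tn
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return np.nan
        return num / den

    recall = _ratio(tp, n_pos, "recall")
    specificity = _ratio(tn, n_neg, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    bal_acc = (recall + specificity) / 2.0
    f1 = fbeta_score_from_pr(precision, recall, 1.0) if np.isfinite(precision) and np.isfinite(recall) else np.nan
    f2 = fbeta_score_from_pr(precision, recall, 2.0) if np.isfinite(precision) and np.isfinite(recall) else np.nan
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else np.nan
    if mcc_den == 0:
        undefined.append("mcc")
    brier = float(np.mean((risks - labels) ** 2))
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "recall": recall, "specificity": specificity, "precision": precision,
            "f1": f1, "f2": f2, "balanced_accuracy": bal_acc, "mcc": mcc,
            "brier": brier, "undefined": undefined}


def rank_metrics(risks, labels) -> tuple:
    """(AUC, AUPRC): tie-corrected Mann–Whitney AUC and step-interpolated
    precision-recall area."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("rank metrics need both classes")
    auc = float(roc_auc_score(labels, risks))
    auprc = float(average_precision_score(labels, risks))
    return auc, auprc


# ---------------------------------------------------------------------------
# clustered bootstrap

@dataclass
class BootstrapCI:
    lo: float
    hi: float
    n_invalid: int = 0
    replicates: np.ndarray = field(default=None, repr=False)
    degenerate: bool = False


def cluster_bootstrap(statistic, cluster_ids, arrays, B: int = 2000,
                      seed: int = 0, alpha: float = 0.05) -> BootstrapCI:
    """Percentile CI for ``statistic(*arrays)`` under resampling of whole
    clusters (patients) with replacement.

    Replicates where the statistic is undefined (raises or returns NaN) are
    excluded and counted.  Deterministic under ``seed``.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    cluster_ids = np.asarray(cluster_ids)
    arrays = [np.asarray(a) for a in arrays]
    codes, uniques = pd.factorize(cluster_ids)
    n_clusters = len(uniques)
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(n_clusters + 1))
    members = [order[bounds[i]:bounds[i + 1]] for i in range(n_clusters)]
    rng = np.random.default_rng(seed)
    reps = np.full(B, np.nan)
    for b in range(B):
        chosen = rng.integers(0, n_clusters, size=n_clusters)
        idx = np.concatenate([members[c] for c in chosen])
        try:
            reps[b] = statistic(*(a[idx] for a in arrays))
        except Exception:
            reps[b] = np.nan
    valid = reps[np.isfinite(reps)]
    n_invalid = int(B - valid.size)
    if valid.size == 0:
        return BootstrapCI(np.nan, np.nan, n_invalid=n_invalid, replicates=reps,
                           degenerate=True)
    lo, hi = np.percentile(valid, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(float(lo), float(hi), n_invalid=n_invalid,
                       replicates=reps, degenerate=(n_clusters == 1))


# ---------------------------------------------------------------------------
# calibration

def calibration_suite(risks, labels, n_bins: int = 10) -> dict:
    """Calibration slope/intercept, CITL, ECE, Brier and reliability curve.

    Slope and intercept come from a logistic regression of the label on
    logit(risk); CITL is the intercept of the same model with the slope
    fixed at 1 (an offset model).  ECE uses equal-width bins on [0, 1].
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("calibration needs both classes")
    risks = _clip_risks(risks)
    lp = _logit(risks)
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if np.ptp(lp) == 0:
            # constant risk: the slope is unidentified; only CITL is defined
            intercept, slope = np.nan, np.nan
        else:
            X = sm.add_constant(lp)
            fit = sm.GLM(labels, X, family=sm.families.Binomial()).fit()
            intercept, slope = float(fit.params[0]), float(fit.params[1])
        citl_fit = sm.GLM(labels, np.ones((labels.size, 1)),
                          family=sm.families.Binomial(), offset=lp).fit()
        citl = float(citl_fit.params[0])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(risks, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    curve = []
    for b in range(n_bins):
        mask = bin_idx == b
        if not mask.any():
            continue
        w = mask.mean()
        mean_risk = float(risks[mask].mean())
        event_rate = float(labels[mask].mean())
        ece += w * abs(mean_risk - event_rate)
        curve.append({"bin": b, "mean_risk": mean_risk, "event_rate": event_rate,
                      "n": int(mask.sum())})
    return {"intercept": intercept, "slope": slope, "citl": citl,
            "ece": float(ece), "brier": float(np.mean((risks - labels) ** 2)),
            "reliability": pd.DataFrame(curve)}


# ---------------------------------------------------------------------------
# decision-curve analysis

def threshold_weight(pt: float) -> float:
    if not 0.0 < pt < 1.0:
        raise InputError("pt must lie in (0, 1)")
    return pt / (1.0 - pt)


def net_benefit(risks, labels, pt: float) -> float:
    """NB = TP/N − (FP/N)·pt/(1 − pt) for the alert rule risk >= pt."""
    w = threshold_weight(pt)
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    alert = risks >= pt
    tp = np.sum(alert & (labels == 1))
    fp = np.sum(alert & (labels == 0))
    return float(tp / n - w * fp / n)


def nb_treat_all(prevalence: float, pt: float) -> float:
    """Net benefit of alerting on every window: π − (1 − π)·pt/(1 − pt)."""
    w = threshold_weight(pt)
    return float(prevalence - (1.0 - prevalence) * w)


def avoided_interventions_per_100(nb_model: float, nb_all: float, pt: float) -> float:
    """Unnecessary responses avoided per 100 windows vs the treat-all policy."""
    return 100.0 * (nb_model - nb_all) / threshold_weight(pt)


def dca_curve(risks, labels, pt_grid) -> pd.DataFrame:
    labels = np.asarray(labels, dtype=int)
    prevalence = float(labels.mean())
    rows = []
    for pt in np.asarray(pt_grid, dtype=float):
        rows.append({"pt": float(pt),
                     "nb_model": net_benefit(risks, labels, pt),
                     "nb_treat_all": nb_treat_all(prevalence, pt),
                     "nb_treat_none": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DeLong comparison (unpaired, placement-value variance)

def _auc_and_variance(risks, labels) -> tuple:
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = risks[labels == 1]
    neg = risks[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("DeLong needs both classes in each group")
    m, n = pos.size, neg.size
    # placement of each positive among negatives, with tie correction
    order = np.argsort(neg, kind="mergesort")
    sneg = neg[order]
    v10 = (np.searchsorted(sneg, pos, side="left")
           + 0.5 * (np.searchsorted(sneg, pos, side="right")
                    - np.searchsorted(sneg, pos, side="left"))) / n
    spos = np.sort(pos)
    v01 = (np.searchsorted(spos, neg, side="left")
           + 0.5 * (np.searchsorted(spos, neg, side="right")
                    - np.searchsorted(spos, neg, side="left")))
    v01 = 1.0 - v01 / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def delong_compare(risks_g1, labels_g1, risks_g2, labels_g2,
                   m_comparisons: int = 1) -> dict:
    """Unpaired DeLong test of AUC difference between two independent groups,
    with Bonferroni correction across ``m_comparisons``."""
    auc1, var1 = _auc_and_variance(risks_g1, labels_g1)
    auc2, var2 = _auc_and_variance(risks_g2, labels_g2)
    se = np.sqrt(var1 + var2)
    if se == 0:
        p = 1.0 if auc1 == auc2 else 0.0
    else:
        z = (auc1 - auc2) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {"auc1": auc1, "auc2": auc2, "p": p,
            "p_bonferroni": float(min(1.0, p * m_comparisons))}


# ---------------------------------------------------------------------------
# covariate balance

def asmd(values_a, values_b, binary: bool = False, weights_a=None,
         weights_b=None) -> float:
    """Absolute standardized mean difference between two window-level
    samples; non-missing entries only, optional per-window weights
    (default 1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    wa = np.ones(a.size) if weights_a is None else np.asarray(weights_a, dtype=float)
    wb = np.ones(b.size) if weights_b is None else np.asarray(weights_b, dtype=float)
    ka, kb = np.isfinite(a), np.isfinite(b)
    a, wa = a[ka], wa[ka]
    b, wb = b[kb], wb[kb]
    ma = np.average(a, weights=wa)
    mb = np.average(b, weights=wb)
    if binary:
        pooled = np.sqrt((ma * (1 - ma) + mb * (1 - mb)) / 2.0)
    else:
        va = np.average((a - ma) ** 2, weights=wa)
        vb = np.average((b - mb) ** 2, weights=wb)
        pooled = np.sqrt((va + vb) / 2.0)
    diff = abs(ma - mb)
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf
    return float(diff / pooled)


# ---------------------------------------------------------------------------
# full evaluation report

def evaluation_report(risks, labels, cluster_ids, pt: float = 0.125,
                      B: int = 2000, seed: int = 0) -> dict:
    """Point estimates plus clustered-bootstrap 95% CIs for the full
    discrimination/threshold metric panel."""
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point = confusion_metrics(risks, labels, pt)
    auc, auprc = rank_metrics(risks, labels)
    point["auc"], point["auprc"] = auc, auprc
    stat_fns = {
        "auc": lambda r, y: rank_metrics(r, y)[0],
        "auprc": lambda r, y: rank_metrics(r, y)[1],
        "recall": lambda r, y: confusion_metrics(r, y, pt)["recall"],
        "specificity": lambda r, y: confusion_metrics(r, y, pt)["specificity"],
        "precision": lambda r, y: confusion_metrics(r, y, pt)["precision"],
        "f1": lambda r, y: confusion_metrics(r, y, pt)["f1"],
        "f2": lambda r, y: confusion_metrics(r, y, pt)["f2"],
        "balanced_accuracy": lambda r, y: confusion_metrics(r, y, pt)["balanced_accuracy"],
        "mcc": lambda r, y: confusion_metrics(r, y, pt)["mcc"],
        "brier": lambda r, y: confusion_metrics(r, y, pt)["brier"],
    }
    out = {"pt": pt}
    for name, fn in stat_fns.items():
        ci = cluster_bootstrap(fn, cluster_ids, [risks, labels], B=B, seed=seed)
        out[name] = {"estimate": float(point[name]) if np.isfinite(point[name]) else np.nan,
                     "ci_lo": ci.lo, "ci_hi": ci.hi, "n_invalid": ci.n_invalid}
    return out
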