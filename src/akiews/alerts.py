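"""Event-level alert analytics: first-alert detection, lead-time bins,
false-positive taxonomy, and alert-burden metrics.

An alert is a prediction window whose recalibrated risk crosses the
operating threshold.  Censoring guarantees every alert in an AKI stay
precedes the onset by more than the leakage gap, so lead time (onset −
cutoff, measured from the moment the prediction is issued) is well defined
for every matched alert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError

FP_CATEGORIES = ("tp_within_horizon", "fp_24_48", "fp_48_72", "fp_gt72", "fp_no_aki")


@dataclass
class AlertEvent:
    stay_id: str
    cutoff: float
    risk: float
    matched_onset: Optional[float]
    lead_time: Optional[float]
    fp_category: str


def extract_alerts(windows_df: pd.DataFrame, risks, onsets: dict,
                   pt: float, gap: float = 2.0, horizon: float = 24.0) -> list:
    """Alerts (risk >= pt) with true-positive/false-positive annotation.

    A true positive has the stay's onset inside its label interval
    (onset − cutoff ≤ gap + horizon); other alerts in onset stays are binned
    by time from cutoff to onset: (gap+horizon, 48] → fp_24_48,
    (48, 72] → fp_48_72, >72 → fp_gt72; alerts in AKI-free stays → fp_no_aki.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.size != len(windows_df) or np.any(~np.isfinite(risks)):
        raise InputError("one finite risk per window is required")
    tp_edge = gap + horizon
    alerts = []
    for (_, row), risk in zip(windows_df.iterrows(), risks):
        if risk < pt:
            continue
        onset = onsets.get(row["stay_id"])
        cutoff = float(row["cutoff"])
        if onset is None:
            cat, lead, matched = "fp_no_aki", None, None
        else:
            delta = onset - cutoff
            matched, lead = onset, delta
            if delta <= tp_edge:
                cat = "tp_within_horizon"
            elif delta <= 48.0:
                cat = "fp_24_48"
            elif delta <= 72.0:
                cat = "fp_48_72"
            else:
                cat = "fp_gt72"
        alerts.append(AlertEvent(stay_id=row["stay_id"], cutoff=cutoff,
                                 risk=float(risk), matched_onset=matched,
                                 lead_time=lead, fp_category=cat))
    return alerts


def lead_time_detection(alerts, onsets: dict,
                        bins=(6.0, 12.0, 18.0, 24.0)) -> pd.DataFrame:
    """Fraction of AKI events whose FIRST true-positive alert leads the
    onset by strictly more than each bin threshold.

    The denominator is every stay with an onset among the evaluated stays;
    events never alerted contribute zero to every bin.
    """
    events = {sid for sid, t in onsets.items() if t is not None}
    first_tp = {}
    for a in sorted(alerts, key=lambda a: a.cutoff):
        if a.fp_category == "tp_within_horizon" and a.stay_id not in first_tp:
            first_tp[a.stay_id] = a
    n_events = len(events)
    rows = []
    for h in bins:
        if n_events == 0:
            rate = 0.0
        else:
            detected = sum(1 for sid, a in first_tp.items()
                           if sid in events and a.lead_time > h)
            rate = detected / n_events
        rows.append({"lead_gt_hours": h, "detection_rate": rate,
                     "n_events": n_events})
    return pd.DataFrame(rows)


def burden_metrics(alerts, stays, gap: float = 2.0,
                   horizon: float = 24.0) -> dict:
    """Alert-burden summary over a set of stays.

    Coverage of one alert is [cutoff, cutoff + gap + horizon); a repeat
    alert is one issued while a previous alert's coverage is still active.
    Time under alert is the union of coverage intervals, reported raw and
    capped at discharge; rates are per patient-day and per 12 h shift.
    """
    los_days = sum(s.discharge_time for s in stays) / 24.0
    if los_days <= 0:
        raise InputError("zero total patient-days")
    disch_of = {s.stay_id: s.discharge_time for s in stays}
    cover = gap + horizon
    by_stay = {}
    for a in alerts:
        by_stay.setdefault(a.stay_id, []).append(a.cutoff)
    total_alerts = len(alerts)
    repeat = 0
    raw_hours = 0.0
    capped_hours = 0.0
    stays_ge1 = 0
    stays_ge2 = 0
    for sid, cutoffs in by_stay.items():
        cutoffs = sorted(cutoffs)
        stays_ge1 += 1
        if len(cutoffs) >= 2:
            stays_ge2 += 1
        active_end = -np.inf
        intervals = []
        for c in cutoffs:
            if c < active_end:
                repeat += 1
            active_end = max(active_end, c + cover)
            if intervals and c <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], max(intervals[-1][1], c + cover))
            else:
                intervals.append((c, c + cover))
        for lo, hi in intervals:
            raw_hours += hi - lo
            capped_hours += max(min(hi, disch_of.get(sid, hi)) - lo, 0.0)
    n_stays = len(stays)
    per_day = total_alerts / los_days
    return {
        "total_alerts": total_alerts,
        "alerts_per_patient_day": per_day,
        "alerts_per_shift": per_day / 2.0,
        "time_under_alert_raw_hours": raw_hours,
        "time_under_alert_capped_hours": capped_hours,
        "repeat_alert_fraction": repeat / total_alerts if total_alerts else 0.0,
        "frac_stays_ge1_alert": stays_ge1 / n_stays if n_stays else 0.0,
        "frac_stays_ge2_alerts": stays_ge2 / n_stays if n_stays else 0.0,
    }
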