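"""Time-respecting KDIGO staging and AKI onset detection.

Stages acute kidney injury from raw creatinine, urine-output, weight and
RRT streams, using only information available strictly before (baselines)
or exactly at (the measurement being staged) each assessment time.

Creatinine criteria, evaluated at each creatinine timestamp t:
  stage 1: SCr − min(SCr in [t−48 h, t)) ≥ 0.3 mg/dL, or
           SCr / min(SCr in [t−168 h, t)) in [1.5, 2.0)
  stage 2: ratio in [2.0, 3.0)
  stage 3: ratio ≥ 3.0
Urine-output criteria, from weight-normalized rolling rates (mL/kg/h):
  stage 1: rate over the prior 6 h  < 0.5
  stage 2: rate over the prior 12 h < 0.5
  stage 3: rate over the prior 24 h < 0.3, or 12 h rate = 0 (anuria)
RRT: stage 3 from the start of any renal-replacement episode.

A rolling rate is missing until a full lookback window fits inside the stay
(t ≥ W) and whenever no weight record exists at or before t.  The overall
stage at t is the maximum over computable components; the AKI onset is the
earliest assessment time (creatinine timestamps, the hourly grid, and RRT
starts) at which any criterion first fires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError

NOT_COMPUTABLE = -1

UO_WINDOWS = (6.0, 12.0, 24.0)


@dataclass
class ScrBaselines:
    t: float
    min48: Optional[float]   # minimum SCr in [t-48, t)
    min7d: Optional[float]   # minimum SCr in [t-168, t)


@dataclass
class UoRates:
    t: float
    rate6: Optional[float]
    rate12: Optional[float]
    rate24: Optional[float]
    weight_used: Optional[float]


@dataclass
class KdigoAssessment:
    t: float
    cr_stage: int      # 0..3 or NOT_COMPUTABLE
    uo_stage: int      # 0..3 or NOT_COMPUTABLE
    rrt_stage: int     # 0 or 3
    overall_stage: int  # 0..3 (NOT_COMPUTABLE components count as 0)


def _check_sorted(times: np.ndarray) -> None:
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise InputError("series must be sorted by time")


def baseline_scr(times, values, t: float) -> ScrBaselines:
    """Time-varying creatinine baselines from strictly prior measurements."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_sorted(times)
    prior = times < t
    m48 = prior & (times >= t - 48.0)
    m7d = prior & (times >= t - 168.0)
    min48 = float(values[m48].min()) if m48.any() else None
    min7d = float(values[m7d].min()) if m7d.any() else None
    return ScrBaselines(t=t, min48=min48, min7d=min7d)


def stage_creatinine(scr_value: float, baselines: ScrBaselines) -> int:
    """Highest creatinine stage satisfied at a measurement."""
    if not scr_value > 0:
        raise InputError("creatinine must be positive")
    if baselines.min48 is None and baselines.min7d is None:
        return NOT_COMPUTABLE
    stage = 0
    if baselines.min7d is not None:
        ratio = scr_value / baselines.min7d
        if ratio >= 3.0:
            stage = 3
        elif ratio >= 2.0:
            stage = 2
        elif ratio >= 1.5:
            stage = 1
    if baselines.min48 is not None and scr_value - baselines.min48 >= 0.3:
        stage = max(stage, 1)
    return stage


def uo_rates(uo_times, uo_vols, w_times, w_vals, t: float) -> UoRates:
    """Weight-normalized rolling urine-output rates over 6/12/24 h.

    rateW = sum of charted volume in [t−W, t) / (W · weight); missing while
    the lookback extends before admission (t < W) or when no weight record
    exists at or before t.
    """
    uo_times = np.asarray(uo_times, dtype=float)
    uo_vols = np.asarray(uo_vols, dtype=float)
    w_times = np.asarray(w_times, dtype=float)
    w_vals = np.asarray(w_vals, dtype=float)
    _check_sorted(uo_times)
    _check_sorted(w_times)
    if np.any(uo_vols < 0):
        raise InputError("urine volumes must be non-negative")
    prior_w = w_times <= t
    if not prior_w.any():
        return UoRates(t=t, rate6=None, rate12=None, rate24=None, weight_used=None)
    weight = float(w_vals[np.nonzero(prior_w)[0][-1]])
    rates = []
    for w in UO_WINDOWS:
        if t < w:
            rates.append(None)
            continue
        mask = (uo_times >= t - w) & (uo_times < t)
        rates.append(float(uo_vols[mask].sum() / (w * weight)))
    return UoRates(t=t, rate6=rates[0], rate12=rates[1], rate24=rates[2],
                   weight_used=weight)


def stage_urine(rates: UoRates) -> int:
    """Highest urine-output stage satisfied by the rolling rates."""
    if rates.rate6 is None and rates.rate12 is None and rates.rate24 is None:
        return NOT_COMPUTABLE
    stage = 0
    if rates.rate6 is not None and rates.rate6 < 0.5:
        stage = 1
    if rates.rate12 is not None and rates.rate12 < 0.5:
        stage = max(stage, 2)
    if rates.rate24 is not None and rates.rate24 < 0.3:
        stage = max(stage, 3)
    if rates.rate12 is not None and rates.rate12 == 0.0:
        stage = 3
    return stage


def _rrt_stage(rrt_episodes, t: float) -> int:
    return 3 if any(start <= t for start, _ in rrt_episodes) else 0


def assess(stay, t: float, criteria: str = "full") -> KdigoAssessment:
    """Full KDIGO assessment of one stay at time t.

    The creatinine component is computable only when a creatinine value was
    measured exactly at t (staging happens at laboratory timestamps).
    ``criteria`` restricts the components considered: "full",
    "creatinine_only", or "uo_only"; RRT always counts (dialysis is stage 3
    under any operationalization).
    """
    cr_stage = NOT_COMPUTABLE
    if criteria in ("full", "creatinine_only") and "creatinine" in stay.labs:
        ct, cv = stay.labs["creatinine"]
        ct = np.asarray(ct, dtype=float)
        at_t = np.isclose(ct, t, rtol=0, atol=1e-9)
        if at_t.any():
            base = baseline_scr(ct, cv, t)
            stages = [stage_creatinine(float(v), base)
                      for v in np.asarray(cv, dtype=float)[at_t]]
            cr_stage = max(stages)
    uo_stage = NOT_COMPUTABLE
    if criteria in ("full", "uo_only"):
        rates = uo_rates(*stay.urine_output, *stay.weights, t)
        uo_stage = stage_urine(rates)
    rrt = _rrt_stage(stay.rrt_episodes, t)
    overall = max(0, cr_stage, uo_stage, rrt)
    return KdigoAssessment(t=t, cr_stage=cr_stage, uo_stage=uo_stage,
                           rrt_stage=rrt, overall_stage=overall)


def assessment_grid(stay) -> np.ndarray:
    """Default assessment times: creatinine timestamps ∪ hourly grid ∪ RRT starts."""
    parts = [np.arange(0.0, np.floor(stay.discharge_time) + 1.0)]
    if "creatinine" in stay.labs:
        parts.append(np.asarray(stay.labs["creatinine"][0], dtype=float))
    if stay.rrt_episodes:
        parts.append(np.array([s for s, _ in stay.rrt_episodes], dtype=float))
    grid = np.unique(np.concatenate(parts))
    return grid[(grid >= 0) & (grid <= stay.discharge_time)]


def _cr_fire_times(stay) -> np.ndarray:
    """Vectorized creatinine criterion: times where cr_stage >= 1."""
    if "creatinine" not in stay.labs:
        return np.array([])
    t, v = stay.labs["creatinine"]
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_sorted(t)
    if np.any(v <= 0):
        raise InputError("creatinine must be positive")
    if t.size == 0:
        return np.array([])
    prior = t[None, :] < t[:, None]                     # prior[i, j]: t_j < t_i
    in48 = prior & (t[None, :] >= t[:, None] - 48.0)
    in7d = prior & (t[None, :] >= t[:, None] - 168.0)
    big = np.inf
    min48 = np.where(in48, v[None, :], big).min(axis=1)
    min7d = np.where(in7d, v[None, :], big).min(axis=1)
    fired = np.zeros(t.size, dtype=bool)
    has48 = np.isfinite(min48)
    has7d = np.isfinite(min7d)
    fired |= has48 & (v - min48 >= 0.3)
    fired |= has7d & (v >= 1.5 * min7d)
    return t[fired]


def _uo_stage_series(stay) -> tuple:
    """Vectorized urine-output staging on the hourly grid.

    Returns (grid_times, stages); stages use NOT_COMPUTABLE where no rate
    is computable.
    """
    n_hours = int(np.floor(stay.discharge_time))
    grid = np.arange(0.0, n_hours + 1.0)
    w_t, w_v = stay.weights
    w_t = np.asarray(w_t, dtype=float)
    if w_t.size == 0:
        return grid, np.full(grid.size, NOT_COMPUTABLE)
    uo_t, uo_v = stay.urine_output
    uo_t = np.asarray(uo_t, dtype=float)
    uo_v = np.asarray(uo_v, dtype=float)
    if np.any(uo_v < 0):
        raise InputError("urine volumes must be non-negative")
    # cumulative volume before each grid time
    order = np.searchsorted(uo_t, grid, side="left")
    csum = np.concatenate([[0.0], np.cumsum(uo_v)])
    vol_before = csum[order]
    w_idx = np.searchsorted(w_t, grid, side="right") - 1
    has_w = w_idx >= 0
    weight = np.where(has_w, np.asarray(w_v, dtype=float)[np.maximum(w_idx, 0)], np.nan)
    stages = np.zeros(grid.size, dtype=int)
    computable = np.zeros(grid.size, dtype=bool)
    rate = {}
    for w in UO_WINDOWS:
        lo = np.searchsorted(uo_t, grid - w, side="left")
        vol = vol_before - csum[lo]
        r = vol / (w * weight)
        valid = (grid >= w) & has_w
        r = np.where(valid, r, np.nan)
        rate[w] = r
        computable |= valid
    s = np.zeros(grid.size, dtype=int)
    with np.errstate(invalid="ignore"):
        s = np.where(rate[6.0] < 0.5, 1, s)
        s = np.where(rate[12.0] < 0.5, 2, s)
        s = np.where(rate[24.0] < 0.3, 3, s)
        s = np.where(rate[12.0] == 0.0, 3, s)
    stages = np.where(computable, s, NOT_COMPUTABLE)
    return grid, stages


def aki_onset(stay, assessment_times=None, criteria: str = "full") -> Optional[float]:
    """Earliest time any KDIGO criterion is met, or None.

    Uses vectorized component evaluations; ``assessment_times`` defaults to
    the creatinine timestamps, the hourly grid, and RRT episode starts.
    """
    candidates = []
    if criteria in ("full", "creatinine_only"):
        fired = _cr_fire_times(stay)
        if assessment_times is not None:
            at = np.asarray(assessment_times, dtype=float)
            fired = fired[np.isin(np.round(fired, 9), np.round(at, 9))]
        if fired.size:
            candidates.append(float(fired.min()))
    if criteria in ("full", "uo_only"):
        grid, stages = _uo_stage_series(stay)
        if assessment_times is not None:
            at = np.asarray(assessment_times, dtype=float)
            keep = np.isin(np.round(grid, 9), np.round(at, 9))
            grid, stages = grid[keep], stages[keep]
        fired = grid[stages >= 1]
        if fired.size:
            candidates.append(float(fired.min()))
    starts = [s for s, _ in stay.rrt_episodes if 0.0 <= s <= stay.discharge_time]
    if starts:
        candidates.append(float(min(starts)))
    if not candidates:
        return None
    return min(candidates)


def label_cohort(stays, criteria: str = "full") -> dict:
    """AKI onset per stay_id (None when no criterion ever fires)."""
    return {s.stay_id: aki_onset(s, criteria=criteria) for s in stays}
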