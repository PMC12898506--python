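"""Independent brute-force oracles used to cross-check the vectorized
implementations.  Everything here is deliberately written as plain Python
loops over raw arrays, sharing no code with the package internals."""

import numpy as np


# ---------------------------------------------------------------------------
# KDIGO staging, evaluated criterion-by-criterion at every timestamp

def brute_cr_stage_at(scr_times, scr_vals, t):
    """Creatinine stage at a lab timestamp t (-1 when not computable)."""
    vals_at_t = [v for tt, v in zip(scr_times, scr_vals) if abs(tt - t) < 1e-9]
    if not vals_at_t:
        return -1
    best = -1
    for scr in vals_at_t:
        prior48 = [v for tt, v in zip(scr_times, scr_vals)
                   if t - 48 <= tt < t]
        prior7d = [v for tt, v in zip(scr_times, scr_vals)
                   if t - 168 <= tt < t]
        if not prior48 and not prior7d:
            stage = -1
        else:
            stage = 0
            if prior7d:
                ratio = scr / min(prior7d)
                if ratio >= 3.0:
                    stage = 3
                elif ratio >= 2.0:
                    stage = 2
                elif ratio >= 1.5:
                    stage = 1
            if prior48 and scr - min(prior48) >= 0.3:
                stage = max(stage, 1)
        best = max(best, stage)
    return best


def brute_uo_stage_at(uo_times, uo_vols, w_times, w_vals, t):
    """Urine-output stage at time t (-1 when not computable)."""
    weights = [(wt, wv) for wt, wv in zip(w_times, w_vals) if wt <= t]
    if not weights:
        return -1
    weight = weights[-1][1]
    rates = {}
    for w in (6.0, 12.0, 24.0):
        if t < w:
            rates[w] = None
            continue
        vol = sum(v for tt, v in zip(uo_times, uo_vols) if t - w <= tt < t)
        rates[w] = vol / (w * weight)
    if all(r is None for r in rates.values()):
        return -1
    stage = 0
    if rates[6.0] is not None and rates[6.0] < 0.5:
        stage = 1
    if rates[12.0] is not None and rates[12.0] < 0.5:
        stage = max(stage, 2)
    if rates[24.0] is not None and rates[24.0] < 0.3:
        stage = 3
    if rates[12.0] is not None and rates[12.0] == 0.0:
        stage = 3
    return stage


def brute_onset(stay):
    """Earliest time any criterion fires, scanning every assessment time."""
    times = set(np.arange(0.0, np.floor(stay.discharge_time) + 1.0))
    if "creatinine" in stay.labs:
        times.update(float(t) for t in stay.labs["creatinine"][0])
    for start, _ in stay.rrt_episodes:
        if 0.0 <= start <= stay.discharge_time:
            times.add(float(start))
    ct, cv = stay.labs.get("creatinine", (np.array([]), np.array([])))
    uo_t, uo_v = stay.urine_output
    w_t, w_v = stay.weights
    fired = []
    for t in sorted(times):
        if t > stay.discharge_time:
            continue
        cr = brute_cr_stage_at(ct, cv, t)
        uo = brute_uo_stage_at(uo_t, uo_v, w_t, w_v, t)
        rrt = 3 if any(s <= t for s, _ in stay.rrt_episodes) else 0
        if max(0, cr, uo, rrt) >= 1:
            fired.append(t)
    return min(fired) if fired else None


# ---------------------------------------------------------------------------
# regression fits

def brute_ols_slope(t, y):
    """Slope from the closed-form normal equations."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    if n < 2 or len(set(t.tolist())) < 2:
        return None
    sx, sy = t.sum(), y.sum()
    sxx, sxy = (t * t).sum(), (t * y).sum()
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


def brute_psc(t, y):
    """Exhaustive two-segment continuous fit over candidate breakpoints."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 4:
        return None
    cands = [b for b in sorted(set(t.tolist()))
             if sum(tt < b for tt in t) >= 2 and sum(tt > b for tt in t) >= 2]
    best_sse, best_psc = None, None
    for b in cands:
        X = np.column_stack([np.ones(len(t)), t, np.maximum(t - b, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ beta) ** 2).sum())
        if best_sse is None or sse < best_sse:
            best_sse, best_psc = sse, float(beta[2])
    return best_psc


# ---------------------------------------------------------------------------
# window labels

def brute_window_labels(onset, cutoffs, gap=2.0, horizon=24.0):
    """Label per cutoff by direct interval membership."""
    labels = []
    for c in cutoffs:
        lo, hi = c + gap, c + gap + horizon
        labels.append(1 if (onset is not None and lo <= onset < hi) else 0)
    return labels


# ---------------------------------------------------------------------------
# AUC by exhaustive pair counting

def brute_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_auc_jackknife_variance(scores, labels):
    """DeLong structural-component variance via explicit placement values."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    m, n = len(pos), len(neg)
    v10 = [sum(1.0 if p > q else 0.5 if p == q else 0.0 for q in neg) / n
           for p in pos]
    v01 = [sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos) / m
           for q in neg]
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


# ---------------------------------------------------------------------------
# alert analytics by per-stay enumeration

def brute_alert_report(window_rows, risks, onsets, discharges, pt,
                       gap=2.0, horizon=24.0):
    """Full alert/lead-time/burden report from first principles.

    window_rows: list of (stay_id, cutoff); risks aligned; onsets/discharges
    keyed by stay_id.
    """
    cover = gap + horizon
    alerts = [(sid, c, r) for (sid, c), r in zip(window_rows, risks) if r >= pt]
    cats = {}
    for sid, c, r in alerts:
        onset = onsets.get(sid)
        if onset is None:
            cat = "fp_no_aki"
        else:
            d = onset - c
            if d <= cover:
                cat = "tp_within_horizon"
            elif d <= 48:
                cat = "fp_24_48"
            elif d <= 72:
                cat = "fp_48_72"
            else:
                cat = "fp_gt72"
        cats[(sid, c)] = cat
    # lead times: first TP alert per event stay
    events = [sid for sid, o in onsets.items() if o is not None]
    lead = {}
    for h in (6.0, 12.0, 18.0, 24.0):
        det = 0
        for sid in events:
            tps = sorted(c for (s, c), cat in cats.items()
                         if s == sid and cat == "tp_within_horizon")
            if tps and onsets[sid] - tps[0] > h:
                det += 1
        lead[h] = det / len(events) if events else 0.0
    # burden
    los_days = sum(discharges.values()) / 24.0
    per_stay = {}
    for sid, c, r in alerts:
        per_stay.setdefault(sid, []).append(c)
    repeats = 0
    raw = 0.0
    capped = 0.0
    ge1 = ge2 = 0
    for sid, cs in per_stay.items():
        cs = sorted(cs)
        ge1 += 1
        if len(cs) >= 2:
            ge2 += 1
        end = -1e18
        for c in cs:
            if c < end:
                repeats += 1
            end = max(end, c + cover)
        # union of intervals by sweeping a fine grid (1/32 h resolution)
        step = 1.0 / 32
        points = np.arange(min(cs), max(cs) + cover, step)
        covered = np.zeros(points.size, bool)
        for c in cs:
            covered |= (points >= c) & (points < c + cover)
        raw += covered.sum() * step
        capped += (covered & (points < discharges[sid])).sum() * step
    return {
        "categories": cats, "lead": lead,
        "total_alerts": len(alerts),
        "per_day": len(alerts) / los_days,
        "per_shift": len(alerts) / los_days / 2.0,
        "raw_hours": raw, "capped_hours": capped,
        "repeat_fraction": repeats / len(alerts) if alerts else 0.0,
        "ge1": ge1, "ge2": ge2,
    }
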