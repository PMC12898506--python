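"""Synthetic ICU cohort generator with known ground truth.

Emulates the structure of multi-center ICU event-stream extracts (stays,
vitals, labs, urine output, weights, treatments, RRT episodes) so the whole
early-warning pipeline — KDIGO labeling, rolling windows, trajectory
features, model training and alert analytics — is testable without any
credentialed data download.

Each stay carries a latent renal "insult" time drawn from a per-stay constant
hazard whose log is a baseline plus a linear combination of risk drivers
(hemodynamic downtrend pattern, oliguria pattern, sepsis, CKD, age).  After
the insult, creatinine rises quickly to a staged plateau and — in stays
carrying the oliguria driver — the urine-output rate drops below the KDIGO
threshold, so at least one staging criterion becomes satisfiable before
discharge.  Risk driver *patterns* (a mean-arterial-pressure downtrend, a
mild urine-output dip) are expressed whenever a stay carries the driver
flag; a pattern is anchored to the insult (as its physiologic prodrome)
only when the driver's effect size is non-zero.  With all effects zero the
drivers are biologically inert: patterns occur at random times, insults
arrive independently of every observable covariate, and the only
label-feature dependence left is the short (hours-scale) pre-onset tail of
the renal trajectory itself — a true null for the modeling stages.

Time axis: continuous hours from ICU admission (t = 0); all intervals
half-open [start, end).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError

VITAL_STREAMS = ("hr", "map", "sbp", "dbp", "rr", "temp", "spo2")
LAB_STREAMS = (
    "creatinine", "bun", "bicarbonate", "anion_gap", "wbc", "glucose",
    "hemoglobin", "platelets", "sodium", "potassium", "chloride",
)
COMORBIDITIES = (
    "ckd", "diabetes", "sepsis", "shock", "hypertension", "cirrhosis",
    "ami", "ahf", "contrast", "covid",
)
RACES = ("White", "Black", "Hispanic", "Asian", "Other")
UNIT_TYPES = ("MICU", "SICU", "CCU", "NeuroICU", "Trauma")

# latent grid resolution, hours
_VITAL_DT = 0.5
_LAB_DT = 1.0


@dataclass
class MissingnessPolicy:
    """Per-stream observation process.

    base_rates: expected charted observations per hour for each stream
    group (vitals are charted roughly hourly; labs are drawn every 8-12 h;
    urine output is charted hourly and near-complete).  severity_multiplier
    scales the lab/vital sampling rate after the latent insult — labs are
    ordered more often when clinical concern is high, which is exactly the
    informative (MNAR) sparsity the modeling stage must cope with.
    """

    base_rates: dict = field(default_factory=lambda: {
        "vitals": 0.9, "labs": 0.11, "urine_output": 4.0,
    })
    severity_multiplier: float = 2.0

    def validate(self) -> None:
        for key, rate in self.base_rates.items():
            if not rate > 0:
                raise ConfigurationError(f"sampling rate for {key!r} must be > 0")
        if self.severity_multiplier < 0:
            raise ConfigurationError("severity multiplier must be >= 0")


@dataclass
class SimConfig:
    n_patients: int = 200
    seed: int = 0
    # log(days): median 3.6 d matches a general adult ICU case-mix
    los_lognormal_params: tuple = (np.log(3.6), 0.65)
    baseline_insult_hazard: float = 0.0045  # per hour
    effect_sizes: dict = field(default_factory=lambda: {
        "map_downtrend": 0.9, "low_uo": 0.8, "sepsis_flag": 0.6,
        "ckd_flag": 0.5, "age": 0.3,
    })
    missingness_policy: MissingnessPolicy = field(default_factory=MissingnessPolicy)
    target_window_prevalence: Optional[float] = None
    # share of insults whose creatinine plateau lands in the stage 1/2/3 band
    stage_mix: tuple = (0.60, 0.25, 0.15)
    forced_insult_time: Optional[float] = None
    prodrome_lead: float = 10.0  # h of hemodynamic drift before the insult

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.baseline_insult_hazard < 0:
            raise ConfigurationError("baseline_insult_hazard must be >= 0")
        for name, eff in self.effect_sizes.items():
            if not np.isfinite(eff):
                raise ConfigurationError(f"effect size {name!r} must be finite")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9 or min(self.stage_mix) < 0:
            raise ConfigurationError("stage_mix must be a probability vector")
        self.missingness_policy.validate()


@dataclass
class StayRecord:
    """One ICU stay: static fields plus timestamped event streams.

    Streams are (times, values) float arrays sorted by time, hours from
    admission.  ``treatments`` rows are (drug, start, end); ``rrt_episodes``
    rows are (start, end).
    """

    patient_id: str
    stay_id: str
    age: Optional[float]
    age_masked: bool
    sex: str
    race: str
    unit_type: str
    comorbidities: dict
    eskd_status: Optional[int]
    discharge_time: float
    vitals: dict
    labs: dict
    urine_output: tuple
    weights: tuple
    treatments: list
    rrt_episodes: list
    latent_insult_time: Optional[float] = None
    admission_time: float = 0.0

    def stream(self, name: str) -> tuple:
        """Look up any timestamped stream by name."""
        if name in self.vitals:
            return self.vitals[name]
        if name in self.labs:
            return self.labs[name]
        if name == "urine_output":
            return self.urine_output
        if name == "weights":
            return self.weights
        raise KeyError(name)


@dataclass
class CohortBundle:
    stays: list
    config: SimConfig
    ground_truth: pd.DataFrame  # stay_id, patient_id, insult_time, intended_stage


def _stay_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: per-stay results stable under cohort-size changes
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _piecewise(t: np.ndarray, knots: list) -> np.ndarray:
    """Piecewise-linear latent trajectory through (time, value) knots."""
    kt = np.array([k[0] for k in knots])
    kv = np.array([k[1] for k in knots])
    return np.interp(t, kt, kv)


def _generate_stay(config: SimConfig, index: int) -> tuple:
    """Return (dense latent StayRecord, intended_stage)."""
    rng = _stay_rng(config.seed, index)
    pid = f"P{index:06d}"
    sid = f"S{index:06d}"

    # demographics -------------------------------------------------------
    u_age = rng.random()
    if u_age < 0.02:
        age, age_masked = None, True
    elif u_age < 0.07:
        age, age_masked = float(rng.uniform(89, 100)), False
    else:
        age, age_masked = float(rng.uniform(18, 88)), False
    sex = "F" if rng.random() < 0.46 else "M"
    race = RACES[rng.choice(len(RACES), p=[0.62, 0.13, 0.09, 0.05, 0.11])]
    unit = UNIT_TYPES[rng.choice(len(UNIT_TYPES), p=[0.35, 0.25, 0.15, 0.15, 0.10])]
    com_p = {"ckd": 0.12, "diabetes": 0.25, "sepsis": 0.17, "shock": 0.20,
             "hypertension": 0.55, "cirrhosis": 0.05, "ami": 0.08,
             "ahf": 0.12, "contrast": 0.02, "covid": 0.03}
    comorbidities = {k: int(rng.random() < p) for k, p in com_p.items()}
    u_eskd = rng.random()
    eskd_status = None if u_eskd < 0.02 else int(u_eskd < 0.035)
    weight0 = float(np.clip(rng.normal(82, 18), 40, 160))

    mu, sigma = config.los_lognormal_params
    los = float(np.clip(np.exp(rng.normal(mu, sigma)) * 24.0, 18.0, 21 * 24.0))

    # risk drivers and latent insult ------------------------------------
    map_down = int(rng.random() < 0.25)
    low_uo = int(rng.random() < 0.30)
    age_z = 0.0 if age is None else (age - 60.0) / 20.0
    eff = config.effect_sizes
    log_hr = (eff.get("map_downtrend", 0.0) * map_down
              + eff.get("low_uo", 0.0) * low_uo
              + eff.get("sepsis_flag", 0.0) * comorbidities["sepsis"]
              + eff.get("ckd_flag", 0.0) * comorbidities["ckd"]
              + eff.get("age", 0.0) * age_z)
    hazard = config.baseline_insult_hazard * float(np.exp(log_hr))
    u_exp = float(rng.exponential(1.0))  # common random number: monotone in hazard
    if config.forced_insult_time is not None:
        insult = float(config.forced_insult_time)
        if insult >= los:
            insult = None
    elif hazard > 0:
        insult = u_exp / hazard
        insult = float(insult) if insult < los else None
    else:
        insult = None

    intended_stage = 0
    plateau_mult = 1.0
    if insult is not None:
        band = rng.choice(3, p=list(config.stage_mix))
        intended_stage = int(band) + 1
        plateau_mult = float((rng.uniform(1.5, 1.9), rng.uniform(2.0, 2.9),
                              rng.uniform(3.0, 4.0))[band])

    # driver-pattern anchoring: a pattern acts as the insult's prodrome only
    # when its effect size is non-zero (inert drivers express at random times)
    rand_anchor_map = float(rng.uniform(0.0, max(los - 6.0, 1.0)))
    rand_anchor_uo = float(rng.uniform(0.0, max(los - 6.0, 1.0)))
    map_coupled = insult is not None and eff.get("map_downtrend", 0.0) != 0
    uo_coupled = insult is not None and eff.get("low_uo", 0.0) != 0
    map_anchor = insult if map_coupled else rand_anchor_map
    uo_anchor = insult if uo_coupled else rand_anchor_uo

    tv = np.arange(0.0, los, _VITAL_DT)
    tl = np.arange(0.0, los, _LAB_DT)

    # vitals -------------------------------------------------------------
    vitals = {}
    map_base = rng.normal(78, 9)
    map_knots = [(0.0, map_base), (los, map_base + rng.normal(0, 3))]
    if map_down:
        drop = rng.uniform(15, 30)
        t0 = max(map_anchor - config.prodrome_lead, 0.0)
        t1 = min(map_anchor + 4.0, los)
        map_knots = [(0.0, map_base), (t0, map_base),
                     (t1, map_base - drop), (los, map_base - drop * 0.7)]
        map_knots = sorted(map_knots)
    map_lat = _piecewise(tv, map_knots) + rng.normal(0, 4.5, tv.size)
    vitals["map"] = (tv, np.clip(map_lat, 35, 140))

    hr_base = rng.normal(84, 10)
    hr_knots = [(0.0, hr_base), (los, hr_base + rng.normal(0, 4))]
    if insult is not None:
        hr_knots = sorted([(0.0, hr_base), (insult, hr_base),
                           (min(insult + 12, los), hr_base + rng.uniform(8, 18)),
                           (los, hr_base + rng.uniform(5, 15))])
    vitals["hr"] = (tv, np.clip(_piecewise(tv, hr_knots) + rng.normal(0, 6, tv.size), 30, 200))

    sbp = vitals["map"][1] * 1.45 + rng.normal(0, 5, tv.size)
    dbp = vitals["map"][1] * 0.75 + rng.normal(0, 4, tv.size)
    vitals["sbp"] = (tv, np.clip(sbp, 50, 230))
    vitals["dbp"] = (tv, np.clip(dbp, 25, 130))
    rr_base = rng.normal(18, 2.5)
    rr_shift = rng.uniform(2, 6) if insult is not None else 0.0
    rr_knots = ([(0.0, rr_base), (los, rr_base)] if insult is None else
                sorted([(0.0, rr_base), (max(insult, 0.0), rr_base),
                        (min(insult + 10, los), rr_base + rr_shift), (los, rr_base + rr_shift)]))
    vitals["rr"] = (tv, np.clip(_piecewise(tv, rr_knots) + rng.normal(0, 1.5, tv.size), 6, 50))
    vitals["temp"] = (tv, np.clip(rng.normal(36.9, 0.4) + rng.normal(0, 0.25, tv.size), 34, 41))
    spo2_base = rng.normal(96.5, 1.2)
    spo2_knots = ([(0.0, spo2_base), (los, spo2_base)] if insult is None else
                  sorted([(0.0, spo2_base), (insult, spo2_base),
                          (min(insult + 12, los), spo2_base - rng.uniform(1, 3)),
                          (los, spo2_base - rng.uniform(0, 2))]))
    vitals["spo2"] = (tv, np.clip(_piecewise(tv, spo2_knots) + rng.normal(0, 0.9, tv.size), 70, 100))

    # labs ---------------------------------------------------------------
    labs = {}
    cr_base = rng.uniform(1.3, 2.5) if comorbidities["ckd"] else rng.uniform(0.6, 1.3)
    if insult is not None:
        # two-phase rise: the staging thresholds are crossed within ~3 h of
        # the insult, the plateau is reached by 18-36 h
        t_rise = rng.uniform(18, 36)
        delta = max(cr_base * (plateau_mult - 1.0), 0.35)
        rise1 = min(max(0.35, 0.5 * delta), delta)
        cr_knots = sorted([(0.0, cr_base), (insult, cr_base),
                           (min(insult + 3.0, los), cr_base + rise1),
                           (min(insult + t_rise, los), cr_base + delta),
                           (los, cr_base + delta)])
    else:
        cr_knots = [(0.0, cr_base), (los, cr_base)]
    cr = _piecewise(tl, cr_knots) + rng.normal(0, 0.04, tl.size)
    labs["creatinine"] = (tl, np.clip(cr, 0.2, None))

    bun_base = rng.uniform(10, 28) + (15 if comorbidities["ckd"] else 0)
    bun_lat = bun_base + 14.0 * (_piecewise(tl, cr_knots) - cr_base)
    labs["bun"] = (tl, np.clip(bun_lat + rng.normal(0, 1.6, tl.size), 2, None))

    def _shifted(base, post_shift, noise_sd, lo=None, hi=None):
        if insult is None or post_shift == 0:
            knots = [(0.0, base), (los, base)]
        else:
            knots = sorted([(0.0, base), (insult, base),
                            (min(insult + 18, los), base + post_shift),
                            (los, base + post_shift)])
        vals = _piecewise(tl, knots) + rng.normal(0, noise_sd, tl.size)
        return (tl, np.clip(vals, lo, hi))

    labs["bicarbonate"] = _shifted(rng.normal(24, 2), -rng.uniform(2, 5), 1.0, lo=5)
    labs["anion_gap"] = _shifted(rng.normal(12.5, 2), rng.uniform(2, 5), 1.0, lo=2)
    labs["wbc"] = _shifted(rng.normal(9.5, 2.5), rng.uniform(1, 4), 0.8, lo=0.5)
    labs["glucose"] = _shifted(rng.normal(132, 25), rng.uniform(10, 40), 8.0, lo=40)
    labs["hemoglobin"] = _shifted(rng.normal(11.2, 1.6), 0.0, 0.3, lo=4)
    labs["platelets"] = _shifted(rng.normal(225, 60), 0.0, 6.0, lo=10)
    labs["sodium"] = _shifted(rng.normal(139, 2.5), 0.0, 0.8, lo=115, hi=165)
    labs["potassium"] = _shifted(rng.normal(4.0, 0.35), rng.uniform(0.2, 0.7) if insult else 0.0, 0.12, lo=2)
    labs["chloride"] = _shifted(rng.normal(104, 3), 0.0, 0.9, lo=80, hi=130)

    # urine output: hourly latent rate (mL/kg/h) realized as charted boluses
    n_hours = int(np.floor(los))
    hours = np.arange(n_hours, dtype=float)
    uo_rate = rng.uniform(0.85, 1.6) + rng.normal(0, 0.08, n_hours).cumsum() * 0.05
    uo_rate = np.clip(uo_rate, 0.65, 2.5)
    mild_dur = rng.uniform(8, 14)
    deep_dur = rng.uniform(8, 14)
    deep_low = rng.uniform(0.15, 0.35)
    if low_uo:
        # pattern expression: a mild, sub-threshold decline; when the driver
        # is causally coupled this precedes the insult as its prodrome
        lead = config.prodrome_lead if uo_coupled else 0.0
        mask = (hours >= uo_anchor - lead) & (hours < uo_anchor + mild_dur)
        uo_rate[mask] = np.minimum(uo_rate[mask], rng.uniform(0.75, 0.9))
    if insult is not None and low_uo:
        # renal insult physiology: oliguria below the staging threshold
        mask = (hours >= insult) & (hours < insult + deep_dur)
        uo_rate[mask] = deep_low
    elif insult is not None:
        mask = (hours >= insult) & (hours < insult + 12)
        uo_rate[mask] = np.clip(uo_rate[mask] * 0.85, 0.6, None)
    uo_vol = uo_rate * weight0  # mL per hour
    # volume for hour (h, h+1] is charted at its end, t = h + 1
    uo_times = hours + 1.0
    keep = uo_times <= los
    urine_output = (uo_times[keep], np.clip(uo_vol[keep], 0, None))

    # weights: admission record plus one optional mid-stay remeasurement
    w_times = [0.0]
    w_vals = [weight0]
    if los > 48 and rng.random() < 0.5:
        w_times.append(float(rng.uniform(24, los - 1)))
        w_vals.append(float(np.clip(weight0 + rng.normal(0, 2.5), 40, 160)))
    weights = (np.array(w_times), np.array(w_vals))

    # treatments ---------------------------------------------------------
    treatments = []
    if comorbidities["shock"] or rng.random() < 0.05:
        start = float(rng.uniform(0, max(los / 2, 1)))
        end = float(min(start + rng.uniform(6, 48), los))
        treatments.append(("norepinephrine", start, end))
    if rng.random() < 0.05:
        start = float(rng.uniform(0, max(los - 6, 1)))
        treatments.append(("phenylephrine", start, float(min(start + rng.uniform(4, 24), los))))
    if comorbidities["contrast"]:
        start = float(rng.uniform(0, max(los - 1, 0.5)))
        treatments.append(("iv_contrast", start, min(start + 0.5, los)))

    # RRT ----------------------------------------------------------------
    rrt_episodes = []
    if rng.random() < 0.01:  # chronic/entry RRT (exclusion fodder)
        rrt_episodes.append((0.0, float(min(72.0, los))))
    elif insult is not None and intended_stage == 3 and rng.random() < 0.35:
        start = insult + rng.uniform(24, 40)
        if start < los:
            rrt_episodes.append((float(start), float(min(start + rng.uniform(24, 72), los))))

    stay = StayRecord(
        patient_id=pid, stay_id=sid, age=age, age_masked=age_masked, sex=sex,
        race=race, unit_type=unit, comorbidities=comorbidities,
        eskd_status=eskd_status, discharge_time=los, vitals=vitals, labs=labs,
        urine_output=urine_output, weights=weights, treatments=treatments,
        rrt_episodes=rrt_episodes, latent_insult_time=insult,
    )
    return stay, intended_stage


def apply_missingness(stay: StayRecord, policy: MissingnessPolicy,
                      rng: Optional[np.random.Generator] = None) -> StayRecord:
    """Thin dense latent streams into an irregular observed record.

    Each latent point survives independently with probability
    min(1, rate · Δt), where the rate is the stream group's base rate times
    the severity multiplier after the insult.  RRT episodes, weights and
    static fields are never thinned.
    """
    policy.validate()
    if rng is None:
        rng = np.random.default_rng(abs(hash(stay.stay_id)) % (2 ** 31))
    insult = stay.latent_insult_time
    mult = policy.severity_multiplier

    def _thin(times, values, rate, dt):
        p = np.full(times.shape, min(1.0, rate * dt))
        if insult is not None and mult != 1.0:
            post = times >= insult
            p[post] = np.minimum(1.0, rate * dt * mult)
        keep = rng.random(times.size) < p
        return times[keep], values[keep]

    vitals = {k: _thin(t, v, policy.base_rates["vitals"], _VITAL_DT)
              for k, (t, v) in stay.vitals.items()}
    labs = {k: _thin(t, v, policy.base_rates["labs"], _LAB_DT)
            for k, (t, v) in stay.labs.items()}
    uo_t, uo_v = stay.urine_output
    urine = _thin(uo_t, uo_v, policy.base_rates["urine_output"], 1.0)
    return dataclasses.replace(stay, vitals=vitals, labs=labs, urine_output=urine)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate ``config.n_patients`` stays (one stay per patient).

    Deterministic for a fixed config: per-stay generators are derived from
    the master seed by counter-based splitting.
    """
    config.validate()
    stays = []
    truth_rows = []
    for i in range(config.n_patients):
        latent, stage = _generate_stay(config, i)
        thin_rng = _stay_rng(config.seed, i + 1_000_000)
        stay = apply_missingness(latent, config.missingness_policy, rng=thin_rng)
        stays.append(stay)
        truth_rows.append({
            "stay_id": stay.stay_id, "patient_id": stay.patient_id,
            "insult_time": np.nan if stay.latent_insult_time is None else stay.latent_insult_time,
            "intended_stage": stage,
        })
    truth = pd.DataFrame(truth_rows)
    return CohortBundle(stays=stays, config=config, ground_truth=truth)


def calibrate_prevalence(config: SimConfig, target: float,
                         n_stays: int = 500, tol: float = 0.02,
                         max_iter: int = 10) -> SimConfig:
    """Bisect the baseline insult hazard until the realized window-level
    label prevalence is within ``tol`` of ``target``.

    Prevalence is estimated on ``n_stays`` simulated stays run through the
    full labeling + windowing pipeline.  Because insult times are generated
    from per-stay unit exponentials divided by the hazard, the realized
    prevalence is exactly non-decreasing in the baseline hazard, so higher
    targets can never return smaller hazards.
    """
    if not (0.0 < target < 0.5):
        raise ConfigurationError("target prevalence must lie in (0, 0.5)")
    from . import kdigo, windows  # local import: avoid a module cycle

    def realized(hazard: float) -> float:
        cfg = dataclasses.replace(
            config, n_patients=n_stays, baseline_insult_hazard=hazard)
        bundle = simulate_cohort(cfg)
        onsets = {s.stay_id: kdigo.aki_onset(s) for s in bundle.stays}
        kept, _ = windows.apply_exclusions(bundle.stays, onsets)
        frames = [windows.build_windows(s, onset=onsets[s.stay_id]) for s in kept]
        frames = [f for f in frames if len(f)]
        if not frames:
            return 0.0
        table = pd.concat(frames, ignore_index=True)
        return float(table["label"].mean())

    lo, hi = 1e-5, 0.15
    p_lo, p_hi = realized(lo), realized(hi)
    if not (p_lo - tol <= target <= p_hi + tol):
        raise ConfigurationError(
            f"target {target:.3f} unattainable; achievable prevalence range "
            f"is approximately [{p_lo:.3f}, {p_hi:.3f}]")
    best_h, best_p = hi, p_hi
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))  # bisect in log space
        p_mid = realized(mid)
        if abs(p_mid - target) < abs(best_p - target):
            best_h, best_p = mid, p_mid
        if abs(p_mid - target) <= tol:
            best_h, best_p = mid, p_mid
            break
        if p_mid < target:
            lo = mid
        else:
            hi = mid
    return dataclasses.replace(config, baseline_insult_hazard=best_h,
                               target_window_prevalence=target)


# ---------------------------------------------------------------------------
# table serialization

def _long_stream_table(stays, accessor) -> pd.DataFrame:
    rows = []
    for stay in stays:
        for name, (t, v) in accessor(stay).items():
            rows.append(pd.DataFrame({
                "stay_id": stay.stay_id, "time": t, "variable": name, "value": v}))
    if not rows:
        return pd.DataFrame(columns=["stay_id", "time", "variable", "value"])
    return pd.concat(rows, ignore_index=True)


def cohort_tables(bundle: CohortBundle) -> dict:
    """Render the cohort as the delimited tables the pipeline stages exchange.

    Units: times in hours from admission, creatinine mg/dL, urine mL,
    weight kg.
    """
    stays = bundle.stays
    stay_rows = []
    for s in stays:
        row = {
            "stay_id": s.stay_id, "patient_id": s.patient_id,
            "age": np.nan if s.age is None else s.age,
            "age_masked": int(s.age_masked), "sex": s.sex, "race": s.race,
            "unit_type": s.unit_type,
            "eskd_status": np.nan if s.eskd_status is None else s.eskd_status,
            "admission_time": s.admission_time, "discharge_time": s.discharge_time,
        }
        row.update(s.comorbidities)
        stay_rows.append(row)
    tables = {
        "stays": pd.DataFrame(stay_rows),
        "vitals": _long_stream_table(stays, lambda s: s.vitals),
        "labs": _long_stream_table(stays, lambda s: s.labs),
        "urine_output": pd.concat(
            [pd.DataFrame({"stay_id": s.stay_id, "time": s.urine_output[0],
                           "volume_ml": s.urine_output[1]}) for s in stays],
            ignore_index=True) if stays else pd.DataFrame(),
        "weights": pd.concat(
            [pd.DataFrame({"stay_id": s.stay_id, "time": s.weights[0],
                           "weight_kg": s.weights[1]}) for s in stays],
            ignore_index=True) if stays else pd.DataFrame(),
        "treatments": pd.DataFrame(
            [{"stay_id": s.stay_id, "drug": d, "start": a, "end": b}
             for s in stays for (d, a, b) in s.treatments],
            columns=["stay_id", "drug", "start", "end"]),
        "rrt": pd.DataFrame(
            [{"stay_id": s.stay_id, "start": a, "end": b}
             for s in stays for (a, b) in s.rrt_episodes],
            columns=["stay_id", "start", "end"]),
        "ground_truth": bundle.ground_truth,
    }
    return tables


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in cohort_tables(bundle).items():
        table.to_csv(out / f"{name}.csv", index=False)


def read_cohort(in_dir) -> list:
    """Load StayRecords from the delimited tables written by write_cohort."""
    p = Path(in_dir)
    stays_df = pd.read_csv(p / "stays.csv")
    streams = {}
    for fname, cols in (("vitals", ("variable", "value")),
                        ("labs", ("variable", "value"))):
        df = pd.read_csv(p / f"{fname}.csv")
        streams[fname] = {sid: g for sid, g in df.groupby("stay_id")}
    uo = pd.read_csv(p / "urine_output.csv")
    uo_g = {sid: g for sid, g in uo.groupby("stay_id")} if len(uo) else {}
    wt = pd.read_csv(p / "weights.csv")
    wt_g = {sid: g for sid, g in wt.groupby("stay_id")} if len(wt) else {}
    tr = pd.read_csv(p / "treatments.csv")
    tr_g = {sid: g for sid, g in tr.groupby("stay_id")} if len(tr) else {}
    rrt = pd.read_csv(p / "rrt.csv")
    rrt_g = {sid: g for sid, g in rrt.groupby("stay_id")} if len(rrt) else {}
    gt_path = p / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else None
    insults = ({} if gt is None else
               {r.stay_id: (None if pd.isna(r.insult_time) else float(r.insult_time))
                for r in gt.itertuples()})

    def _split(group_df, value_col):
        out = {}
        if group_df is None:
            return out
        for name, g in group_df.groupby("variable"):
            g = g.sort_values("time")
            out[name] = (g["time"].to_numpy(float), g[value_col].to_numpy(float))
        return out

    stays = []
    for r in stays_df.itertuples():
        sid = r.stay_id
        vit = _split(streams["vitals"].get(sid), "value")
        lab = _split(streams["labs"].get(sid), "value")
        g = uo_g.get(sid)
        uo_s = ((g.sort_values("time")["time"].to_numpy(float),
                 g.sort_values("time")["volume_ml"].to_numpy(float))
                if g is not None else (np.array([]), np.array([])))
        g = wt_g.get(sid)
        wt_s = ((g.sort_values("time")["time"].to_numpy(float),
                 g.sort_values("time")["weight_kg"].to_numpy(float))
                if g is not None else (np.array([]), np.array([])))
        g = tr_g.get(sid)
        treatments = ([(row.drug, float(row.start), float(row.end)) for row in g.itertuples()]
                      if g is not None else [])
        g = rrt_g.get(sid)
        rrt_eps = ([(float(row.start), float(row.end)) for row in g.itertuples()]
                   if g is not None else [])
        comorbidities = {c: int(getattr(r, c)) for c in COMORBIDITIES}
        stays.append(StayRecord(
            patient_id=r.patient_id, stay_id=sid,
            age=None if pd.isna(r.age) else float(r.age),
            age_masked=bool(r.age_masked), sex=r.sex, race=r.race,
            unit_type=r.unit_type, comorbidities=comorbidities,
            eskd_status=None if pd.isna(r.eskd_status) else int(r.eskd_status),
            discharge_time=float(r.discharge_time), vitals=vit, labs=lab,
            urine_output=uo_s, weights=wt_s, treatments=treatments,
            rrt_episodes=rrt_eps, latent_insult_time=insults.get(sid)))
    return stays


def bundle_digest(bundle: CohortBundle) -> str:
    """Stable content digest of a cohort (used by determinism checks)."""
    import hashlib
    h = hashlib.sha256()
    tables = cohort_tables(bundle)
    for name in sorted(tables):
        buf = io.StringIO()
        tables[name].to_csv(buf, index=False)
        h.update(name.encode())
        h.update(buf.getvalue().encode())
    return h.hexdigest()
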