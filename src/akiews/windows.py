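"""Rolling prediction windows, cohort exclusions, labels, and grouped folds.

Each eligible stay is expanded into overlapping prediction windows: a 12 h
feature window, a 2 h leakage gap, and a 24 h outcome horizon, refreshed
every 6 h.  A window's label is 1 iff the stay's first AKI onset falls in
[cutoff + gap, cutoff + gap + horizon); stays are censored at the first
onset, so no window's gap end extends past it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError

EXCLUSION_REASONS = ("age_out_of_range", "age_masked", "rrt_at_entry",
                     "prevalent_aki", "missing_status", "too_short")


@dataclass
class WindowScheme:
    feature_window: float = 12.0
    gap: float = 2.0
    horizon: float = 24.0
    stride: float = 6.0

    def validate(self) -> None:
        if min(self.feature_window, self.gap, self.horizon, self.stride) <= 0:
            raise ConfigurationError("all window-scheme fields must be positive")
        if self.gap >= self.horizon:
            raise ConfigurationError("gap must be smaller than horizon")

    @property
    def first_cutoff(self) -> float:
        # one full feature window after admission
        return self.feature_window


def apply_exclusions(stays, onsets: dict,
                     scheme: Optional[WindowScheme] = None,
                     age_range=(18.0, 88.0)):
    """Filter stays by eligibility; log the first triggered reason per stay.

    Exclusions, in priority order: age outside [18, 88]; privacy-masked age;
    RRT already running at ICU entry; AKI onset before the first eligible
    cutoff's gap end (prevalent AKI); missing ESKD/baseline status; stay too
    short to contain one feature window plus the gap.
    """
    scheme = scheme or WindowScheme()
    scheme.validate()
    min_horizon_start = scheme.first_cutoff + scheme.gap
    kept = []
    log_rows = []
    for stay in stays:
        reason = None
        onset = onsets.get(stay.stay_id)
        if stay.age_masked:
            reason = "age_masked"
        elif stay.age is None or not (age_range[0] <= stay.age <= age_range[1]):
            reason = "age_out_of_range"
        elif any(start <= 0.0 for start, _ in stay.rrt_episodes):
            reason = "rrt_at_entry"
        elif onset is not None and onset < min_horizon_start:
            reason = "prevalent_aki"
        elif stay.eskd_status is None:
            reason = "missing_status"
        elif stay.discharge_time < scheme.feature_window + scheme.gap:
            reason = "too_short"
        if reason is None:
            kept.append(stay)
        else:
            log_rows.append({"stay_id": stay.stay_id, "reason": reason})
    log = pd.DataFrame(log_rows, columns=["stay_id", "reason"])
    return kept, log


def build_windows(stay, scheme: Optional[WindowScheme] = None,
                  onset: Optional[float] = None) -> pd.DataFrame:
    """Prediction windows for one stay (columns: patient_id, stay_id,
    cutoff, label, horizon_start, horizon_end).

    Cutoffs run from the end of the first feature window in stride steps
    while cutoff + gap ≤ min(onset, discharge): windows whose gap would
    straddle the onset are dropped, so censoring holds by construction.
    Horizons extending past discharge are kept and labeled from observed
    data (a short stay without an onset contributes negatives).
    """
    scheme = scheme or WindowScheme()
    scheme.validate()
    limit = stay.discharge_time if onset is None else min(onset, stay.discharge_time)
    n = int(np.floor((limit - scheme.gap - scheme.first_cutoff) / scheme.stride))
    if limit - scheme.gap < scheme.first_cutoff:
        cutoffs = np.array([])
    else:
        cutoffs = scheme.first_cutoff + scheme.stride * np.arange(n + 1)
    rows = []
    for c in cutoffs:
        h_start = c + scheme.gap
        h_end = h_start + scheme.horizon
        label = int(onset is not None and h_start <= onset < h_end)
        rows.append({"patient_id": stay.patient_id, "stay_id": stay.stay_id,
                     "cutoff": float(c), "label": label,
                     "horizon_start": float(h_start), "horizon_end": float(h_end)})
    return pd.DataFrame(rows, columns=["patient_id", "stay_id", "cutoff",
                                       "label", "horizon_start", "horizon_end"])


def build_cohort_windows(stays, onsets: dict,
                         scheme: Optional[WindowScheme] = None) -> pd.DataFrame:
    frames = [build_windows(s, scheme=scheme, onset=onsets.get(s.stay_id))
              for s in stays]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["patient_id", "stay_id", "cutoff", "label",
                                     "horizon_start", "horizon_end"])
    return pd.concat(frames, ignore_index=True)


def assign_folds(windows_df: pd.DataFrame, k: int, seed: int) -> pd.Series:
    """Patient-grouped fold assignment: all windows from a patient share a
    fold; fold sizes are balanced within one patient."""
    if k < 2:
        raise ConfigurationError("need at least 2 folds")
    patients = np.sort(windows_df["patient_id"].unique())
    if patients.size < k:
        raise ConfigurationError(
            f"{patients.size} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients.size)
    fold_of = {patients[idx]: i % k for i, idx in enumerate(perm)}
    return windows_df["patient_id"].map(fold_of).astype(int)
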