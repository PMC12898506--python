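"""Event-level alert analytics against hand-enumerated and brute-force
expectations."""

import numpy as np
import pandas as pd
import pytest

from akiews import alerts
from akiews.errors import InputError
from conftest import make_stay
from oracles import brute_alert_report


def _windows_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "stay_id", "cutoff", "label"])


class TestCategories:
    def test_true_positives_within_horizon(self):
        win = _windows_frame([("P", "S", 12.0, 1), ("P", "S", 18.0, 1)])
        out = alerts.extract_alerts(win, [0.8, 0.9], {"S": 30.0}, pt=0.5)
        assert [a.fp_category for a in out] == ["tp_within_horizon"] * 2
        assert out[0].lead_time == pytest.approx(18.0)

    def test_distant_onset_binned(self):
        win = _windows_frame([("P", "S", 10.0, 0)])
        out = alerts.extract_alerts(win, [0.9], {"S": 70.0}, pt=0.5)
        assert out[0].fp_category == "fp_48_72"    # onset - cutoff = 60

    def test_alert_without_aki(self):
        win = _windows_frame([("P", "S", 12.0, 0)])
        out = alerts.extract_alerts(win, [0.9], {"S": None}, pt=0.5)
        assert out[0].fp_category == "fp_no_aki"

    def test_boundary_bins(self):
        onsets = {"S": 100.0}
        for cutoff, expected in [(74.0, "tp_within_horizon"),  # delta 26
                                 (52.0, "fp_24_48"),           # delta 48
                                 (28.0, "fp_48_72"),           # delta 72
                                 (20.0, "fp_gt72")]:           # delta 80
            win = _windows_frame([("P", "S", cutoff, 0)])
            out = alerts.extract_alerts(win, [0.9], onsets, pt=0.5)
            assert out[0].fp_category == expected, cutoff

    def test_missing_risk_rejected(self):
        win = _windows_frame([("P", "S", 12.0, 0)])
        with pytest.raises(InputError):
            alerts.extract_alerts(win, [np.nan], {"S": None}, pt=0.5)


class TestLeadTime:
    def test_strict_bin_membership(self):
        win = _windows_frame([("P", "S", 12.0, 1)])
        out = alerts.extract_alerts(win, [0.9], {"S": 30.0}, pt=0.5)
        table = alerts.lead_time_detection(out, {"S": 30.0})
        rates = dict(zip(table["lead_gt_hours"], table["detection_rate"]))
        # first alert lead = 18.0: counted in >6 and >12, not >18 (strict)
        assert rates == {6.0: 1.0, 12.0: 1.0, 18.0: 0.0, 24.0: 0.0}

    def test_no_alerts_gives_zero_rates(self):
        table = alerts.lead_time_detection([], {"S": 30.0})
        assert (table["detection_rate"] == 0.0).all()

    def test_first_alert_defines_lead(self):
        win = _windows_frame([("P", "S", 12.0, 1), ("P", "S", 18.0, 1)])
        out = alerts.extract_alerts(win, [0.9, 0.9], {"S": 33.0}, pt=0.5)
        table = alerts.lead_time_detection(out, {"S": 33.0})
        rates = dict(zip(table["lead_gt_hours"], table["detection_rate"]))
        assert rates[18.0] == 1.0    # first alert at 12 h, lead 21 h
        assert rates[24.0] == 0.0


class TestBurden:
    def test_rate_arithmetic(self):
        stays = [make_stay("A", discharge=48.0), make_stay("B", discharge=48.0)]
        win = _windows_frame([("P", "A", 12.0, 0), ("P", "B", 12.0, 0)])
        out = alerts.extract_alerts(win, [0.9, 0.9], {"A": None, "B": None}, pt=0.5)
        rep = alerts.burden_metrics(out, stays)
        assert rep["alerts_per_patient_day"] == pytest.approx(0.5)
        assert rep["alerts_per_shift"] == pytest.approx(0.25)

    def test_repeat_and_union_coverage(self):
        stays = [make_stay("A", discharge=96.0)]
        win = _windows_frame([("P", "A", 12.0, 0), ("P", "A", 18.0, 0)])
        out = alerts.extract_alerts(win, [0.9, 0.9], {"A": None}, pt=0.5)
        rep = alerts.burden_metrics(out, stays)
        assert rep["repeat_alert_fraction"] == pytest.approx(0.5)
        assert rep["time_under_alert_raw_hours"] == pytest.approx(32.0)
        assert rep["frac_stays_ge2_alerts"] == 1.0

    def test_coverage_capped_at_discharge(self):
        stays = [make_stay("A", discharge=40.0)]
        win = _windows_frame([("P", "A", 12.0, 0), ("P", "A", 18.0, 0)])
        out = alerts.extract_alerts(win, [0.9, 0.9], {"A": None}, pt=0.5)
        rep = alerts.burden_metrics(out, stays)
        # union coverage [12, 44) = 32 h raw; capped at the 40 h discharge
        assert rep["time_under_alert_raw_hours"] == pytest.approx(32.0)
        assert rep["time_under_alert_capped_hours"] == pytest.approx(28.0)

    def test_zero_patient_days_rejected(self):
        with pytest.raises(InputError):
            alerts.burden_metrics([], [])


class TestBruteForceFixture:
    def test_twenty_stay_enumeration(self):
        rng = np.random.default_rng(20)
        stays = []
        onsets = {}
        rows = []
        risks = []
        for i in range(20):
            sid = f"S{i}"
            disch = float(rng.uniform(40, 140))
            stays.append(make_stay(sid, patient_id=f"P{i}", discharge=disch))
            onset = float(rng.uniform(20, disch)) if rng.random() < 0.5 else None
            onsets[sid] = onset
            limit = disch if onset is None else min(onset, disch)
            c = 12.0
            while c + 2.0 <= limit:
                label = int(onset is not None and c + 2 <= onset < c + 26)
                rows.append((f"P{i}", sid, c, label))
                risks.append(float(rng.random()))
                c += 6.0
        win = _windows_frame(rows)
        pt = 0.6
        out = alerts.extract_alerts(win, risks, onsets, pt=pt)
        lead = alerts.lead_time_detection(out, onsets)
        burden = alerts.burden_metrics(out, stays)
        ref = brute_alert_report([(r[1], r[2]) for r in rows], risks, onsets,
                                 {s.stay_id: s.discharge_time for s in stays}, pt)
        # categories
        got_cats = {(a.stay_id, a.cutoff): a.fp_category for a in out}
        assert got_cats == ref["categories"]
        counts = pd.Series([a.fp_category for a in out]).value_counts().sum()
        assert counts == burden["total_alerts"] == ref["total_alerts"]
        # lead-time rates
        got_rates = dict(zip(lead["lead_gt_hours"], lead["detection_rate"]))
        for h, rate in ref["lead"].items():
            assert got_rates[h] == pytest.approx(rate)
        # rates non-increasing in h
        vals = [got_rates[h] for h in (6.0, 12.0, 18.0, 24.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        # burden
        assert burden["alerts_per_patient_day"] == pytest.approx(ref["per_day"])
        assert burden["alerts_per_shift"] == pytest.approx(ref["per_shift"])
        assert burden["repeat_alert_fraction"] == pytest.approx(ref["repeat_fraction"])
        assert burden["frac_stays_ge1_alert"] == pytest.approx(ref["ge1"] / 20)
        assert burden["frac_stays_ge2_alerts"] == pytest.approx(ref["ge2"] / 20)
        # oracle sweeps a 1/32 h grid: allow one grid step per stay
        assert burden["time_under_alert_raw_hours"] == pytest.approx(
            ref["raw_hours"], abs=20 / 32)
        assert burden["time_under_alert_capped_hours"] == pytest.approx(
            ref["capped_hours"], abs=20 / 32)
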