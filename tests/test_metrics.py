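"""Discrimination, calibration, decision-curve, DeLong and balance metrics."""

import numpy as np
import pytest

from akiews import metrics
from akiews.errors import InputError
from oracles import brute_auc, brute_auc_jackknife_variance


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        risks = np.array([0.9, 0.95, 0.05, 0.1])
        labels = np.array([1, 1, 0, 0])
        m = metrics.confusion_metrics(risks, labels, 0.5)
        for key in ("recall", "specificity", "precision", "f1", "f2",
                    "balanced_accuracy", "mcc"):
            assert m[key] == pytest.approx(1.0)
        assert m["brier"] < 0.01

    def test_single_class_flags_undefined(self):
        m = metrics.confusion_metrics(np.array([0.2, 0.3]), np.array([0, 0]), 0.5)
        assert "recall" in m["undefined"]
        assert np.isnan(m["recall"])

    def test_balanced_accuracy_definition(self):
        risks = np.array([0.9, 0.1, 0.9, 0.1, 0.9])
        labels = np.array([1, 1, 0, 0, 0])
        m = metrics.confusion_metrics(risks, labels, 0.5)
        assert m["balanced_accuracy"] == pytest.approx(
            (m["recall"] + m["specificity"]) / 2)


class TestRankMetrics:
    def test_score_reversal_antisymmetry(self):
        rng = np.random.default_rng(0)
        risks = rng.random(500)
        labels = (rng.random(500) < 0.3).astype(int)
        auc, _ = metrics.rank_metrics(risks, labels)
        auc_rev, _ = metrics.rank_metrics(1 - risks, labels)
        assert auc_rev == pytest.approx(1 - auc)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(1)
        risks = np.round(rng.random(60), 1)     # force ties
        labels = (rng.random(60) < 0.4).astype(int)
        auc, _ = metrics.rank_metrics(risks, labels)
        assert auc == pytest.approx(brute_auc(risks, labels), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        risks = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        auc, _ = metrics.rank_metrics(risks, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            metrics.rank_metrics(np.array([0.1, 0.2]), np.array([1, 1]))


class TestClusterBootstrap:
    def test_single_cluster_degenerate(self):
        ci = metrics.cluster_bootstrap(
            lambda x: x.mean(), np.zeros(10), [np.arange(10.0)], B=50, seed=0)
        assert ci.lo == ci.hi == pytest.approx(4.5)
        assert ci.degenerate

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        cl = rng.integers(0, 20, 200)
        a = metrics.cluster_bootstrap(lambda v: v.mean(), cl, [x], B=100, seed=9)
        b = metrics.cluster_bootstrap(lambda v: v.mean(), cl, [x], B=100, seed=9)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_invalid_replicates_counted(self):
        # statistic undefined whenever the resample lacks positives
        x = np.array([1.0] + [0.0] * 9)
        cl = np.arange(10)

        def frac_pos(v):
            if v.sum() == 0:
                raise ValueError("no positives")
            return v.mean()

        ci = metrics.cluster_bootstrap(frac_pos, cl, [x], B=200, seed=1)
        assert ci.n_invalid > 0

    def test_ci_width_shrinks_with_clusters(self):
        rng = np.random.default_rng(4)
        widths = []
        for n_cl in (10, 40, 160):
            effects = rng.normal(0, 1, n_cl)
            x = np.concatenate([e + rng.normal(0, 0.5, 5) for e in effects])
            cl = np.repeat(np.arange(n_cl), 5)
            ci = metrics.cluster_bootstrap(lambda v: v.mean(), cl, [x],
                                           B=300, seed=5)
            widths.append(ci.hi - ci.lo)
        assert widths[0] > widths[1] > widths[2]


class TestCalibration:
    def test_constant_risk_at_prevalence(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(4000) < 0.25).astype(int)
        prev = labels.mean()
        rep = metrics.calibration_suite(np.full(labels.size, prev), labels)
        assert rep["citl"] == pytest.approx(0.0, abs=1e-6)
        assert rep["ece"] == pytest.approx(0.0, abs=1e-12)

    def test_brier_closed_form_for_prevalence_forecast(self):
        rng = np.random.default_rng(6)
        labels = (rng.random(20_000) < 0.3).astype(int)
        prev = labels.mean()
        rep = metrics.calibration_suite(np.full(labels.size, prev), labels)
        assert rep["brier"] == pytest.approx(prev * (1 - prev), abs=1e-9)

    def test_extreme_risks_clipped_with_warning(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.warns(UserWarning):
            metrics.calibration_suite(np.array([0.0, 1.0, 0.2, 0.8]), labels)


class TestNetBenefit:
    def test_threshold_weight(self):
        assert metrics.threshold_weight(0.125) == pytest.approx(0.143, abs=5e-4)

    def test_treat_all_from_printed_prevalences(self):
        assert round(metrics.nb_treat_all(0.171, 0.125), 3) == 0.053
        assert round(metrics.nb_treat_all(0.142, 0.125), 3) == 0.019

    def test_low_threshold_limits(self):
        rng = np.random.default_rng(7)
        risks = rng.random(2000)
        labels = (rng.random(2000) < 0.2).astype(int)
        prev = labels.mean()
        assert metrics.nb_treat_all(prev, 1e-6) == pytest.approx(prev, abs=1e-4)
        nb = metrics.net_benefit(risks, labels, 1e-6)
        assert nb == pytest.approx(prev, abs=1e-4)   # everyone alerts, TP/N -> pi

    def test_model_nb_bounded_by_prevalence(self):
        rng = np.random.default_rng(8)
        risks = rng.random(3000)
        labels = (rng.random(3000) < risks).astype(int)
        prev = labels.mean()
        for pt in (0.05, 0.125, 0.3, 0.6):
            assert metrics.net_benefit(risks, labels, pt) <= prev + 1e-12

    def test_perfect_predictor_dominates(self):
        rng = np.random.default_rng(9)
        labels = (rng.random(4000) < 0.2).astype(int)
        risks = labels.astype(float) * 0.98 + 0.01
        curve = metrics.dca_curve(risks, labels, np.linspace(0.02, 0.9, 15))
        assert (curve["nb_model"] >= curve["nb_treat_all"] - 1e-12).all()
        assert (curve["nb_model"] >= -1e-12).all()


class TestDeLong:
    def test_identical_groups(self):
        rng = np.random.default_rng(10)
        risks = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        res = metrics.delong_compare(risks, labels, risks, labels)
        assert res["auc1"] == res["auc2"]
        assert res["p"] == pytest.approx(1.0)

    def test_variance_matches_placement_oracle(self):
        rng = np.random.default_rng(11)
        risks = np.round(rng.random(40), 1)
        labels = (rng.random(40) < 0.5).astype(int)
        auc, var = metrics._auc_and_variance(risks, labels)
        assert auc == pytest.approx(brute_auc(risks, labels), abs=1e-12)
        assert var == pytest.approx(
            brute_auc_jackknife_variance(risks, labels), abs=1e-6)

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(12)
        r1 = rng.random(300)
        y1 = (rng.random(300) < r1).astype(int)
        r2 = rng.random(300)
        y2 = rng.integers(0, 2, 300)
        res = metrics.delong_compare(r1, y1, r2, y2, m_comparisons=20)
        assert res["p_bonferroni"] == pytest.approx(min(1.0, res["p"] * 20))


class TestAsmd:
    def test_identical_distributions(self):
        x = np.arange(50.0)
        assert metrics.asmd(x, x) == pytest.approx(0.0)

    def test_equal_binary_proportions(self):
        a = np.array([0, 1] * 25)
        assert metrics.asmd(a, a, binary=True) == pytest.approx(0.0)

    def test_unit_shift_closed_form(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 200_000)
        b = rng.normal(1, 1, 200_000)
        assert metrics.asmd(a, b) == pytest.approx(1.0, abs=0.02)

    def test_zero_spread_unequal_means_flagged(self):
        assert metrics.asmd(np.ones(5), np.full(5, 2.0)) == np.inf
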