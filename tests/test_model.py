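"""Constrained boosting, SHAP selection, Platt scaling, and the operating
threshold."""

import numpy as np
import pandas as pd
import pytest

from akiews import model
from akiews.errors import ConfigurationError, InputError

GRID1 = [{"max_depth": 3, "eta": 0.2, "subsample": 0.9,
          "colsample_bytree": 0.9, "min_child_weight": 3,
          "num_boost_round": 60}]


def _synthetic_frame(n=2500, n_noise=10, seed=0, beta=None):
    """Logistic data with named informative features and noise columns."""
    rng = np.random.default_rng(seed)
    beta = beta if beta is not None else [1.2, -1.0, 0.8]
    X = pd.DataFrame({f"signal_{i}": rng.normal(size=n)
                      for i in range(len(beta))})
    lin = -1.5 + sum(b * X[f"signal_{i}"] for i, b in enumerate(beta))
    y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
    for j in range(n_noise):
        X[f"noise_{j}"] = rng.normal(size=n)
    folds = rng.integers(0, 4, n)
    return X, y, folds


class TestTuneAndTrain:
    def test_grid_of_one_wins(self):
        X, y, folds = _synthetic_frame(n=800)
        bundle, oof = model.tune_and_train(X, y, folds, grid=GRID1, seed=0)
        assert bundle.params["max_depth"] == 3
        assert np.isfinite(oof["raw_risk"]).all()

    def test_each_row_predicted_out_of_fold(self):
        X, y, folds = _synthetic_frame(n=600)
        # leakage check: permuting one validation fold's labels must not
        # change that fold's predictions (they come from other folds' model)
        bundle, oof = model.tune_and_train(X, y, folds, grid=GRID1, seed=0)
        y2 = y.copy()
        mask = folds == 0
        y2[mask] = np.random.default_rng(1).permutation(y2[mask])
        if len(np.unique(y2[~mask])) < 2:
            pytest.skip("degenerate permutation")
        bundle2, oof2 = model.tune_and_train(X, y2, folds, grid=GRID1, seed=0)
        np.testing.assert_allclose(oof.loc[mask, "raw_risk"],
                                   oof2.loc[mask, "raw_risk"], rtol=1e-6)

    def test_single_class_fold_rejected(self):
        X, y, folds = _synthetic_frame(n=200)
        y_bad = np.zeros_like(y)
        y_bad[folds == 0] = 1  # every other training split sees one class
        with pytest.raises(InputError, match="fold"):
            model.tune_and_train(X, y_bad, folds, grid=GRID1, seed=0)


class TestMonotone:
    def test_constrained_sweeps_clean(self):
        X, y, folds = _synthetic_frame(n=2000, seed=3)
        constraints = {"signal_0": +1, "signal_1": -1}
        bundle, _ = model.tune_and_train(X, y, folds, grid=GRID1,
                                         constraints=constraints, seed=0)
        report = model.enforce_monotone(bundle, X.iloc[:50], n_grid=20)
        assert report.empty

    def test_unconstrained_feature_not_asserted(self):
        X, y, folds = _synthetic_frame(n=800, seed=3)
        bundle, _ = model.tune_and_train(X, y, folds, grid=GRID1,
                                         constraints={"signal_0": +1}, seed=0)
        report = model.enforce_monotone(bundle, X.iloc[:30])
        assert set(report["feature"]) <= {"signal_0"}


class TestShapSelection:
    def test_informative_features_retained(self):
        X, y, folds = _synthetic_frame(n=3000, n_noise=50, seed=5,
                                       beta=[1.5, -1.2, 1.0, 0.9, -0.8])
        bundle, _ = model.tune_and_train(X, y, folds, grid=GRID1, seed=0)
        selected, new_bundle, new_oof, delta = model.shap_select(
            X, y, folds, bundle, k=10, seed=0)
        assert {f"signal_{i}" for i in range(5)} <= set(selected)
        assert delta["delta"] >= -0.02

    def test_identity_selection_is_noop(self):
        X, y, folds = _synthetic_frame(n=800, seed=6)
        bundle, oof = model.tune_and_train(X, y, folds, grid=GRID1, seed=0)
        selected, nb, new_oof, delta = model.shap_select(
            X, y, folds, bundle, k=X.shape[1], seed=0)
        assert set(selected) == set(X.columns)
        assert delta["delta"] == pytest.approx(0.0, abs=1e-12)

    def test_k_too_large_rejected(self):
        X, y, folds = _synthetic_frame(n=300)
        bundle, _ = model.tune_and_train(X, y, folds, grid=GRID1, seed=0)
        with pytest.raises(ConfigurationError):
            model.shap_select(X, y, folds, bundle, k=999)


class TestPlatt:
    def test_constant_risk_maps_to_prevalence(self):
        rng = np.random.default_rng(0)
        y = (rng.random(5000) < 0.3).astype(int)
        a, b = model.platt_fit(np.full(y.size, 0.5), y)
        recal = model.platt_apply(np.array([0.5]), a, b)
        assert recal[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_calibrated_input_recovers_identity(self):
        rng = np.random.default_rng(1)
        p = 1 / (1 + np.exp(-rng.normal(-1.0, 1.5, 60_000)))
        y = (rng.random(p.size) < p).astype(int)
        a, b = model.platt_fit(p, y)
        assert 0.9 <= b <= 1.1
        assert -0.1 <= a <= 0.1

    def test_refit_on_recalibrated_is_near_identity(self):
        rng = np.random.default_rng(2)
        z = rng.normal(-1.0, 1.2, 60_000)
        p_true = 1 / (1 + np.exp(-z))
        raw = 1 / (1 + np.exp(-(0.4 + 0.7 * z)))    # miscalibrated scores
        y = (rng.random(z.size) < p_true).astype(int)
        a, b = model.platt_fit(raw, y)
        recal = model.platt_apply(raw, a, b)
        a2, b2 = model.platt_fit(recal, y)
        assert 0.95 <= b2 <= 1.05

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            model.platt_fit(np.array([0.2, 0.4]), np.array([1, 1]))


class TestThreshold:
    def test_perfect_separation(self):
        risks = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        pt = model.choose_threshold(risks, labels)
        assert pt == 0.8   # smallest threshold with F2 = 1
        from akiews.metrics import confusion_metrics
        assert confusion_metrics(risks, labels, pt)["f2"] == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        risks = np.round(rng.random(300), 2)
        labels = (rng.random(300) < risks).astype(int)
        pt = model.choose_threshold(risks, labels, beta=2.0)
        from akiews.metrics import confusion_metrics

        def f2_at(c):
            m = confusion_metrics(risks, labels, c)
            return m["f2"] if np.isfinite(m["f2"]) else -1.0

        best = max(sorted(set(risks)), key=lambda c: (f2_at(c), -c))
        assert pt == best
        assert f2_at(pt) == pytest.approx(max(f2_at(c) for c in set(risks)))

    def test_f2_threshold_not_above_f1_threshold(self):
        rng = np.random.default_rng(9)
        z = rng.normal(-2.0, 1.0, 4000)
        risks = 1 / (1 + np.exp(-z))
        labels = (rng.random(z.size) < risks).astype(int)
        t2 = model.choose_threshold(risks, labels, beta=2.0)
        t1 = model.choose_threshold(risks, labels, beta=1.0)
        assert t2 <= t1


class TestBundleRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        X, y, folds = _synthetic_frame(n=500)
        bundle, oof = model.tune_and_train(X, y, folds, grid=GRID1,
                                           constraints={"signal_0": +1}, seed=0)
        bundle.platt = model.platt_fit(oof["raw_risk"], y)
        bundle.save(tmp_path / "m")
        loaded = model.ModelBundle.load(tmp_path / "m")
        np.testing.assert_allclose(bundle.predict_risk(X.iloc[:20]),
                                   loaded.predict_risk(X.iloc[:20]), rtol=1e-6)
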