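"""Candidate extraction, features, SVM classification and co-occurrence."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from ibikit import (
    ApnoeaClassifier,
    FilteredIP,
    IBISeries,
    SimulationConfig,
    compute_ibis,
    compute_metrics,
    cooccurrence_events,
    detect_breaths,
    extract_candidates,
    extract_features,
    find_bradycardias,
    inject_pause,
    loso_cv,
    preprocess,
    simulate_feature_set,
    simulate_recording,
    train_classifier,
)
from ibikit.apnoea import ApnoeaCandidate

RATE = 62.5


class TestExtractCandidates:
    def test_threshold_is_inclusive(self):
        ibis = IBISeries([0.0, 30.0, 60.0], [19.9, 50.0, 85.0], [True, True, True])
        cands = extract_candidates(ibis)
        assert [round(c.duration, 1) for c in cands] == [20.0, 25.0]

    def test_invalid_interval_excluded(self):
        ibis = IBISeries([0.0], [30.0], [False])
        assert extract_candidates(ibis) == []

    def test_simulated_candidates_counted(self):
        cfg = SimulationConfig(duration=400, seed=23)
        rec, truth = simulate_recording(cfg)
        rec, truth = inject_pause(rec, truth, 60, 25, "apnoea-no-response")
        rec, truth = inject_pause(rec, truth, 170, 22, "apnoea-with-response", hr_response=90)
        rec, truth = inject_pause(rec, truth, 290, 25, "low-amplitude-false-alarm")
        f = preprocess(rec)
        ibis = compute_ibis(detect_breaths(f), f.artefact_mask, f.rate)
        assert len(extract_candidates(ibis)) == 3


class TestExtractFeatures:
    def _filtered(self, x):
        return FilteredIP(x, RATE, np.zeros(x.size, dtype=bool), np.full(x.size, 2.5))

    def test_silent_apnoea_zero_rms(self):
        n = int(120 * RATE)
        x = np.zeros(n)
        c = ApnoeaCandidate("s", 40.0, 65.0)
        hr = np.full(120, 150.0)
        feats = extract_features(c, self._filtered(x), hr, np.full(120, 97.0))
        assert feats.rms_during == 0.0

    def test_hr_drop_arithmetic(self):
        n = int(150 * RATE)
        x = np.sin(2 * np.pi * 0.75 * np.arange(n) / RATE)
        hr = np.full(150, 160.0)
        hr[45:70] = 100.0  # minimum inside the 60 s response window
        c = ApnoeaCandidate("s", 40.0, 65.0)
        feats = extract_features(c, self._filtered(x), hr, np.full(150, 97.0))
        assert feats.delta_hr60 == pytest.approx(-60.0)

    def test_sinusoid_rms_closed_form(self):
        n = int(150 * RATE)
        amp = 0.8
        x = amp * np.sin(2 * np.pi * 0.75 * np.arange(n) / RATE)
        c = ApnoeaCandidate("s", 40.0, 65.0)
        feats = extract_features(c, self._filtered(x), np.full(150, 150.0), np.full(150, 97.0))
        assert feats.rms_pre10 == pytest.approx(amp / np.sqrt(2), rel=0.02)

    def test_low_coverage_flags_missing(self):
        n = int(90 * RATE)
        x = np.zeros(n)
        c = ApnoeaCandidate("s", 3.0, 26.0)  # pre-window mostly before t=0
        feats = extract_features(c, self._filtered(x), np.full(90, 150.0), np.full(90, 97.0))
        assert np.isnan(feats.rms_pre10) and feats.missing


class TestClassifier:
    def test_separable_training_is_perfect(self):
        X, y, _ = simulate_feature_set(50, 50, separation=6.0, seed=1)
        model = train_classifier(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_standardisation_invariance(self):
        X, y, _ = simulate_feature_set(40, 40, separation=2.0, seed=2)
        base = train_classifier(X, y).predict(X)
        scaled = X * 1000.0
        assert np.array_equal(train_classifier(scaled, y).predict(scaled), base)

    def test_single_class_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError):
            train_classifier(X, np.ones(10))

    def test_contradictory_duplicates_never_crash(self):
        X = np.tile([[1.0, 2.0, 3.0, 4.0, 5.0]], (10, 1))
        y = np.array([0, 1] * 5)
        model = train_classifier(X, y)
        assert model.predict(X).shape == (10,)

    def test_json_roundtrip_predicts_identically(self, tmp_path):
        X, y, _ = simulate_feature_set(30, 30, separation=3.0, seed=4)
        model = train_classifier(X, y)
        path = tmp_path / "model.json"
        model.save_json(path)
        loaded = ApnoeaClassifier.load_json(path)
        assert np.array_equal(loaded.predict(X), model.predict(X))
        assert np.allclose(loaded.decision_function(X), model.decision_function(X))

    def test_sklearn_get_set_params(self):
        model = ApnoeaClassifier(C=2.0)
        assert model.get_params()["C"] == 2.0
        model.set_params(C=0.5)
        assert model.C == 0.5


class TestLosoCV:
    def test_single_subject_errors(self):
        X, y, _ = simulate_feature_set(10, 10, 2.0, seed=0)
        with pytest.raises(ValueError):
            loso_cv(X, y, np.zeros(20))

    def test_high_separation_high_accuracy(self):
        X, y, g = simulate_feature_set(60, 60, separation=6.0, seed=3)
        assert loso_cv(X, y, g).accuracy >= 0.95

    def test_zero_separation_near_chance(self):
        X, y, g = simulate_feature_set(100, 100, separation=0.0, seed=3)
        prior = 0.5
        sd = np.sqrt(prior * (1 - prior) / y.size)
        assert abs(loso_cv(X, y, g).accuracy - prior) <= 4 * sd

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for sep in (0.0, 1.0, 2.0, 4.0, 6.0):
            X, y, g = simulate_feature_set(60, 60, separation=sep, seed=7)
            accs.append(loso_cv(X, y, g).accuracy)
        assert all(b >= a - 0.03 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]

    def test_all_features_beat_ip_only(self):
        """HR/SpO2 deltas carry signal, so dropping them cannot help."""
        X, y, g = simulate_feature_set(100, 100, separation=2.0, seed=9)
        full = loso_cv(X, y, g).accuracy
        ip_only = loso_cv(X[:, :3], y, g).accuracy
        assert ip_only <= full

    def test_affine_feature_rescaling_leaves_predictions(self):
        X, y, g = simulate_feature_set(40, 40, separation=2.0, seed=5)
        base = loso_cv(X, y, g)
        X2 = X.copy()
        X2[:, 3] = X2[:, 3] * 7.0 - 100.0
        again = loso_cv(X2, y, g)
        assert (base.tp, base.fp, base.fn, base.tn) == (again.tp, again.fp, again.fn, again.tn)


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (m.accuracy, m.fpr, m.fnr, m.mcc) == (1.0, 0.0, 0.0, 1.0)

    def test_worked_confusion_matrix(self):
        # tp=5, fp=1, fn=2, tn=8 -> mcc = 38/sqrt(3780)
        pred = [1] * 5 + [1] + [0] * 2 + [0] * 8
        act = [1] * 5 + [0] + [1] * 2 + [0] * 8
        m = compute_metrics(pred, act)
        assert m.mcc == pytest.approx(38 / np.sqrt(3780))
        assert (m.tp, m.fp, m.fn, m.tn) == (5, 1, 2, 8)

    def test_degenerate_marginal_convention(self):
        m = compute_metrics([1, 1, 1], [1, 0, 1])
        assert m.mcc == 0.0

    def test_agrees_with_sklearn_on_random_draws(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(4, 40)
            pred = rng.integers(0, 2, n)
            act = rng.integers(0, 2, n)
            m = compute_metrics(pred, act)
            assert m.accuracy == pytest.approx(np.mean(pred == act))
            assert m.mcc == pytest.approx(matthews_corrcoef(act, pred), abs=1e-12)


class TestCooccurrence:
    def test_flags_from_nadirs(self):
        hr = np.full(200, 150.0)
        spo2 = np.full(200, 97.0)
        hr[60:70] = 90.0
        spo2[65:75] = 75.0
        events = cooccurrence_events([(40.0, 60.0)], hr, spo2)
        assert events[0].bradycardia and events[0].desaturation

    def test_no_bradycardia_when_hr_high(self):
        hr = np.full(200, 150.0)
        events = cooccurrence_events([(40.0, 60.0)], hr, np.full(200, 97.0))
        assert not events[0].bradycardia

    def test_simulator_responses_drive_flags(self):
        cfg = SimulationConfig(duration=400, seed=29)
        rec, truth = simulate_recording(cfg)
        rec, truth = inject_pause(
            rec, truth, 60, 25, "apnoea-with-response", hr_response=90, spo2_response=75
        )
        rec, truth = inject_pause(rec, truth, 250, 25, "apnoea-no-response")
        events = cooccurrence_events([(60.0, 85.0), (250.0, 275.0)], rec.hr, rec.spo2)
        assert events[0].bradycardia and events[0].desaturation
        assert not events[1].bradycardia and not events[1].desaturation


class TestBradycardias:
    def test_constant_high_hr_empty(self):
        assert find_bradycardias(np.full(300, 110.0)) == []

    def test_exact_boundary_counts(self):
        hr = np.full(300, 120.0)
        hr[100:115] = 95.0  # 15 samples at 1 Hz = 15 s
        assert find_bradycardias(hr) == [(100.0, 115.0)]

    def test_sub_threshold_dips_ignored(self):
        hr = np.full(300, 120.0)
        hr[50:60] = 95.0
        hr[80:90] = 95.0
        assert find_bradycardias(hr) == []
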