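"""SVM training, decision scoring against the kernel-expansion identity,
threshold calibration, grid search and model persistence."""

import json
import math

import numpy as np
import pytest
from sklearn.svm import SVC

from prkc_psp.dataio import LabeledDataset
from prkc_psp.evaluation import auroc, cross_validate
from prkc_psp.model import (
    CalibrationError,
    ModelLoadError,
    SVMConfig,
    build_predictor,
    calibrate_thresholds,
    decision_score,
    grid_search,
    load_model,
    save_model,
    train,
)

from conftest import random_training_set


class TestTrain:
    def test_separable_training_auroc_is_one(self, separable_dataset):
        model = train(separable_dataset)
        scores = model.decision_values(separable_dataset.windows)
        labels = [w.label for w in separable_dataset.windows]
        assert auroc(scores, labels) == pytest.approx(1.0, abs=1e-12)
        pos = scores[np.array(labels) == "positive"]
        neg = scores[np.array(labels) == "negative"]
        assert pos.min() > neg.max()

    def test_same_data_same_seed_identical_scores(self, separable_dataset):
        m1 = train(separable_dataset, SVMConfig(seed=7))
        m2 = train(separable_dataset, SVMConfig(seed=7))
        s1 = m1.decision_values(separable_dataset.windows)
        s2 = m2.decision_values(separable_dataset.windows)
        np.testing.assert_array_equal(s1, s2)

    def test_window_order_invariance(self, separable_dataset):
        shuffled = list(separable_dataset.windows)
        np.random.default_rng(3).shuffle(shuffled)
        m1 = train(separable_dataset)
        m2 = train(LabeledDataset(windows=shuffled))
        np.testing.assert_allclose(
            m1.decision_values(separable_dataset.windows),
            m2.decision_values(separable_dataset.windows),
            atol=1e-10,
        )

    def test_decision_values_match_reference_svm(self, separable_dataset):
        """The stored dual expansion must reproduce the backend's own
        decision_function on the identical scaled features."""
        model = train(separable_dataset)
        x = model.encode_scale(sorted(
            separable_dataset.windows, key=lambda w: (w.accession, w.position)
        ))
        y = [
            1 if w.label == "positive" else 0
            for w in sorted(separable_dataset.windows, key=lambda w: (w.accession, w.position))
        ]
        ref = SVC(kernel="rbf", C=model.config.C, gamma=model.config.gamma)
        ref.fit(x, y)
        np.testing.assert_allclose(
            model.decision_values(separable_dataset.windows),
            ref.decision_function(model.encode_scale(separable_dataset.windows)),
            atol=1e-8,
        )

    def test_explicit_kernel_sum_oracle(self, separable_dataset):
        model = train(separable_dataset)
        w = separable_dataset.windows[0]
        x = model.encode_scale([w])[0]
        # brute-force sum over support vectors
        s = sum(
            a * math.exp(-model.config.gamma * float(np.sum((x - sv) ** 2)))
            for a, sv in zip(model.dual_coef, model.support_vectors)
        ) + model.intercept
        assert decision_score(model, w) == pytest.approx(s, abs=1e-8)

    def test_single_class_raises(self, separable_dataset):
        only_pos = LabeledDataset(
            windows=[w for w in separable_dataset.windows if w.label == "positive"]
        )
        with pytest.raises(ValueError):
            train(only_pos)


class TestCalibrateThresholds:
    def test_enumerated_example(self):
        scores = [-2.0, -1.0, 1.0, 2.0]
        labels = ["negative", "negative", "positive", "positive"]
        ts = calibrate_thresholds(scores, labels, {"high": 0.95})
        t = ts.thresholds["high"]
        assert t.cutoff == 1.0
        assert t.achieved_specificity == 1.0
        assert t.achieved_sensitivity == 1.0

    def test_zero_target_gives_minus_inf_sentinel(self):
        scores = [-2.0, -1.0, 1.0, 2.0]
        labels = ["negative", "negative", "positive", "positive"]
        ts = calibrate_thresholds(scores, labels, {"low": 0.0})
        assert ts.thresholds["low"].cutoff == -math.inf
        assert ts.thresholds["low"].achieved_sensitivity == 1.0

    def test_cutoffs_monotone_in_target(self):
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(-1, 1, 200)])
        labels = ["positive"] * 50 + ["negative"] * 200
        ts = calibrate_thresholds(scores, labels)
        assert (
            ts.thresholds["high"].cutoff
            >= ts.thresholds["medium"].cutoff
            >= ts.thresholds["low"].cutoff
        )
        # achieved specificity non-increasing from high to low
        assert (
            ts.thresholds["high"].achieved_specificity
            >= ts.thresholds["medium"].achieved_specificity
            >= ts.thresholds["low"].achieved_specificity
        )

    def test_smallest_qualifying_cutoff(self):
        rng = np.random.default_rng(9)
        scores = np.round(np.concatenate([rng.normal(1, 1, 40), rng.normal(-1, 1, 160)]), 1)
        labels = np.array(["positive"] * 40 + ["negative"] * 160)
        neg = scores[labels == "negative"]
        ts = calibrate_thresholds(scores, labels, {"high": 0.9})
        cut = ts.thresholds["high"].cutoff
        assert np.mean(neg < cut) >= 0.9
        below = sorted(set(scores[scores < cut]))
        if below:  # any strictly smaller observed score fails the target
            assert np.mean(neg < below[-1]) < 0.9

    def test_all_tied_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_thresholds(
                [0.0, 0.0, 0.0], ["positive", "negative", "negative"], {"high": 0.95}
            )


class TestGridSearch:
    def test_singleton_grid(self, separable_dataset):
        cfg = grid_search(separable_dataset, [32.0], [0.5], n_folds=3, seed=1)
        assert (cfg.C, cfg.gamma) == (32.0, 0.5)

    def test_tie_break_prefers_small_c_then_gamma(self, separable_dataset):
        # separable data: every grid point reaches AROC 1.0
        cfg = grid_search(separable_dataset, [1.0, 32.0], [0.1, 0.5], n_folds=3, seed=1)
        assert (cfg.C, cfg.gamma) == (1.0, 0.1)

    def test_winner_beats_fixed_points(self, small_benchmark):
        _, _, dataset = small_benchmark
        C_grid, gamma_grid = [1.0, 32.0], [0.5, 2.0]
        best = grid_search(dataset, C_grid, gamma_grid, n_folds=4, seed=2)
        best_auc = cross_validate(
            dataset, best, n_folds=4, seed=2, calibrate=False
        ).auroc
        for C in C_grid:
            for g in gamma_grid:
                other = cross_validate(
                    dataset, SVMConfig(C=C, gamma=g), n_folds=4, seed=2, calibrate=False
                ).auroc
                assert best_auc >= other

    def test_bad_folds(self, separable_dataset):
        with pytest.raises(ValueError):
            grid_search(separable_dataset, [1.0], [1.0], n_folds=1, seed=0)


class TestPersistence:
    def test_round_trip_bitwise(self, tmp_path, small_predictor):
        path = tmp_path / "model.json"
        save_model(small_predictor, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            loaded.support_vectors, small_predictor.support_vectors
        )
        np.testing.assert_array_equal(loaded.dual_coef, small_predictor.dual_coef)
        np.testing.assert_array_equal(
            loaded.frequency_model.f_pos, small_predictor.frequency_model.f_pos
        )
        assert loaded.intercept == small_predictor.intercept
        assert loaded.thresholds.thresholds.keys() == \
            small_predictor.thresholds.thresholds.keys()

    def test_scores_stable_across_round_trip(self, tmp_path, small_predictor, small_benchmark):
        _, _, dataset = small_benchmark
        path = tmp_path / "model.json"
        save_model(small_predictor, path)
        loaded = load_model(path)
        rng = np.random.default_rng(12)
        sample = [dataset.windows[i] for i in rng.integers(0, len(dataset), 100)]
        before = small_predictor.decision_values(sample)
        after = loaded.decision_values(sample)
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_truncated_file_raises(self, tmp_path, small_predictor):
        path = tmp_path / "model.json"
        save_model(small_predictor, path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_newer_schema_refused(self, tmp_path, small_predictor):
        path = tmp_path / "model.json"
        save_model(small_predictor, path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelLoadError, match="newer"):
            load_model(path)


class TestBuildPredictor:
    def test_thresholds_attached_and_nested(self, small_predictor):
        ts = small_predictor.thresholds
        assert ts is not None
        assert ts.thresholds["high"].achieved_specificity >= 0.95
        assert ts.thresholds["medium"].achieved_specificity >= 0.90
        assert ts.thresholds["low"].achieved_specificity >= 0.85
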