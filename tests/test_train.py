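"""Trainer harness: LOSO folds, determinism, batching, sliding windows."""

import numpy as np
import pytest

from fogseg.io import DegenerateTrialError
from fogseg.losses import LossConfig
from fogseg.metrics import labels_to_segments
from fogseg.nn import BiLSTMRecognizer, MSGCN, ModelConfig
from fogseg.synth import CohortSpec, generate_cohort
from fogseg.train import (DivergenceError, PlanError, audit_no_leakage,
                          loso_folds, majority_label, make_batches,
                          make_windows, sliding_window_predict, train,
                          train_recognizer, trials_to_xy)


class TestLosoFolds:
    def test_two_subjects_give_complementary_folds(self, small_cohort):
        trials, _ = small_cohort
        subset = [t for t in trials if t.subject_id in ("S01", "S02")]
        plan = loso_folds(subset)
        assert len(plan.folds) == 2
        for train_ids, eval_subject in plan.folds:
            eval_ids = {t.trial_id for t in subset
                        if t.subject_id == eval_subject}
            assert eval_ids.isdisjoint(train_ids)
            assert set(train_ids) | eval_ids == {t.trial_id for t in subset}

    def test_enrichment_subjects_train_only(self, small_cohort):
        trials, _ = small_cohort
        plan = loso_folds(trials, eval_subjects=["S01", "S02"])
        s3_ids = {t.trial_id for t in trials if t.subject_id == "S03"}
        assert len(plan.folds) == 2
        for train_ids, eval_subject in plan.folds:
            assert eval_subject != "S03"
            assert s3_ids <= set(train_ids)

    def test_each_subject_evaluated_exactly_once(self, small_cohort):
        trials, _ = small_cohort
        plan = loso_folds(trials)
        assert sorted(s for _, s in plan.folds) == ["S01", "S02", "S03"]
        audit_no_leakage(plan, trials)

    def test_unknown_eval_subject_rejected(self, small_cohort):
        trials, _ = small_cohort
        with pytest.raises(PlanError):
            loso_folds(trials, eval_subjects=["S01", "S99"])

    def test_single_subject_rejected(self, small_cohort):
        trials, _ = small_cohort
        with pytest.raises(PlanError):
            loso_folds([t for t in trials if t.subject_id == "S01"])

    def test_leakage_audit_detects_contamination(self, small_cohort):
        trials, _ = small_cohort
        plan = loso_folds(trials)
        eval_subject = plan.folds[0][1]
        leaked = next(t.trial_id for t in trials
                      if t.subject_id == eval_subject)
        plan.folds[0][0].append(leaked)
        with pytest.raises(PlanError):
            audit_no_leakage(plan, trials)


class TestBatching:
    def test_padding_and_masks(self, rng):
        feats = [rng.standard_normal((T, 9, 3)).astype(np.float32)
                 for T in (30, 50, 20)]
        labels = [np.zeros(T, int) for T in (30, 50, 20)]
        batches = make_batches(feats, labels, batch_size=2)
        assert len(batches) == 2
        x, y, mask = batches[0]            # the two longest sequences
        assert x.shape[1] == 50
        np.testing.assert_array_equal(mask.sum(axis=1), [50, 30])
        assert np.all(x[1, 30:] == 0)


class TestTraining:
    def _setup(self):
        trials, _ = generate_cohort(CohortSpec(
            n_subjects=2, trials_per_subject=1, trial_duration_s=(4.0, 5.0),
            nonfreezer_fraction=0.5, seed=21))
        X, y = trials_to_xy(trials)
        cfg = ModelConfig(num_stages=2, layers_per_stage=3, filters=8,
                          dilation_schedule=(1, 2, 4))
        return X, y, cfg

    def test_fixed_seed_reproduces_loss_curve(self):
        X, y, cfg = self._setup()
        runs = []
        for _ in range(2):
            model = MSGCN(cfg, rng=7)
            runs.append(train(model, X, y, LossConfig(), lr=0.01, epochs=3,
                              batch_size=1, seed=7))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_loss_decreases(self):
        X, y, cfg = self._setup()
        model = MSGCN(cfg, rng=0)
        hist = train(model, X, y, LossConfig(), lr=0.01, epochs=8,
                     batch_size=2, seed=0)
        assert hist[-1] < hist[0]

    def test_divergence_aborts_with_diagnostic(self):
        X, y, cfg = self._setup()
        model = MSGCN(cfg, rng=0)
        with pytest.raises(DivergenceError):
            train(model, X, y, LossConfig(), lr=1e6, epochs=10,
                  batch_size=2, seed=0)

    def test_smoothing_reduces_predicted_fragmentation(self):
        """With the smoothing term enabled, the trained model predicts no
        more segments on held-out trials than without it (expectation over
        several seeds)."""
        trials, _ = generate_cohort(CohortSpec(
            n_subjects=3, trials_per_subject=2, trial_duration_s=(5.0, 7.0),
            nonfreezer_fraction=0.0, seed=33))
        X, y = trials_to_xy(trials)
        cfg = ModelConfig(num_stages=1, layers_per_stage=4, filters=8,
                          dilation_schedule=(1, 2, 4, 8))
        counts = {0.0: [], 0.15: []}
        for seed in range(5):
            for lam in counts:
                model = MSGCN(cfg, rng=seed)
                train(model, X[:4], y[:4], LossConfig(lambda_smooth=lam),
                      lr=0.02, epochs=8, batch_size=2, seed=seed)
                n_segs = sum(len(labels_to_segments(model.predict(x)))
                             for x in X[4:])
                counts[lam].append(n_segs)
        assert np.mean(counts[0.15]) <= np.mean(counts[0.0])


class TestSlidingWindow:
    def test_majority_and_tie_break(self):
        win = np.r_[np.ones(120, int), np.zeros(80, int)]
        assert majority_label(win) == 1
        tie = np.r_[np.ones(100, int), np.zeros(100, int)]
        assert majority_label(tie) == 0

    def test_sub_second_episode_never_majority(self):
        """A 40-sample FOG episode inside 2-second windows cannot dominate,
        so the windowed training target contains no FOG label at all."""
        labels = np.zeros(1000, int)
        labels[500:540] = 1
        feats = np.zeros((1000, 9, 3), np.float32)
        _, window_labels = make_windows(feats, labels, window=200)
        assert window_labels.sum() == 0

    def test_center_assignment_and_edges(self):
        class StubRecognizer:
            def predict_windows(self, windows):
                # label 1 iff the window's central sample is positive
                return (windows[:, windows.shape[1] // 2, 0, 0] > 0).astype(int)

        T = 400
        feats = np.zeros((T, 9, 3), np.float32)
        feats[150:260, 0, 0] = 1.0
        labels = sliding_window_predict(StubRecognizer(), feats,
                                        window_s=2.0, rate_hz=100.0)
        np.testing.assert_array_equal(np.flatnonzero(labels),
                                      np.arange(150, 260))

    def test_short_trial_rejected(self):
        with pytest.raises(DegenerateTrialError):
            sliding_window_predict(None, np.zeros((150, 9, 3), np.float32))

    def test_recognizer_trains_on_separable_windows(self):
        rng = np.random.default_rng(0)
        T = 600
        feats, labels = [], []
        for k in range(2):
            f = rng.normal(0, 0.1, size=(T, 9, 3)).astype(np.float32)
            l = np.zeros(T, int)
            l[200:400] = 1
            f[l == 0, :, 1] += 5.0      # strong displacement during gait
            feats.append(f)
            labels.append(l)
        rec = BiLSTMRecognizer(ModelConfig(), hidden=8, rng=0)
        hist = train_recognizer(rec, feats, labels, window_s=0.5,
                                rate_hz=100.0, lr=0.01, epochs=10,
                                batch_size=8, seed=0)
        assert hist[-1] < hist[0]
        windows, wl = make_windows(feats[0], labels[0], window=50)
        acc = np.mean(rec.predict_windows(windows) == wl)
        assert acc > 0.9
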