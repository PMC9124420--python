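"""Evaluation metrics against independent brute-force oracles and hand cases.

The oracles here are deliberately written in a different style from the
implementation (python sets of sample indices, explicit loops) so that
agreement is meaningful.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from fogseg.metrics import (AlignmentError, agreement_stats,
                            clinical_outcomes, correlation_strength,
                            episode_detection, evaluate_subject,
                            evaluate_trial, labels_to_segments, mcc,
                            segment_f1, segment_iou, segments_to_labels)

# ---------------------------------------------------------------- oracles


def oracle_segments(labels):
    """Run-length encode by explicit scan."""
    segs, start = [], 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            segs.append((start, t, int(labels[start])))
            start = t
    return segs


def oracle_f1(pred_labels, ref_labels, thr):
    """Set-based greedy-in-order matcher."""
    p_sets = [set(range(s, e)) for s, e, c in oracle_segments(pred_labels)
              if c == 1]
    r_sets = [set(range(s, e)) for s, e, c in oracle_segments(ref_labels)
              if c == 1]
    used = set()
    tp = fp = 0
    for p in p_sets:
        ious = [len(p & r) / len(p | r) for r in r_sets]
        best = max(range(len(r_sets)), key=lambda i: ious[i], default=None)
        if best is not None and ious[best] >= thr and best not in used:
            used.add(best)
            tp += 1
        else:
            fp += 1
    fn = len(r_sets) - len(used)
    denom = 2 * tp + fp + fn
    f1 = 100.0 if denom == 0 else 100.0 * 2 * tp / denom
    return f1, tp, fp, fn


def oracle_detection(pred_labels, ref_labels):
    p_sets = [set(range(s, e)) for s, e, c in oracle_segments(pred_labels)
              if c == 1]
    r_sets = [set(range(s, e)) for s, e, c in oracle_segments(ref_labels)
              if c == 1]
    tp = sum(1 for r in r_sets if any(r & p for p in p_sets))
    fp = sum(1 for p in p_sets if not any(p & r for r in r_sets))
    return tp, fp


def oracle_outcomes(labels):
    pct = 100.0 * sum(1 for v in labels if v == 1) / len(labels)
    episodes = sum(1 for s, e, c in oracle_segments(labels) if c == 1)
    return pct, episodes


def random_labels(rng, T):
    """Structured random label sequence (geometric run lengths)."""
    out = []
    state = int(rng.integers(0, 2))
    while len(out) < T:
        run = 1 + int(rng.geometric(0.08))
        out.extend([state] * run)
        state = 1 - state
    return np.array(out[:T])


# ------------------------------------------------------------- unit tests


class TestSegments:
    def test_hand_example(self):
        segs = labels_to_segments([0, 0, 1, 1, 0])
        assert segs.segments == [(0, 2, 0), (2, 4, 1), (4, 5, 0)]

    def test_all_fog(self):
        assert labels_to_segments([1] * 5).segments == [(0, 5, 1)]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    def test_round_trip_identity(self, labels):
        segs = labels_to_segments(labels)
        np.testing.assert_array_equal(segments_to_labels(segs), labels)
        for (s1, e1, c1), (s2, e2, c2) in zip(segs, segs.segments[1:]):
            assert e1 == s2 and c1 != c2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            labels_to_segments([])


class TestIoU:
    def test_identical(self):
        assert segment_iou((3, 9), (3, 9)) == 1.0

    def test_disjoint(self):
        assert segment_iou((0, 5), (7, 9)) == 0.0

    def test_hand_value(self):
        assert segment_iou((0, 10), (5, 15)) == pytest.approx(1 / 3)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            segment_iou((4, 4), (0, 2))


class TestSegmentF1:
    def test_perfect_prediction_all_thresholds(self, rng):
        labels = random_labels(rng, 300)
        for thr in (0.1, 0.25, 0.5, 0.75):
            f1, tp, fp, fn = segment_f1(labels_to_segments(labels),
                                        labels_to_segments(labels), thr)
            assert f1 == 100.0 and fp == 0 and fn == 0

    def test_both_empty_is_100_one_empty_is_0(self):
        empty = labels_to_segments(np.zeros(50, int))
        full = labels_to_segments(np.r_[np.zeros(25, int), np.ones(25, int)])
        assert segment_f1(empty, empty, 0.5)[0] == 100.0
        assert segment_f1(empty, full, 0.5)[0] == 0.0
        assert segment_f1(full, empty, 0.5)[0] == 0.0

    def test_monotone_in_threshold(self, rng):
        for _ in range(25):
            pred = random_labels(rng, 200)
            ref = random_labels(rng, 200)
            scores = [segment_f1(pred, ref, t)[0]
                      for t in (0.1, 0.25, 0.5, 0.75)]
            assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            segment_f1(labels_to_segments([0, 1]), labels_to_segments([0, 1, 0]),
                       0.5)


class TestMCC:
    def test_matches_sklearn_on_random_pairs(self, rng):
        for _ in range(50):
            a = random_labels(rng, 150)
            b = random_labels(rng, 150)
            assert mcc(a, b) == pytest.approx(
                100 * matthews_corrcoef(b, a), abs=1e-8)

    def test_class_swap_symmetry(self, rng):
        a, b = random_labels(rng, 200), random_labels(rng, 200)
        assert mcc(a, b) == pytest.approx(mcc(1 - a, 1 - b), abs=1e-9)


class TestClinicalOutcomes:
    def test_all_fg(self):
        assert clinical_outcomes(np.zeros(80, int)) == (0.0, 0)

    def test_half_frozen_single_episode(self):
        labels = np.zeros(100, int)
        labels[10:60] = 1
        assert clinical_outcomes(labels) == (50.0, 1)

    def test_alternating(self):
        assert clinical_outcomes([1, 0, 1, 0, 1]) == (60.0, 3)

    def test_consistent_with_segment_view(self, rng):
        labels = random_labels(rng, 400)
        pct, n = clinical_outcomes(labels)
        segs = labels_to_segments(labels).of_class(1)
        assert n == len(segs)
        assert pct == pytest.approx(100 * sum(e - s for s, e in segs) / 400)


class TestEpisodeDetection:
    def test_single_sample_overlap_counts(self):
        ref = np.zeros(50, int)
        ref[10:20] = 1
        pred = np.zeros(50, int)
        pred[19:30] = 1      # one overlapping sample
        assert episode_detection(labels_to_segments(pred),
                                 labels_to_segments(ref)) == (1, 0)

    def test_prediction_on_clean_reference_is_fp(self):
        pred = np.zeros(40, int)
        pred[5:9] = 1
        tp, fp = episode_detection(labels_to_segments(pred),
                                   labels_to_segments(np.zeros(40, int)))
        assert (tp, fp) == (0, 1)


class TestEvaluateSubject:
    def test_pools_counts_across_trials(self, rng):
        ref1 = np.zeros(100, int); ref1[20:40] = 1
        ref2 = np.zeros(80, int); ref2[10:30] = 1
        rep = evaluate_subject([ref1, 1 - ref2], [ref1, ref2])
        assert rep.tp[50] == 1 and rep.fn[50] == 1
        assert rep.n_fog_ref == 2


class TestAgreement:
    def test_identity_relation(self):
        x = np.array([1.0, 5.0, 9.0, 12.0, 20.0])
        rep = agreement_stats(x, x)
        assert rep.r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0, abs=1e-9)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.significant

    def test_doubling_relation(self):
        x = np.array([1.0, 5.0, 9.0, 12.0, 20.0])
        rep = agreement_stats(2 * x, x)
        assert rep.r == pytest.approx(1.0) and rep.slope == pytest.approx(2.0)

    def test_strength_bins_boundaries(self):
        assert correlation_strength(0.79) == "moderately strong"
        assert correlation_strength(0.80) == "strong"
        assert correlation_strength(0.59) == "fair"
        assert correlation_strength(0.29) == "poor"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0, 2.0], [1.0, 2.0])


def test_evaluate_trial_report_fields(rng):
    ref = random_labels(rng, 250)
    pred = random_labels(rng, 250)
    rep = evaluate_trial(pred, ref)
    assert set(rep.f1_at) == {10, 25, 50, 75}
    assert -100.0 <= rep.mcc <= 100.0
    assert 0.0 <= rep.pct_tf_pred <= 100.0


def test_subject_table_columns(rng):
    from fogseg.metrics import subject_table
    ref = random_labels(rng, 200)
    reports = {"S1": evaluate_subject([ref], [ref]),
               "S2": evaluate_subject([1 - ref], [ref])}
    table = subject_table(reports)
    assert list(table.index) == ["S1", "S2"]
    assert table.loc["S1", "f1@50"] == 100.0
    for col in ("mcc", "n_fog_pred", "n_fog_ref", "pct_tf_pred", "pct_tf_ref"):
        assert col in table.columns
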