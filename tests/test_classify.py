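"""Metrics, cross-validation, window labelling, noise scoring, HR timelines."""

import numpy as np
import pytest

from cyclebeat.aggregate import EmbeddingSequence
from cyclebeat.classify import (
    WindowStrategy,
    cross_validate,
    evaluate_binary_af,
    heart_rate_timeline,
    label_window,
    make_windows,
    noise_scores,
    train_classifier,
)
from cyclebeat.trajectory import TrajectoryParams, Variant


def brute_force_auc(scores, labels):
    """Pairwise rank statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_confusion_arithmetic(self):
        # TP=8, FP=2, FN=2, TN=88
        p = np.concatenate([np.full(8, 0.9), np.full(2, 0.1),
                            np.full(2, 0.9), np.full(88, 0.1)])
        y = np.concatenate([np.ones(10), np.zeros(90)]).astype(bool)
        rep = evaluate_binary_af(p, y)
        assert rep.sensitivity[0] == pytest.approx(0.8)
        assert rep.ppv[0] == pytest.approx(0.8)
        assert rep.f1[0] == pytest.approx(0.8)
        assert rep.accuracy[0] == pytest.approx(0.96)
        assert rep.specificity[0] == pytest.approx(88 / 90)

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=60)
        y = rng.uniform(size=60) > 0.5
        rep = evaluate_binary_af(p, y)
        ppv, sens = rep.ppv[0], rep.sensitivity[0]
        expect = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
        assert rep.f1[0] == pytest.approx(expect)

    def test_auc_examples(self):
        rep = evaluate_binary_af(np.array([0.1, 0.4, 0.35, 0.8]),
                                 np.array([False, False, True, True]))
        assert rep.auc[0] == pytest.approx(0.75)
        perfect = evaluate_binary_af(np.array([0.1, 0.2, 0.8, 0.9]),
                                     np.array([False, False, True, True]))
        assert perfect.auc[0] == pytest.approx(1.0)

    def test_auc_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 21))
            p = np.round(rng.uniform(size=n), 2)
            y = rng.uniform(size=n) > 0.5
            if 0 < y.sum() < n:
                rep = evaluate_binary_af(p, y)
                assert rep.auc[0] == pytest.approx(brute_force_auc(p, y))

    def test_single_class_auc_missing(self):
        rep = evaluate_binary_af(np.array([0.2, 0.9]), np.array([True, True]))
        assert rep.auc is None

    def test_duplication_invariance(self):
        p = np.array([0.1, 0.7, 0.8, 0.3])
        y = np.array([False, True, True, False])
        a = evaluate_binary_af(p, y)
        b = evaluate_binary_af(np.tile(p, 2), np.tile(y, 2))
        for name in ("f1", "sensitivity", "specificity", "ppv", "accuracy"):
            assert getattr(a, name)[0] == pytest.approx(getattr(b, name)[0])
        assert a.auc[0] == pytest.approx(b.auc[0])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            evaluate_binary_af(np.array([0.5, 1.5]), np.array([True, False]))
        with pytest.raises(ValueError):
            evaluate_binary_af(np.array([0.5]), np.array([True, False]))


class TestCrossValidation:
    def test_deterministic_and_reasonable(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, (40, 3)), rng.normal(3, 1, (40, 3))])
        y = np.array(["NSR"] * 40 + ["AF"] * 40)
        a = cross_validate(X, y, af_label="AF", k=5, seed=1)
        b = cross_validate(X, y, af_label="AF", k=5, seed=1)
        assert a.as_dict() == b.as_dict()
        assert a.auc[0] > 0.95

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((5, 2)), np.array([0, 1, 0, 1, 0]), k=10)


class TestClassifierHead:
    def test_probabilities_sum_to_one_four_classes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 4)) + np.repeat(np.arange(4), 20)[:, None]
        y = np.repeat(["NSR", "AF", "OTHER", "NOISY"], 20)
        clf = train_classifier(X, y, seed=0)
        proba = clf.predict_proba(X[:10])
        assert proba.shape == (10, 4)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_separable_data_learned(self):
        X = np.concatenate([np.zeros((30, 2)), np.ones((30, 2)) * 4])
        y = np.array([0] * 30 + [1] * 30)
        clf = train_classifier(X, y, seed=0)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((4, 2)), np.zeros(5))


class TestWindowLabelling:
    def oracle(self, flags, strategy, p=0.8):
        count = sum(flags)
        if strategy is WindowStrategy.MAJORITY:
            return count >= 15
        if strategy is WindowStrategy.MIDDLE:
            return bool(flags[15])
        return count / 30 >= p

    def test_majority_boundary(self):
        assert label_window([True] * 15 + [False] * 15, WindowStrategy.MAJORITY)
        assert not label_window([True] * 14 + [False] * 16, WindowStrategy.MAJORITY)

    def test_threshold_boundary(self):
        flags = [True] * 24 + [False] * 6  # 24/30 == 0.8 exactly
        assert label_window(flags, WindowStrategy.THRESHOLD, p=0.8)
        assert not label_window(flags, WindowStrategy.THRESHOLD, p=0.8, strict=True)

    def test_middle_index_options(self):
        flags = [False] * 14 + [True] + [False] * 15  # only index 14 set
        assert not label_window(flags, WindowStrategy.MIDDLE)
        assert label_window(flags, WindowStrategy.MIDDLE, middle_index=14)

    def test_matches_oracle_on_random_patterns(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            flags = (rng.uniform(size=30) < rng.uniform()).tolist()
            for strat in WindowStrategy:
                assert label_window(flags, strat) == self.oracle(flags, strat)

    def test_majority_equals_threshold_at_half(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            flags = (rng.uniform(size=30) < 0.5).tolist()
            assert label_window(flags, WindowStrategy.MAJORITY) == label_window(
                flags, WindowStrategy.THRESHOLD, p=0.5
            )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            label_window([True] * 29)


class TestMakeWindows:
    def test_fenceposts(self):
        emb = np.zeros((31, 4))
        flags = [False] * 31
        assert len(make_windows(emb, flags)) == 2
        assert len(make_windows(emb[:30], flags[:30])) == 1

    def test_disjoint_at_stride_30(self):
        emb = np.zeros((60, 2))
        windows = make_windows(emb, [True] * 60, stride=30)
        assert len(windows) == 2

    def test_too_few_beats_warns(self):
        with pytest.warns(UserWarning):
            out = make_windows(np.zeros((10, 2)), [False] * 10)
        assert out == []

    def test_labels_follow_strategy(self):
        flags = [True] * 20 + [False] * 40
        windows = make_windows(np.zeros((60, 2)), flags,
                               strategy=WindowStrategy.MAJORITY)
        assert windows[0].label and not windows[-1].label


class TestNoiseScore:
    def test_clean_vs_noise_separation(self, pace_model):
        from cyclebeat.synthetic import SynthConfig, generate_record

        clean = [generate_record(SynthConfig(duration_s=15, seed=50 + i))[0]
                 for i in range(3)]
        noisy = [generate_record(SynthConfig(duration_s=15, noise_only=True,
                                             noise_sd=0.3, seed=60 + i))[0]
                 for i in range(3)]
        scores = noise_scores(pace_model, clean + noisy)
        assert np.all(np.isfinite(scores))
        assert scores[:3].max() < scores[3:].min()

    def test_beat_free_record_gets_maximum(self, pace_model):
        from cyclebeat.io import ECGRecord
        from cyclebeat.synthetic import SynthConfig, generate_record

        flat = ECGRecord(record_id="flat", samples=np.zeros(3000), fs=300.0)
        rec = generate_record(SynthConfig(duration_s=15, seed=77))[0]
        scores = noise_scores(pace_model, [rec, flat])
        assert scores[1] == scores.max()


class TestHeartRateTimeline:
    def test_bpm_conversion_and_order(self):
        params = [TrajectoryParams(Variant.PACE, b=np.zeros(2), f=1.25)] * 3
        seq = EmbeddingSequence("r", params)
        timeline = heart_rate_timeline(seq, [0.5, 1.5, 2.5])
        assert timeline == [(0.5, 75.0), (1.5, 75.0), (2.5, 75.0)]

    def test_shape_variant_rejected(self):
        seq = EmbeddingSequence("r", [TrajectoryParams(Variant.SHAPE, b=np.zeros(2))])
        with pytest.raises(ValueError, match="frequency"):
            heart_rate_timeline(seq, [0.0])

    def test_length_mismatch(self):
        seq = EmbeddingSequence("r", [TrajectoryParams(Variant.PACE, b=np.zeros(2), f=1.0)])
        with pytest.raises(ValueError):
            heart_rate_timeline(seq, [0.0, 1.0])
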