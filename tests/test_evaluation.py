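import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songscan.annotations import Selection
from songscan.classifier import SVMConfig
from songscan.evaluation import (
    DEFAULT_FRACTIONS,
    balanced_accuracy,
    learning_curve,
    match_detections,
    repeated_holdout,
    roc_auc,
)

from oracles import auc_brute_force


def sel(i, begin, end, source="rec"):
    return Selection(
        selection_id=i, source_id=source, begin_time=begin, end_time=end,
        low_freq=1000.0, high_freq=6100.0,
    )


class TestBalancedAccuracy:
    def test_perfect(self):
        bac, p_a, p_b = balanced_accuracy([1, 1, 0, 0], [1, 1, 0, 0])
        assert (bac, p_a, p_b) == (100.0, 1.0, 1.0)

    def test_printed_equation(self):
        # P(A)=0.9, P(B)=0.8 -> BAC 85
        truth = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        bac, p_a, p_b = balanced_accuracy(pred, truth)
        assert p_a == pytest.approx(0.9)
        assert p_b == pytest.approx(0.8)
        assert bac == pytest.approx(85.0)

    def test_all_one_class_predictions_give_50(self):
        truth = [1] * 10 + [0] * 10
        bac, _, _ = balanced_accuracy([1] * 20, truth)
        assert bac == pytest.approx(50.0)

    def test_one_class_truth_errors(self):
        with pytest.raises(ValueError):
            balanced_accuracy([1, 0], [1, 1])

    def test_equals_plain_accuracy_on_balanced_truth(self):
        rng = np.random.default_rng(0)
        truth = np.repeat([0, 1], 25)
        pred = rng.integers(0, 2, 50)
        bac, _, _ = balanced_accuracy(pred, truth)
        # on balanced truth BAC equals ordinary accuracy
        per_class = [
            (pred[truth == 1] == 1).mean(),
            (pred[truth == 0] == 0).mean(),
        ]
        assert bac == pytest.approx(np.mean(per_class) * 100)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_permutation_within_classes(self, seed):
        rng = np.random.default_rng(seed)
        truth = np.array([1] * 8 + [0] * 12)
        pred = rng.integers(0, 2, 20)
        bac1, _, _ = balanced_accuracy(pred, truth)
        perm = np.concatenate([rng.permutation(8), 8 + rng.permutation(12)])
        bac2, _, _ = balanced_accuracy(pred[perm], truth[perm])
        assert bac1 == pytest.approx(bac2)


class TestRocAuc:
    def test_perfectly_ranked(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_hand_computed_example(self):
        # 3 of 4 pairs concordant
        auc = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [0, 0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(4, 31))
            truth = np.zeros(n, dtype=int)
            truth[: max(1, n // 3)] = 1
            rng.shuffle(truth)
            if truth.min() == truth.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            assert roc_auc(scores, truth) == pytest.approx(auc_brute_force(scores, truth))

    def test_negation_symmetry(self):
        rng = np.random.default_rng(8)
        truth = np.array([1, 0] * 10)
        scores = rng.normal(size=20)
        assert roc_auc(scores, truth) == pytest.approx(1.0 - roc_auc(-scores, truth))


class TestRepeatedHoldout:
    def leak_features(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        x = np.column_stack([y.astype(float), rng.normal(size=n)])
        return x, y

    def test_oracle_feature_gives_bac_100_sd_0(self):
        x, y = self.leak_features()
        res = repeated_holdout(x, y, SVMConfig(), n_reps=20, seed=1)
        assert res.bac_mean == pytest.approx(100.0)
        assert res.bac_sd == pytest.approx(0.0)

    def test_uninformative_features_near_50(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 60)
        x = rng.normal(size=(120, 3))
        res = repeated_holdout(x, y, SVMConfig(), n_reps=100, seed=2)
        assert res.bac_mean == pytest.approx(50.0, abs=3.0)

    def test_same_seed_identical(self):
        x, y = self.leak_features()
        r1 = repeated_holdout(x, y, SVMConfig(), n_reps=10, seed=7)
        r2 = repeated_holdout(x, y, SVMConfig(), n_reps=10, seed=7)
        assert r1.bac_mean == r2.bac_mean
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.bac_values, r2.bac_values)

    def test_extending_reps_preserves_earlier_reps(self):
        x, y = self.leak_features(seed=3)
        rng = np.random.default_rng(4)
        x = x + rng.normal(0, 0.2, x.shape)  # make reps non-degenerate
        short = repeated_holdout(x, y, SVMConfig(), n_reps=5, seed=5)
        long = repeated_holdout(x, y, SVMConfig(), n_reps=10, seed=5)
        np.testing.assert_array_equal(short.bac_values, long.bac_values[:5])

    def test_class_too_small_errors(self):
        x = np.zeros((5, 1))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            repeated_holdout(x, y, SVMConfig(), n_reps=2, seed=0)

    def test_per_class_accuracy_keys(self):
        x, y = self.leak_features()
        classes = np.where(y == 0, 0, np.resize([1, 2, 3], len(y)))
        classes[y == 0] = 0
        res = repeated_holdout(x, y, SVMConfig(), n_reps=5, seed=0, class_labels=classes)
        assert set(res.per_class_accuracy) <= {0, 1, 2, 3}
        assert all(0 <= v <= 1 for v in res.per_class_accuracy.values())


class TestLearningCurve:
    def test_fraction_one_reproduces_repeated_holdout(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 30)
        x = np.column_stack([y + rng.normal(0, 0.5, 60), rng.normal(size=60)])
        curve = learning_curve(x, y, SVMConfig(), fractions=(1.0,), n_reps=8, seed=3)
        direct = repeated_holdout(x, y, SVMConfig(), n_reps=8, seed=3)
        assert curve.bac_mean[0] == pytest.approx(direct.bac_mean)
        assert curve.bac_sd[0] == pytest.approx(direct.bac_sd)

    def test_default_fractions_are_the_nine_printed_values(self):
        assert DEFAULT_FRACTIONS == (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

    def test_easy_data_flat_curve(self):
        rng = np.random.default_rng(13)
        y = np.repeat([0, 1], 100)
        x = np.column_stack([y * 6 + rng.normal(size=200), rng.normal(size=200)])
        curve = learning_curve(x, y, SVMConfig(), fractions=(1.0, 0.5), n_reps=10, seed=1)
        assert abs(curve.bac_mean[1] - curve.bac_mean[0]) <= 2.0

    def test_invalid_fraction_rejected(self):
        x = np.zeros((10, 1))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            learning_curve(x, y, SVMConfig(), fractions=(1.5,), n_reps=2, seed=0)


class TestMatchDetections:
    def test_identical_sets_perfect(self):
        truth = [sel(1, 0.0, 1.0), sel(2, 5.0, 6.0)]
        score = match_detections(truth, truth)
        assert score.recall == 1.0 and score.precision == 1.0

    def test_no_detections_flagged(self):
        truth = [sel(1, 0.0, 1.0)]
        score = match_detections([], truth)
        assert score.recall == 0.0
        assert score.precision == 0.0
        assert not score.precision_defined

    def test_nine_of_ten_recall(self):
        truth = [sel(i + 1, 10.0 * i, 10.0 * i + 2.0) for i in range(10)]
        detected = [sel(i + 1, 10.0 * i + 0.2, 10.0 * i + 2.1) for i in range(9)]
        score = match_detections(detected, truth)
        assert score.recall == pytest.approx(0.9)
        assert score.n_matched == 9

    def test_one_to_one_matching(self):
        truth = [sel(1, 0.0, 2.0)]
        detected = [sel(1, 0.0, 2.0), sel(2, 0.1, 1.9)]
        score = match_detections(detected, truth)
        assert score.n_matched == 1
        assert score.precision == pytest.approx(0.5)

    def test_below_threshold_not_matched(self):
        truth = [sel(1, 0.0, 2.0)]
        detected = [sel(1, 1.5, 3.5)]  # 25% overlap of truth
        assert match_detections(detected, truth).n_matched == 0
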