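"""Loss family, class-weight scheduler, metrics and conv-cost tests."""

import numpy as np
import pytest

from foxtune.losses import (
    class_error_rates,
    conv_costs,
    cross_entropy,
    focal_loss,
    update_class_weights,
    weighted_cross_entropy,
)
from foxtune.metrics import ConfusionMatrix, classification_metrics, confusion_matrix


def random_batch(rng, n=8, c=4):
    logits = rng.normal(size=(n, c))
    probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    targets = np.eye(c)[rng.integers(0, c, size=n)]
    return probs, targets


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        targets = np.array([[1.0, 0.0, 0.0]])
        assert cross_entropy(probs, targets) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_four_class(self):
        probs = np.full((1, 4), 0.25)
        targets = np.eye(4)[[2]]
        assert cross_entropy(probs, targets) == pytest.approx(np.log(4))

    def test_sum_convention_additivity(self, rng):
        probs, targets = random_batch(rng)
        once = cross_entropy(probs, targets)
        doubled = cross_entropy(
            np.vstack([probs, probs]), np.vstack([targets, targets])
        )
        assert doubled == pytest.approx(2 * once)

    def test_mean_reduction(self, rng):
        probs, targets = random_batch(rng, n=6)
        assert cross_entropy(probs, targets, reduction="mean") == pytest.approx(
            cross_entropy(probs, targets) / 6
        )

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([[0.5, 0.2]]), np.array([[1.0, 0.0]]))


class TestWeightedCrossEntropy:
    def test_unit_weights_reduce_to_plain(self, rng):
        probs, targets = random_batch(rng)
        assert weighted_cross_entropy(
            probs, targets, np.ones(4)
        ) == pytest.approx(cross_entropy(probs, targets))

    def test_uniform_weights_scale_exactly(self, rng):
        probs, targets = random_batch(rng)
        assert weighted_cross_entropy(
            probs, targets, np.full(4, 0.25)
        ) == pytest.approx(cross_entropy(probs, targets) / 4)

    def test_zero_weights_zero_loss(self, rng):
        probs, targets = random_batch(rng)
        assert weighted_cross_entropy(probs, targets, np.zeros(4)) == 0.0

    def test_one_hot_selection(self):
        probs = np.array([[0.7, 0.2, 0.1]])
        targets = np.array([[0.0, 1.0, 0.0]])
        w = np.array([5.0, 2.0, 9.0])
        expected = 2.0 * -np.log(0.2)
        assert weighted_cross_entropy(probs, targets, w) == pytest.approx(expected)

    def test_negative_weight_rejected(self, rng):
        probs, targets = random_batch(rng)
        with pytest.raises(ValueError):
            weighted_cross_entropy(probs, targets, np.array([1, -1, 1, 1.0]))


class TestFocalLoss:
    def test_delta_zero_reduces_to_cross_entropy(self, rng):
        probs, targets = random_batch(rng)
        assert focal_loss(probs, targets, delta=0.0) == pytest.approx(
            cross_entropy(probs, targets)
        )

    def test_confident_prediction_zero(self):
        probs = np.array([[1.0, 0.0]])
        targets = np.array([[1.0, 0.0]])
        assert focal_loss(probs, targets, delta=3.0) == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_delta_two(self):
        probs = np.array([[0.5, 0.5]])
        targets = np.array([[1.0, 0.0]])
        assert focal_loss(probs, targets, delta=2.0) == pytest.approx(
            0.25 * np.log(2)
        )

    def test_never_exceeds_cross_entropy(self, rng):
        for _ in range(20):
            probs, targets = random_batch(rng)
            assert focal_loss(probs, targets, delta=2.0) <= cross_entropy(
                probs, targets
            ) + 1e-12


class TestClassWeights:
    def test_error_rates_from_diagonal(self):
        cm = np.diag([3, 4, 5])
        np.testing.assert_allclose(class_error_rates(cm), [0, 0, 0])

    def test_error_rate_arithmetic(self):
        cm = np.array([[3, 1], [0, 6]])
        er = class_error_rates(cm)
        np.testing.assert_allclose(er, [0.25, 0.0])

    def test_er_plus_tpr_is_one(self, rng):
        cm = rng.integers(1, 20, size=(4, 4))
        er = class_error_rates(cm)
        tpr = np.diag(cm) / cm.sum(axis=1)
        np.testing.assert_allclose(er + tpr, 1.0)

    @pytest.mark.parametrize("rho", ["identity", "cube", "exp1", "exp10", "exp100"])
    def test_equal_errors_give_uniform_weights(self, rho):
        w = update_class_weights(np.full(3, 0.4), rho)
        np.testing.assert_allclose(w, 1 / 3)
        assert w.sum() == pytest.approx(1.0)

    def test_identity_rho_arithmetic(self):
        np.testing.assert_allclose(
            update_class_weights(np.array([0.1, 0.3]), "identity"), [0.25, 0.75]
        )

    def test_zero_errors_exp_rho(self):
        np.testing.assert_allclose(
            update_class_weights(np.zeros(2), "exp1"), [0.5, 0.5]
        )

    def test_identity_scale_invariance(self, rng):
        er = rng.uniform(0.1, 0.9, size=4)
        w1 = update_class_weights(er, "identity")
        w2 = update_class_weights(er * 0.5, "identity")
        np.testing.assert_allclose(w1, w2)

    def test_all_zero_identity_falls_back_uniform(self):
        np.testing.assert_allclose(
            update_class_weights(np.zeros(4), "identity"), 0.25
        )


class TestConfusionMatrix:
    def test_diagonal_when_perfect(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.trace(cm.counts) == 4 and cm.total == 4

    def test_empty_inputs(self):
        cm = confusion_matrix([], [], 2)
        assert cm.total == 0

    def test_binary_cell_layout(self):
        # one TP (1->1), one TN (0->0), one FP (0->1), one FN (1->0)
        cm = confusion_matrix([1, 0, 0, 1], [1, 0, 1, 0], 2)
        tp, fp, fn, tn = cm.one_vs_rest(1)
        assert (tp, fp, fn, tn) == (1, 1, 1, 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)


class TestClassificationMetrics:
    def test_perfect_binary(self):
        rep = classification_metrics(np.array([[1, 0], [0, 1]]))
        assert rep.accuracy == rep.precision == rep.sensitivity == rep.f1 == 1.0

    def test_hand_worked_binary(self):
        # TP=3, FP=1, FN=1, TN=5 with class 1 positive
        cm = np.array([[5, 1], [1, 3]])
        rep = classification_metrics(cm)
        assert rep.precision == pytest.approx(0.75)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)
        assert rep.accuracy == pytest.approx(0.8)

    def test_random_matrices_match_formula_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 5)
            counts = rng.integers(0, 30, size=(n, n))
            if counts.sum() == 0:
                counts[0, 0] = 1
            rep = classification_metrics(counts)
            # independent per-formula oracle
            senss, precs, f1s = [], [], []
            for c in range(n):
                tp = counts[c, c]
                fn = counts[c].sum() - tp
                fp = counts[:, c].sum() - tp
                sens = tp / (tp + fn) if tp + fn else 0.0
                prec = tp / (tp + fp) if tp + fp else 0.0
                f1 = (2 * sens * prec / (sens + prec)) if sens + prec else 0.0
                senss.append(sens)
                precs.append(prec)
                f1s.append(f1)
            if n == 2:
                assert rep.sensitivity == pytest.approx(senss[1])
                assert rep.precision == pytest.approx(precs[1])
            else:
                assert rep.sensitivity == pytest.approx(np.mean(senss))
                assert rep.precision == pytest.approx(np.mean(precs))
                assert rep.f1 == pytest.approx(np.mean(f1s))
            assert 0 <= rep.accuracy <= 1

    def test_matches_sklearn_macro(self, rng):
        from sklearn.metrics import precision_score, recall_score

        y_true = rng.integers(0, 3, size=200)
        y_pred = rng.integers(0, 3, size=200)
        rep = classification_metrics(confusion_matrix(y_true, y_pred, 3))
        assert rep.precision == pytest.approx(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        )
        assert rep.sensitivity == pytest.approx(
            recall_score(y_true, y_pred, average="macro", zero_division=0)
        )


class TestConvCosts:
    def test_unit_arguments(self):
        c_nor, c_sep, ratio = conv_costs(1, 1, 1, 1, 1)
        assert (c_nor, c_sep, ratio) == (1.0, 2.0, 0.5)

    def test_mobilenet_style_ratio(self):
        _, _, ratio = conv_costs(32, 32, 16, 64, 3)
        assert ratio == pytest.approx(576 / 73)

    def test_ratio_identity_holds_on_random_tuples(self, rng):
        for _ in range(100):
            hi, wi, di, dj, k = rng.integers(1, 20, size=5)
            c_nor, c_sep, ratio = conv_costs(hi, wi, di, dj, k)
            assert ratio == pytest.approx(c_nor / c_sep, rel=1e-12)

    def test_ratio_independent_of_spatial_extent(self):
        _, _, r1 = conv_costs(8, 8, 4, 32, 3)
        _, _, r2 = conv_costs(100, 7, 9, 32, 3)
        assert r1 == r2

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            conv_costs(0, 1, 1, 1, 1)
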