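import numpy as np
import pytest

from driverisk.calibration import auprc
from driverisk.errors import ConfigError, DomainError
from driverisk.losses import (
    BoosterParams,
    LossSpec,
    loss_value,
    objective_grad_hess,
    sigmoid,
    train_boosted_classifier,
)
from driverisk.simulate import ClassSimParams, generate_classification


def random_grid(n, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    p = rng.uniform(1e-6, 1 - 1e-6, n)
    w = rng.uniform(1.0, 22.3)
    return y, p, w


class TestLossValue:
    def test_log_half(self):
        assert loss_value([1], [0.5], LossSpec("cross_entropy")) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_weight_doubles_positive_loss(self):
        assert loss_value([1], [0.5], LossSpec("cross_entropy", 2.0)) == pytest.approx(
            2 * np.log(2), abs=1e-12
        )

    def test_weight_does_not_touch_negatives(self):
        for w in (1.0, 5.0, 22.3):
            assert loss_value([0], [0.5], LossSpec("cross_entropy", w)) == pytest.approx(
                np.log(2), abs=1e-12
            )

    def test_focal_gamma_zero_equals_cross_entropy(self):
        y, p, w = random_grid(10_000, seed=1)
        lf = loss_value(y, p, LossSpec("focal", w, 0.0))
        lw = loss_value(y, p, LossSpec("cross_entropy", w))
        assert abs(lf - lw) < 1e-12 * max(1.0, abs(lw))

    def test_additivity_over_samples(self):
        y, p, w = random_grid(100, seed=2)
        spec = LossSpec("focal", w, 1.7)
        total = loss_value(y, p, spec)
        split = loss_value(y[:40], p[:40], spec) + loss_value(y[40:], p[40:], spec)
        assert total == pytest.approx(split, rel=1e-12)

    def test_linear_in_weight_on_positives(self):
        y = np.ones(50, int)
        p = np.random.default_rng(3).uniform(0.01, 0.99, 50)
        l1 = loss_value(y, p, LossSpec("cross_entropy", 1.0))
        l3 = loss_value(y, p, LossSpec("cross_entropy", 3.0))
        assert l3 == pytest.approx(3 * l1, rel=1e-12)

    def test_bad_labels_rejected(self):
        with pytest.raises(DomainError):
            loss_value([2], [0.5], LossSpec("cross_entropy"))


class TestSpecValidation:
    def test_gamma_with_cross_entropy_rejected(self):
        with pytest.raises(ConfigError):
            LossSpec("cross_entropy", 1.0, 2.0)

    def test_focal_without_gamma_rejected(self):
        with pytest.raises(ConfigError):
            LossSpec("focal", 1.0)

    def test_weight_below_one_rejected(self):
        with pytest.raises(ConfigError):
            LossSpec("cross_entropy", 0.5)

    def test_booster_range_enforced(self):
        with pytest.raises(ConfigError):
            BoosterParams(n_estimators=5)
        with pytest.raises(ConfigError):
            BoosterParams(learning_rate=0.05)


def finite_difference_check(spec, n=200, seed=0, eps=1e-5):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 3, n)
    y = rng.integers(0, 2, n)
    grad, hess = objective_grad_hess(z, y, spec, hess_floor=0)

    def pointwise(zv):
        return np.array(
            [
                loss_value([yy], [float(sigmoid(zi))], spec)
                for zi, yy in zip(zv, y)
            ]
        )

    g_fd = (pointwise(z + eps) - pointwise(z - eps)) / (2 * eps)
    g_hi, _ = objective_grad_hess(z + eps, y, spec, hess_floor=0)
    g_lo, _ = objective_grad_hess(z - eps, y, spec, hess_floor=0)
    h_fd = (g_hi - g_lo) / (2 * eps)
    g_err = np.max(np.abs(grad - g_fd) / np.maximum(np.abs(g_fd), 1e-6))
    h_err = np.max(np.abs(hess - h_fd) / np.maximum(np.abs(h_fd), 1e-6))
    return g_err, h_err


class TestObjective:
    def test_cross_entropy_gradient_is_classical_identity(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 3, 100)
        y = rng.integers(0, 2, 100)
        grad, hess = objective_grad_hess(z, y, LossSpec("cross_entropy"), hess_floor=0)
        p = sigmoid(z)
        assert np.allclose(grad, p - y, atol=1e-12)
        assert np.allclose(hess, p * (1 - p), atol=1e-12)
        assert (hess >= 0).all()  # convexity in the margin

    @pytest.mark.parametrize(
        "spec",
        [
            LossSpec("cross_entropy", 7.3),
            LossSpec("focal", 1.0, 2.0),
            LossSpec("focal", 12.0, 0.5),
            LossSpec("focal", 22.3, 4.0),
        ],
        ids=["weighted-ce", "focal-g2", "focal-heavy-w", "focal-extremes"],
    )
    def test_matches_finite_differences(self, spec):
        g_err, h_err = finite_difference_check(spec)
        assert g_err < 1e-5
        assert h_err < 1e-5

    def test_hess_floor_clamps(self):
        z = np.array([-30.0])
        y = np.array([1])
        _, hess = objective_grad_hess(z, y, LossSpec("focal", 1.0, 2.0))
        assert hess[0] >= 1e-12


class TestTraining:
    def test_separable_data_reaches_perfect_training_auprc(self, small_booster):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = np.column_stack([y * 2.0 + rng.normal(0, 0.1, 200), rng.normal(size=200)])
        model = train_boosted_classifier(X, y, LossSpec("cross_entropy"), small_booster, seed=0)
        assert auprc(model.predict_proba(X), y) == pytest.approx(1.0)

    def test_determinism(self, small_booster, imbalanced_sample):
        s = imbalanced_sample
        m1 = train_boosted_classifier(s.X, s.y, LossSpec("focal", 5.0, 1.0), small_booster, seed=4)
        m2 = train_boosted_classifier(s.X, s.y, LossSpec("focal", 5.0, 1.0), small_booster, seed=4)
        assert np.array_equal(m1.predict_margin(s.X), m2.predict_margin(s.X))

    def test_minority_weight_raises_recall(self, small_booster):
        # cost-sensitivity direction: at threshold 0.5 the heavily weighted
        # model recalls at least as many positives (sign test over seeds)
        wins = ties = 0
        for seed in range(20):
            s = generate_classification(
                ClassSimParams(
                    n_samples=300, n_features=4, minority_fraction=0.1,
                    separation=1.5, seed=seed,
                )
            )
            rec = {}
            for w in (1.0, 22.3):
                model = train_boosted_classifier(
                    s.X, s.y, LossSpec("cross_entropy", w), small_booster, seed=seed
                )
                pred = (model.predict_proba(s.X) >= 0.5).astype(int)
                tp = np.sum((pred == 1) & (s.y == 1))
                rec[w] = tp / max(1, np.sum(s.y == 1))
            if rec[22.3] > rec[1.0]:
                wins += 1
            elif rec[22.3] == rec[1.0]:
                ties += 1
        assert wins + ties >= 15 and wins >= 1

    def test_single_class_rejected(self, small_booster):
        with pytest.raises(DomainError):
            train_boosted_classifier(
                np.zeros((10, 2)), np.zeros(10, int), LossSpec("cross_entropy"), small_booster
            )
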