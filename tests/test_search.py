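import numpy as np
import pytest
import xgboost as xgb
from sklearn.metrics import average_precision_score

from driverisk.errors import DomainError
from driverisk.losses import BoosterParams, LossSpec
from driverisk.sampling import SamplerSpec
from driverisk.search import (
    LeakageAudit,
    PipelineConfig,
    config_from_flat,
    evaluate_configuration,
    grid_combinations,
    manual_grid,
    optimize,
    run_rounds,
    stratified_fold_plan,
    threshold_sensitivity,
)
from driverisk.simulate import ClassSimParams, generate_classification
from driverisk.tpe import Categorical


def plain_config(booster, sampler="none", loss_w=1.0, calibration="none"):
    return PipelineConfig(
        sampler=SamplerSpec(sampler, sampling_fraction=0.5 if sampler != "none" else None),
        loss=LossSpec("cross_entropy", loss_w),
        calibration=calibration,
        booster=booster,
    )


class TestFoldPlan:
    def test_stratification_arithmetic(self):
        y = np.array([0] * 2230 + [1] * 100)
        plan = stratified_fold_plan(y, k=5, seed=0)
        for train, calib, test in plan.rotations:
            assert abs(int(np.sum(y[test] == 0)) - 446) <= 1
            assert int(np.sum(y[test] == 1)) == 20

    def test_every_sample_tested_exactly_once(self):
        y = np.array([0] * 90 + [1] * 10)
        plan = stratified_fold_plan(y, k=5, seed=1)
        tested = np.concatenate([t for _, _, t in plan.rotations])
        assert np.array_equal(np.sort(tested), np.arange(100))

    def test_roles_disjoint_within_rotation(self):
        y = np.array([0] * 90 + [1] * 10)
        plan = stratified_fold_plan(y, k=5, seed=2)
        for train, calib, test in plan.rotations:
            assert not set(train) & set(calib)
            assert not set(train) & set(test)
            assert not set(calib) & set(test)
            assert len(train) + len(calib) + len(test) == 100

    def test_same_seed_same_plan(self):
        y = np.array([0] * 90 + [1] * 10)
        p1 = stratified_fold_plan(y, k=5, seed=3)
        p2 = stratified_fold_plan(y, k=5, seed=3)
        for (a, b, c), (d, e, f) in zip(p1.rotations, p2.rotations):
            assert np.array_equal(a, d) and np.array_equal(b, e) and np.array_equal(c, f)

    def test_minority_below_k_rejected(self):
        with pytest.raises(DomainError):
            stratified_fold_plan(np.array([0] * 50 + [1] * 3), k=5)


class TestEvaluateConfiguration:
    def test_deterministic(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        plan = stratified_fold_plan(s.y, k=5, seed=0)
        cfg = plain_config(small_booster, sampler="smote", loss_w=3.0, calibration="isotonic")
        r1 = evaluate_configuration(cfg, s.X, s.y, plan, seed=0)
        r2 = evaluate_configuration(cfg, s.X, s.y, plan, seed=0)
        assert r1.objective == r2.objective
        assert [m.to_dict() for m in r1.fold_metrics] == [m.to_dict() for m in r2.fold_metrics]

    def test_planted_signal_beats_prevalence_baseline(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        plan = stratified_fold_plan(s.y, k=5, seed=0)
        rec = evaluate_configuration(plain_config(small_booster), s.X, s.y, plan, seed=0)
        prevalence = s.y.mean()
        assert rec.objective > prevalence + 0.3

    def test_failure_is_soft(self, imbalanced_sample):
        s = imbalanced_sample
        plan = stratified_fold_plan(s.y, k=5, seed=0)
        bad = PipelineConfig(
            sampler=SamplerSpec("smote", 0.01),  # below the original fraction
            loss=LossSpec("cross_entropy"),
            calibration="none",
            booster=BoosterParams(),
        )
        rec = evaluate_configuration(bad, s.X, s.y, plan, seed=0)
        assert rec.objective == float("-inf")
        assert rec.error is not None

    def test_degenerate_config_matches_independent_plain_cv(
        self, imbalanced_sample, small_booster
    ):
        """No sampling, w = 1, no calibration must equal an independently
        coded stratified-CV evaluation of the boosted classifier."""
        s = imbalanced_sample
        plan = stratified_fold_plan(s.y, k=5, seed=0)
        rec = evaluate_configuration(plain_config(small_booster), s.X, s.y, plan, seed=0)

        # independent implementation: raw xgboost API, local objective
        def local_obj(preds, dtrain):
            yy = dtrain.get_label()
            p = 1.0 / (1.0 + np.exp(-preds))
            return p - yy, np.maximum(p * (1.0 - p), 1e-12)

        scores = []
        for train, _calib, test in plan.rotations:
            dtrain = xgb.DMatrix(s.X[train], label=s.y[train].astype(float))
            bst = xgb.train(
                {
                    "max_depth": small_booster.max_depth,
                    "eta": small_booster.learning_rate,
                    "subsample": small_booster.subsample,
                    "colsample_bytree": small_booster.colsample_bytree,
                    "base_score": 0.5,
                    "tree_method": "hist",
                    "nthread": 1,
                    "seed": 0,
                },
                dtrain,
                num_boost_round=small_booster.n_estimators,
                obj=local_obj,
            )
            margins = bst.predict(xgb.DMatrix(s.X[test]), output_margin=True)
            probs = 1.0 / (1.0 + np.exp(-margins))
            scores.append(average_precision_score(s.y[test], probs))
        assert rec.objective == pytest.approx(float(np.mean(scores)), abs=1e-9)

    def test_leakage_audit_roles(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        plan = stratified_fold_plan(s.y, k=5, seed=0)
        audit = LeakageAudit()
        evaluate_configuration(
            plain_config(small_booster, sampler="smote"), s.X, s.y, plan, seed=0, audit=audit
        )
        for sampled, calib, test in zip(
            audit.sampled_rows, audit.calibration_rows, audit.test_rows
        ):
            assert not set(sampled) & set(test), "resampling saw test rows"
            assert not set(calib) & set(test), "calibrator saw test rows"
            assert not set(sampled) & set(calib)


class TestOptimize:
    def test_single_iteration_returns_that_trial(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        res = optimize(s.X, s.y, n_iter=1, seed=0, booster_defaults=small_booster,
                       space=[Categorical("method", ["none"])])
        assert len(res.trials) == 1
        assert res.cv1_objective == res.trials[0].objective

    def test_running_best_non_decreasing(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        space = [
            Categorical("method", ["none", "ros"]),
            Categorical("sampling_fraction", [0.5, 1.0],
                        condition=lambda c: c["method"] != "none"),
            Categorical("weight", [1.0, 5.0]),
        ]
        res = optimize(s.X, s.y, space=space, n_iter=12, seed=0,
                       booster_defaults=small_booster, n_startup=4)
        rb = res.running_best()
        assert (np.diff(rb) >= 0).all()
        assert res.cv1_objective == rb[-1]

    def test_reproducible_round(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        space = [Categorical("method", ["none", "ros"]),
                 Categorical("sampling_fraction", [1.0],
                             condition=lambda c: c["method"] != "none")]
        r1 = optimize(s.X, s.y, space=space, n_iter=6, seed=5, booster_defaults=small_booster)
        r2 = optimize(s.X, s.y, space=space, n_iter=6, seed=5, booster_defaults=small_booster)
        assert [t.objective for t in r1.trials] == [t.objective for t in r2.trials]
        assert r1.cv2_objective == r2.cv2_objective

    def test_cv2_uses_different_plan(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        res = optimize(s.X, s.y, space=[Categorical("method", ["none"])],
                       n_iter=1, seed=0, booster_defaults=small_booster)
        # CV1 and CV2 objectives come from different shuffles; on finite
        # data they virtually never coincide exactly
        assert res.cv2_objective != res.cv1_objective


class TestRunRounds:
    def test_single_round_degenerates_to_optimize(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        space = [Categorical("method", ["none"])]
        rep = run_rounds(s.X, s.y, n_rounds=1, n_iter=2, seed=3,
                         space=space, booster_defaults=small_booster)
        single = optimize(s.X, s.y, space=space, n_iter=2, seed=3,
                          booster_defaults=small_booster)
        assert rep.rounds[0].cv1_objective == single.cv1_objective

    def test_aggregate_is_mean_of_rounds(self, imbalanced_sample, small_booster):
        s = imbalanced_sample
        space = [Categorical("method", ["none", "ros"]),
                 Categorical("sampling_fraction", [1.0],
                             condition=lambda c: c["method"] != "none")]
        rep = run_rounds(s.X, s.y, n_rounds=2, n_iter=3, seed=0,
                         space=space, booster_defaults=small_booster)
        assert rep.mean_cv2.auprc == pytest.approx(
            np.mean([r.cv2_metrics.auprc for r in rep.rounds])
        )
        table = rep.per_round_table()
        assert len(table) == 2


class TestManualGrid:
    def test_enumeration_is_78_combinations(self):
        combos = grid_combinations()
        assert len(combos) == 78
        assert len(set(combos)) == 78

    def test_reduced_grid_matches_direct_evaluations(self, small_booster):
        s = generate_classification(
            ClassSimParams(n_samples=200, n_features=4, minority_fraction=0.2,
                           separation=2.5, seed=6)
        )
        plan = stratified_fold_plan(s.y, k=3, seed=0)
        table = manual_grid(
            s.X, s.y, plan=plan, booster=small_booster, weight=2.0,
            sampling_fraction=0.8, tune_weight_iters=0, seed=0, k=3,
        )
        assert table.attrs["n_combinations"] == 78
        assert len(table) == 78
        # ranked by objective
        obj = table["auprc"].to_numpy()
        finite = obj[np.isfinite(obj)]
        assert (np.diff(finite) <= 1e-12).all()
        # spot-check two rows against direct evaluation
        for _, row in table.iloc[[0, 10]].iterrows():
            frac = None if (row.sampler in ("none", "tomek", "enn", "renn", "allknn")) else 0.8
            cfg = PipelineConfig(
                sampler=SamplerSpec(row.sampler, sampling_fraction=frac),
                loss=LossSpec(row.loss, 2.0, 2.0 if row.loss == "focal" else None),
                calibration=row.calibration,
                booster=small_booster,
            )
            rec = evaluate_configuration(cfg, s.X, s.y, plan, seed=0)
            assert rec.objective == pytest.approx(row.auprc, abs=1e-12)


class TestThresholdSensitivity:
    def test_monotone_prevalence_and_infeasible_marking(self, small_booster):
        rng = np.random.default_rng(0)
        n = 300
        acrs = rng.exponential(0.15, n)
        import pandas as pd

        feats = pd.DataFrame(
            {"f0": acrs + rng.normal(0, 0.05, n), "f1": rng.normal(size=n)}
        )
        feats["label"] = 0  # placeholder, relabelled internally
        space = [Categorical("method", ["none"])]
        table = threshold_sensitivity(
            acrs, feats, thresholds=[0.1, 0.4, 5.0], n_iter=2, seed=0, k=3, space=space
        )
        assert (np.diff(table["risky_pct"]) <= 0).all()
        assert not table.iloc[-1]["feasible"]
        assert np.isnan(table.iloc[-1]["auprc"])
        assert table.iloc[0]["feasible"] and np.isfinite(table.iloc[0]["auprc"])

    def test_nonpositive_threshold_rejected(self):
        import pandas as pd

        with pytest.raises(DomainError):
            threshold_sensitivity(
                np.ones(10), pd.DataFrame({"f0": np.ones(10), "label": 0}), [0.0]
            )
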