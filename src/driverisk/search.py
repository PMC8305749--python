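"""Joint search over sampling, loss, calibration and booster hyperparameters.

The pipeline being optimized has five free elements — sampling method,
sampling fraction, loss function (with its minority weight), probability
calibration method — plus the booster hyperparameters.  A configuration is
scored by stratified 5-fold cross-validation with three roles per rotation:
three folds are resampled and used for training, one fold fits the
calibrator, and the last fold is scored.  The objective is the mean test
AUPRC over the five rotations.

Two search drivers sit on top of the evaluator: TPE Bayesian optimization
(:func:`optimize`, the headline route) and the exhaustive factorial of
{13 samplers} x {2 losses} x {3 calibrations} (:func:`manual_grid`, the
manual baseline).  The best configuration found on the search-time CV (CV1)
is always re-evaluated on a second CV with an independent shuffle seed (CV2)
to expose search overfitting.  Resampling and calibration never see test
rows — an instrumentable invariant, see :class:`LeakageAudit`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .calibration import (
    CALIBRATION_KINDS,
    MetricBundle,
    compute_metrics,
    fit_calibrator,
)
from .errors import DomainError, SearchError
from .losses import BoosterParams, LossSpec, train_boosted_classifier
from .sampling import RATIO_FREE, SAMPLER_NAMES, SamplerSpec, apply_sampling, effective_fraction
from .tpe import Categorical, TPEOptimizer, Uniform

MAX_WEIGHT = 22.3  # upper end of the minority-weight search range


@dataclass
class PipelineConfig:
    """One point in the joint search space."""

    sampler: SamplerSpec
    loss: LossSpec
    calibration: str
    booster: BoosterParams

    def __post_init__(self) -> None:
        if self.calibration not in CALIBRATION_KINDS:
            raise DomainError(f"unknown calibration {self.calibration!r}")

    def to_dict(self) -> dict:
        return {
            "sampler": self.sampler.to_dict(),
            "loss": self.loss.to_dict(),
            "calibration": self.calibration,
            "booster": self.booster.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            sampler=SamplerSpec.from_dict(d["sampler"]),
            loss=LossSpec.from_dict(d["loss"]),
            calibration=d["calibration"],
            booster=BoosterParams.from_dict(d["booster"]),
        )


@dataclass
class TrialRecord:
    """Evaluation of one configuration: per-fold metrics and the CV objective."""

    config: PipelineConfig
    fold_metrics: list[MetricBundle]
    objective: float
    iteration: int = -1
    seed: int = 0
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "objective": self.objective,
            "config": self.config.to_dict(),
            "fold_metrics": [m.to_dict() for m in self.fold_metrics],
            "seed": self.seed,
            "error": self.error,
        }


@dataclass
class FoldPlan:
    """Stratified k-fold rotation with train/calibration/test roles.

    Rotation i tests on fold i, calibrates on fold (i+1) mod k, and trains
    on the remaining k-2 folds.
    """

    rotations: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    k: int
    seed: int


def stratified_fold_plan(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Build the stratified rotation plan.

    Each fold carries the full dataset's class ratio within integer
    rounding; every sample appears exactly once as a test sample across the
    rotations.  Deterministic given ``seed``.
    """
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise DomainError(
            f"minority count {counts.min()} is below the fold count {k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    rotations = []
    for i in range(k):
        test = folds[i]
        calib = folds[(i + 1) % k]
        train = np.concatenate([folds[j] for j in range(k) if j not in (i, (i + 1) % k)])
        rotations.append((np.sort(train), np.sort(calib), np.sort(test)))
    return FoldPlan(rotations, k, seed)


class LeakageAudit:
    """Records which row indices each pipeline stage was allowed to see."""

    def __init__(self) -> None:
        self.sampled_rows: list[np.ndarray] = []
        self.calibration_rows: list[np.ndarray] = []
        self.test_rows: list[np.ndarray] = []


def evaluate_configuration(
    config: PipelineConfig,
    X,
    y,
    plan: FoldPlan,
    seed: int = 0,
    ece_bins: int = 10,
    audit: LeakageAudit | None = None,
    iteration: int = -1,
) -> TrialRecord:
    """Score one configuration on the rotation plan.

    Per rotation: resample the training folds only, fit the boosted
    classifier, fit the calibrator on the calibration fold's raw scores,
    then score the calibrated probabilities on the test fold.  Failures are
    soft: any rotation error yields objective -inf with the error recorded,
    so a search can continue past degenerate configurations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    metrics: list[MetricBundle] = []
    try:
        for train, calib, test in plan.rotations:
            if audit is not None:
                audit.sampled_rows.append(train.copy())
                audit.calibration_rows.append(calib.copy())
                audit.test_rows.append(test.copy())
            Xr, yr = apply_sampling(X[train], y[train], config.sampler, seed=seed)
            model = train_boosted_classifier(Xr, yr, config.loss, config.booster, seed=seed)
            calibrator = fit_calibrator(
                config.calibration, model.predict_proba(X[calib]), y[calib]
            )
            p_test = calibrator.transform(model.predict_proba(X[test]))
            metrics.append(compute_metrics(p_test, y[test], ece_bins=ece_bins))
        objective = float(np.mean([m.auprc for m in metrics]))
        return TrialRecord(config, metrics, objective, iteration=iteration, seed=seed)
    except Exception as exc:  # fail-soft: the search must continue
        return TrialRecord(
            config, metrics, float("-inf"), iteration=iteration, seed=seed, error=repr(exc)
        )


# ---------------------------------------------------------------------------
# search space


def default_search_space(f0: float) -> list:
    """The full joint space: five pipeline elements plus booster ranges.

    ``f0`` is the dataset's original minority/majority fraction; sampling
    fractions run over (f0, 1], i.e. from "leave the imbalance as is" to
    exact balance.  The fraction is inactive for the fixed-rule cleaners,
    and the focusing parameter only exists under the focal loss.
    """
    return [
        Categorical("method", list(SAMPLER_NAMES)),
        Uniform(
            "sampling_fraction",
            f0,
            1.0,
            condition=lambda c: c["method"] not in RATIO_FREE and c["method"] != "none",
        ),
        Categorical("loss_kind", ["cross_entropy", "focal"]),
        Uniform("weight", 1.0, MAX_WEIGHT),
        Uniform("focal_gamma", 0.0, 4.0, condition=lambda c: c["loss_kind"] == "focal"),
        Categorical("calibration", list(CALIBRATION_KINDS)),
        Uniform("n_estimators", 10, 350, q=1, integer=True),
        Uniform("max_depth", 3, 10, q=1, integer=True),
        Uniform("learning_rate", 0.1, 1.0),
        Uniform("subsample", 0.5, 1.0),
        Uniform("colsample_bytree", 0.5, 1.0),
    ]


def config_from_flat(flat: dict, defaults: BoosterParams | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a flat TPE sample (missing keys -> defaults)."""
    base = (defaults or BoosterParams.midpoint()).to_dict()
    booster = BoosterParams(
        **{k: flat[k] if flat.get(k) is not None else base[k] for k in base}
    )
    gamma = flat.get("focal_gamma")
    loss = LossSpec(
        kind=flat.get("loss_kind", "cross_entropy"),
        weight=float(flat.get("weight", 1.0) or 1.0),
        focal_gamma=gamma if flat.get("loss_kind") == "focal" else None,
    )
    sampler = SamplerSpec(
        method=flat.get("method", "none"),
        sampling_fraction=flat.get("sampling_fraction"),
    )
    return PipelineConfig(
        sampler=sampler,
        loss=loss,
        calibration=flat.get("calibration", "none"),
        booster=booster,
    )


@dataclass
class RoundResult:
    """One optimization round: the CV1 winner and its CV2 re-evaluation."""

    best_config: PipelineConfig
    cv1_objective: float
    cv2_metrics: MetricBundle
    cv2_objective: float
    trials: list[TrialRecord]
    seed: int

    def running_best(self) -> np.ndarray:
        obj = np.array([t.objective for t in self.trials])
        return np.maximum.accumulate(np.where(np.isfinite(obj), obj, -np.inf))

    def trials_to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trials:
                fh.write(json.dumps(t.to_dict()) + "\n")


def _mean_bundle(bundles: list[MetricBundle]) -> MetricBundle:
    return MetricBundle(
        precision=float(np.mean([b.precision for b in bundles])),
        recall=float(np.mean([b.recall for b in bundles])),
        f1=float(np.mean([b.f1 for b in bundles])),
        auprc=float(np.mean([b.auprc for b in bundles])),
        ece=float(np.mean([b.ece for b in bundles])),
        bin_count=bundles[0].bin_count,
    )


def optimize(
    X,
    y,
    space: list | None = None,
    n_iter: int = 500,
    seed: int = 0,
    k: int = 5,
    ece_bins: int = 10,
    n_startup: int = 20,
    booster_defaults: BoosterParams | None = None,
) -> RoundResult:
    """One TPE round: search on CV1, re-evaluate the winner on CV2.

    CV1 and CV2 differ only in the shuffle seed of the stratified split, so
    the gap between their objectives measures how much the search overfitted
    the CV1 test folds.  The full trial log is retained for iteration-curve
    diagnostics.
    """
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    y = np.asarray(y).astype(int)
    space = space if space is not None else default_search_space(effective_fraction(y))
    plan_cv1 = stratified_fold_plan(y, k=k, seed=seed)
    plan_cv2 = stratified_fold_plan(y, k=k, seed=seed + 100_003)
    opt = TPEOptimizer(space, seed=seed, n_startup=n_startup)
    trials: list[TrialRecord] = []
    for it in range(n_iter):
        flat = opt.suggest()
        try:
            config = config_from_flat(flat, booster_defaults)
        except Exception as exc:
            opt.observe(flat, float("-inf"))
            continue
        rec = evaluate_configuration(
            config, X, y, plan_cv1, seed=seed, ece_bins=ece_bins, iteration=it
        )
        trials.append(rec)
        opt.observe(flat, rec.objective)
    finite = [t for t in trials if np.isfinite(t.objective)]
    if not finite:
        raise SearchError(f"all {n_iter} trials failed; last errors: "
                          f"{[t.error for t in trials[-3:]]}")
    best = max(finite, key=lambda t: t.objective)
    cv2 = evaluate_configuration(best.config, X, y, plan_cv2, seed=seed, ece_bins=ece_bins)
    cv2_bundle = _mean_bundle(cv2.fold_metrics) if cv2.fold_metrics else MetricBundle(
        0, 0, 0, 0, 1, ece_bins
    )
    return RoundResult(
        best_config=best.config,
        cv1_objective=best.objective,
        cv2_metrics=cv2_bundle,
        cv2_objective=cv2.objective if np.isfinite(cv2.objective) else float("nan"),
        trials=trials,
        seed=seed,
    )


@dataclass
class RoundsReport:
    """Aggregate of several independent optimization rounds."""

    rounds: list[RoundResult]

    @property
    def mean_cv2(self) -> MetricBundle:
        return _mean_bundle([r.cv2_metrics for r in self.rounds])

    def per_round_table(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rounds, start=1):
            c = r.best_config
            rows.append(
                {
                    "round": i,
                    "cv1_auprc": r.cv1_objective,
                    "cv2_auprc": r.cv2_objective,
                    "sampler": c.sampler.method,
                    "sampling_fraction": c.sampler.sampling_fraction,
                    "loss": c.loss.kind,
                    "weight": c.loss.weight,
                    "focal_gamma": c.loss.focal_gamma,
                    "calibration": c.calibration,
                    **c.booster.to_dict(),
                }
            )
        return pd.DataFrame(rows)


def run_rounds(
    X,
    y,
    n_rounds: int = 5,
    n_iter: int = 500,
    seed: int = 0,
    k: int = 5,
    space: list | None = None,
    **kwargs,
) -> RoundsReport:
    """Repeat the whole optimize-then-re-evaluate procedure with distinct seeds.

    TPE can stop at a local optimum; independent rounds expose how stable
    the winning configuration is (the objectives typically agree closely
    even when the configurations differ).  The report carries every round's
    winner and the mean CV2 metrics.
    """
    if n_rounds < 1:
        raise DomainError("n_rounds must be >= 1")
    rounds = [
        optimize(X, y, space=space, n_iter=n_iter, seed=seed + 7919 * r, k=k, **kwargs)
        for r in range(n_rounds)
    ]
    return RoundsReport(rounds)


# ---------------------------------------------------------------------------
# manual factorial baseline


def grid_combinations() -> list[tuple[str, str, str]]:
    """The manual factorial: every (sampler, loss, calibration) triple."""
    return [
        (m, l, c)
        for m in SAMPLER_NAMES
        for l in ("cross_entropy", "focal")
        for c in CALIBRATION_KINDS
    ]


def manual_grid(
    X,
    y,
    plan: FoldPlan | None = None,
    booster: BoosterParams | None = None,
    weight: float = 1.0,
    sampling_fraction: float = 1.0,
    tune_weight_iters: int = 10,
    seed: int = 0,
    k: int = 5,
    ece_bins: int = 10,
) -> pd.DataFrame:
    """Exhaustive factorial over {13 samplers} x {2 losses} x {3 calibrations}.

    Non-element hyperparameters are fixed at the search-range midpoints; the
    minority weight is tuned per combination by a short inner TPE over
    [1, 22.3] (``tune_weight_iters=0`` keeps ``weight`` fixed instead).
    Returns every combination ranked by mean AUPRC; failed combinations rank
    last.  The combination count is stored in ``DataFrame.attrs['n_combinations']``.
    """
    y = np.asarray(y).astype(int)
    plan = plan or stratified_fold_plan(y, k=k, seed=seed)
    booster = booster or BoosterParams.midpoint()
    rows = []
    for method, loss_kind, calib in grid_combinations():
        frac = None if (method in RATIO_FREE or method == "none") else sampling_fraction
        sampler = SamplerSpec(method=method, sampling_fraction=frac)

        def build(w: float, g: float | None) -> PipelineConfig:
            return PipelineConfig(
                sampler=sampler,
                loss=LossSpec(
                    kind=loss_kind,
                    weight=w,
                    focal_gamma=(g if loss_kind == "focal" else None),
                ),
                calibration=calib,
                booster=booster,
            )

        gamma_default = 2.0
        if tune_weight_iters > 0:
            inner_space = [Uniform("weight", 1.0, MAX_WEIGHT)]
            if loss_kind == "focal":
                inner_space.append(Uniform("focal_gamma", 0.0, 4.0))
            opt = TPEOptimizer(
                inner_space, seed=seed, n_startup=max(3, tune_weight_iters // 2)
            )
            rec = None
            for _ in range(tune_weight_iters):
                flat = opt.suggest()
                cfg = build(flat["weight"], flat.get("focal_gamma"))
                cand = evaluate_configuration(cfg, X, y, plan, seed=seed, ece_bins=ece_bins)
                opt.observe(flat, cand.objective)
                if rec is None or cand.objective > rec.objective:
                    rec = cand
        else:
            rec = evaluate_configuration(
                build(weight, gamma_default), X, y, plan, seed=seed, ece_bins=ece_bins
            )
        bundle = (
            _mean_bundle(rec.fold_metrics)
            if rec.fold_metrics and np.isfinite(rec.objective)
            else None
        )
        rows.append(
            {
                "sampler": method,
                "loss": loss_kind,
                "calibration": calib,
                "auprc": rec.objective if np.isfinite(rec.objective) else np.nan,
                "precision": bundle.precision if bundle else np.nan,
                "recall": bundle.recall if bundle else np.nan,
                "f1": bundle.f1 if bundle else np.nan,
                "ece": bundle.ece if bundle else np.nan,
                "weight": rec.config.loss.weight,
                "focal_gamma": rec.config.loss.focal_gamma,
                "error": rec.error,
            }
        )
    df = pd.DataFrame(rows).sort_values("auprc", ascending=False, na_position="last")
    df = df.reset_index(drop=True)
    df.attrs["n_combinations"] = len(rows)
    return df


def grid_combination_count() -> int:
    """Size of the manual factorial: samplers x losses x calibrations."""
    return len(SAMPLER_NAMES) * 2 * len(CALIBRATION_KINDS)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Search settings loadable from a YAML file.

    Booster bounds default to the full search ranges; any subset may be
    narrowed in the file.  Unknown keys are rejected to catch typos.
    """

    n_iter: int = 500
    n_rounds: int = 5
    seed: int = 0
    n_folds: int = 5
    ece_bins: int = 10
    data_path: str | None = None
    label_column: str = "label"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )


# ---------------------------------------------------------------------------
# ACR-threshold sensitivity


def threshold_sensitivity(
    acrs,
    features: pd.DataFrame,
    thresholds,
    n_iter: int = 50,
    seed: int = 0,
    k: int = 5,
    space: list | None = None,
) -> pd.DataFrame:
    """Re-label drivers at each ACR threshold and re-run a fixed-budget search.

    Lower thresholds flag more drivers as risky, easing the imbalance;
    the table shows how prevalence and the achievable metrics move together.
    Thresholds that leave fewer than ``k`` risky drivers are marked
    infeasible.
    """
    acrs = np.asarray(acrs, dtype=float)
    thresholds = sorted(float(t) for t in thresholds)
    if any(t <= 0 for t in thresholds):
        raise DomainError("thresholds must be positive")
    feat_cols = [c for c in features.columns if c != "label"]
    X = features[feat_cols].to_numpy(dtype=float)
    rows = []
    for t in thresholds:
        y = (acrs > t).astype(int)
        n_risky = int(y.sum())
        row = {
            "threshold": t,
            "n_risky": n_risky,
            "risky_pct": 100.0 * n_risky / len(y),
            "feasible": n_risky >= k and n_risky < len(y),
        }
        if row["feasible"]:
            res = optimize(X, y, space=space, n_iter=n_iter, seed=seed, k=k)
            row.update(
                auprc=res.cv2_metrics.auprc,
                precision=res.cv2_metrics.precision,
                recall=res.cv2_metrics.recall,
                f1=res.cv2_metrics.f1,
                ece=res.cv2_metrics.ece,
            )
        else:
            row.update(auprc=np.nan, precision=np.nan, recall=np.nan, f1=np.nan, ece=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
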