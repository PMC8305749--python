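"""Cost-sensitive losses and the boosted-tree backend.

Two losses over binary labels y and predicted probabilities p = sigma(z)
(z the raw boosting margin), each with a minority-class weight w >= 1 (the
majority weight is always 1):

* weighted binary cross-entropy
      L_w = -sum_i [ w y_i log p_i + (1 - y_i) log(1 - p_i) ]
* weighted binary focal loss, with focusing parameter gamma >= 0,
      L_f = -sum_i [ w y_i (1-p_i)^gamma log p_i
                     + (1 - y_i) p_i^gamma log(1 - p_i) ]

At gamma = 0 the focal loss reduces exactly to the weighted cross-entropy.
The focusing term discounts well-classified samples so that gradient mass
concentrates on the hard ones — under class imbalance, mostly minority
points misclassified as majority.

Both losses are wired into gradient boosting as custom objectives: the
analytic first and second derivatives with respect to z are implemented
here.  For the cross-entropy these are the classical sigma(z) - y and
p(1-p) (scaled by w on positives); the focal derivatives follow from the
chain rule with dp/dz = p(1-p):

    y=1:  g = w [ gamma p (1-p)^gamma log p - (1-p)^(gamma+1) ]
          h = w p (1-p)^gamma [ -gamma^2 p log p + gamma (1-p)(log p + 1)
                                + (gamma+1)(1-p) ]
    y=0:  mirror image with p <-> 1-p, log p <-> log(1-p).

The focal curvature is genuinely negative at extreme margins (the loss is
non-convex in z); a configurable floor clamps it for stable leaf weights
during training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import xgboost as xgb

from .errors import ConfigError, DomainError

P_CLIP = 1e-15
HESS_FLOOR = 1e-12


@dataclass
class LossSpec:
    """Loss choice with its cost-sensitivity knobs.

    kind : 'cross_entropy' or 'focal'
    weight : minority-class weight w >= 1 (search range up to 22.3)
    focal_gamma : focusing parameter, present iff kind == 'focal'
    """

    kind: str
    weight: float = 1.0
    focal_gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cross_entropy", "focal"):
            raise ConfigError(f"unknown loss kind {self.kind!r}")
        if self.kind == "focal" and self.focal_gamma is None:
            raise ConfigError("focal loss requires focal_gamma")
        if self.kind == "cross_entropy" and self.focal_gamma is not None:
            raise ConfigError("focal_gamma is only applicable to the focal loss")
        if self.weight < 1.0:
            raise ConfigError("minority weight must be >= 1")
        if self.focal_gamma is not None and not (0.0 <= self.focal_gamma <= 4.0):
            raise ConfigError("focal_gamma must lie in [0, 4]")

    @property
    def gamma(self) -> float:
        return 0.0 if self.focal_gamma is None else self.focal_gamma

    def to_dict(self) -> dict:
        return {"kind": self.kind, "weight": self.weight, "focal_gamma": self.focal_gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "LossSpec":
        return cls(**d)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise DomainError("labels must be binary 0/1")
    return y.astype(float)


def loss_value(y, p_hat, spec: LossSpec) -> float:
    """Total loss over the sample (probabilities clipped to [1e-15, 1-1e-15])."""
    y = _check_labels(y)
    p = np.clip(np.asarray(p_hat, dtype=float), P_CLIP, 1.0 - P_CLIP)
    w, g = spec.weight, spec.gamma
    pos = w * y * (1.0 - p) ** g * np.log(p)
    neg = (1.0 - y) * p**g * np.log(1.0 - p)
    return float(-np.sum(pos + neg))


def sigmoid(z):
    z = np.asarray(z, dtype=float)
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def objective_grad_hess(
    raw_scores, y, spec: LossSpec, hess_floor: float | None = HESS_FLOOR
):
    """Per-sample first and second derivatives of the loss w.r.t. the margin z.

    ``hess_floor`` clamps the curvature from below for boosting stability;
    pass 0 (or None) for the exact analytic values, e.g. when comparing with
    finite differences.
    """
    y = _check_labels(y)
    z = np.asarray(raw_scores, dtype=float)
    p = np.clip(sigmoid(z), P_CLIP, 1.0 - P_CLIP)
    u = 1.0 - p
    w, g = spec.weight, spec.gamma

    if g == 0.0:
        grad = np.where(y == 1.0, w * (p - 1.0), p)
        hess = np.where(y == 1.0, w, 1.0) * p * u
    else:
        logp = np.log(p)
        logu = np.log(u)
        g1 = w * (g * p * u**g * logp - u ** (g + 1.0))
        h1 = w * p * u**g * (-(g**2) * p * logp + g * u * (logp + 1.0) + (g + 1.0) * u)
        g0 = p ** (g + 1.0) - g * u * p**g * logu
        h0 = u * p**g * (-(g**2) * u * logu + g * p * (logu + 1.0) + (g + 1.0) * p)
        grad = np.where(y == 1.0, g1, g0)
        hess = np.where(y == 1.0, h1, h0)

    if hess_floor:
        hess = np.maximum(hess, hess_floor)
    return grad, hess


def make_xgb_objective(spec: LossSpec, hess_floor: float = HESS_FLOOR):
    """Custom objective callable for ``xgboost.train``."""

    def objective(preds: np.ndarray, dtrain) -> tuple[np.ndarray, np.ndarray]:
        return objective_grad_hess(preds, dtrain.get_label(), spec, hess_floor)

    return objective


# Search ranges of the booster hyperparameters (inclusive bounds).
BOOSTER_RANGES = {
    "n_estimators": (10, 350),
    "max_depth": (3, 10),
    "learning_rate": (0.1, 1.0),
    "subsample": (0.5, 1.0),
    "colsample_bytree": (0.5, 1.0),
}


@dataclass
class BoosterParams:
    """Gradient-boosted-tree hyperparameters and their search ranges.

    n_estimators : number of boosting rounds, integer in [10, 350]
    max_depth : maximum tree depth, integer in [3, 10]
    learning_rate : shrinkage, in [0.1, 1]
    subsample : row subsample ratio per round, in [0.5, 1]
    colsample_bytree : column subsample ratio per tree, in [0.5, 1]
    """

    n_estimators: int = 180
    max_depth: int = 6
    learning_rate: float = 0.55
    subsample: float = 0.75
    colsample_bytree: float = 0.75

    def __post_init__(self) -> None:
        self.n_estimators = int(self.n_estimators)
        self.max_depth = int(self.max_depth)
        for name, (lo, hi) in BOOSTER_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside the search range [{lo}, {hi}]")

    @classmethod
    def midpoint(cls) -> "BoosterParams":
        """Midpoint of every search range (the manual-grid default)."""
        return cls(
            n_estimators=180,
            max_depth=6,
            learning_rate=0.55,
            subsample=0.75,
            colsample_bytree=0.75,
        )

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoosterParams":
        return cls(**d)


class BoostedScorer:
    """A fitted gradient-boosted classifier exposing margins and probabilities."""

    def __init__(self, booster: xgb.Booster, spec: LossSpec, params: BoosterParams):
        self._booster = booster
        self.loss_spec = spec
        self.params = params

    def predict_margin(self, X) -> np.ndarray:
        d = xgb.DMatrix(np.asarray(X, dtype=float))
        return self._booster.predict(d, output_margin=True)

    def predict_proba(self, X) -> np.ndarray:
        """Raw (uncalibrated) probabilities sigma(margin)."""
        return sigmoid(self.predict_margin(X))

    def feature_importances(self, n_features: int) -> np.ndarray:
        """Gain-based importances as a dense vector (0 for unused features)."""
        scores = self._booster.get_score(importance_type="gain")
        out = np.zeros(n_features)
        for name, v in scores.items():
            out[int(name[1:])] = v
        return out


def train_boosted_classifier(
    X,
    y,
    spec: LossSpec,
    params: BoosterParams | None = None,
    seed: int = 0,
    hess_floor: float = HESS_FLOOR,
) -> BoostedScorer:
    """Fit the boosted-tree classifier with the requested custom objective.

    Single-threaded and deterministic given ``seed``.  Raw margins start at 0
    (base score 0.5); probabilities are recovered as sigma(margin).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DomainError("training labels are single-class")
    params = params or BoosterParams()
    dtrain = xgb.DMatrix(np.asarray(X, dtype=float), label=y.astype(float))
    xgb_params = {
        "max_depth": params.max_depth,
        "eta": params.learning_rate,
        "subsample": params.subsample,
        "colsample_bytree": params.colsample_bytree,
        "base_score": 0.5,
        "tree_method": "hist",
        "nthread": 1,
        "seed": seed,
        "verbosity": 0,
    }
    try:
        booster = xgb.train(
            xgb_params,
            dtrain,
            num_boost_round=params.n_estimators,
            obj=make_xgb_objective(spec, hess_floor),
        )
    except xgb.core.XGBoostError as exc:  # pragma: no cover - backend failure path
        raise RuntimeError(
            f"boosting backend failed for spec={spec}, params={params}: {exc}"
        ) from exc
    return BoostedScorer(booster, spec, params)
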