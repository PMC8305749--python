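"""Probability calibration and the evaluation metrics.

Boosted trees are not trained in a probabilistic framework and, under class
imbalance, systematically distort the minority-class probabilities; a
calibrator fitted on a held-out fold maps the raw scores back toward the
true class probability.  Two calibrators are provided: Platt scaling (a
two-parameter logistic fitted on the log-odds of the raw probability) and
isotonic regression (a monotone non-decreasing step function able to correct
any monotone distortion).  ``none`` is the identity.

Metrics: precision TP/(TP+FP), recall TP/(TP+FN), their harmonic mean F1,
the area under the precision-recall curve (AUPRC, average-precision rule —
a random ranker scores the positive prevalence), and the expected
calibration error over M equal-width probability bins

    ECE = sum_k P(k) |o_k - e_k|

with o_k the empirical positive fraction, e_k the mean predicted probability
and P(k) the occupancy of bin k.  AUPRC rather than AUROC drives model
selection throughout: with a rare positive class AUROC is deceptively
optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .errors import CalibrationError, ConfigError, DomainError

CALIBRATION_KINDS = ("none", "platt", "isotonic")

_LOGIT_CLIP = 1e-7


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return np.log(p / (1.0 - p))


class Calibrator:
    """Fitted mapping raw probability -> calibrated probability in [0, 1]."""

    def __init__(self, kind: str, model=None):
        if kind not in CALIBRATION_KINDS:
            raise ConfigError(f"unknown calibration kind {kind!r}")
        self.kind = kind
        self._model = model

    def transform(self, scores) -> np.ndarray:
        p = np.asarray(scores, dtype=float)
        if self.kind == "none":
            return p.copy()
        if self.kind == "platt":
            return self._model.predict_proba(_logit(p).reshape(-1, 1))[:, 1]
        return np.clip(self._model.predict(p), 0.0, 1.0)

    __call__ = transform


def fit_calibrator(kind: str, scores, labels) -> Calibrator:
    """Fit a calibrator on the calibration fold's raw scores and labels.

    Platt scaling fits an unpenalised logistic regression on the log-odds of
    the raw probabilities (log-odds for numerical conditioning).  Isotonic
    regression fits the monotone step function by pooled adjacent violators;
    inputs outside the fitted range are clipped to the boundary values.
    """
    if kind == "none":
        return Calibrator("none")
    y = np.asarray(labels).astype(int)
    p = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise CalibrationError("calibration fold contains a single class")
    if kind == "platt":
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        lr.fit(_logit(p).reshape(-1, 1), y)
        return Calibrator("platt", lr)
    if kind == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip", increasing=True)
        iso.fit(p, y)
        return Calibrator("isotonic", iso)
    raise ConfigError(f"unknown calibration kind {kind!r}")


def precision_recall_f1(predicted, true) -> tuple[float, float, float]:
    """Precision, recall and F1 of binary label predictions.

    Zero-denominator conventions: precision = 0 when nothing is predicted
    positive; recall = 0 when there are no true positives to find; F1 = 0
    when precision + recall = 0.
    """
    yp = np.asarray(predicted).astype(int)
    yt = np.asarray(true).astype(int)
    tp = int(np.sum((yp == 1) & (yt == 1)))
    fp = int(np.sum((yp == 1) & (yt == 0)))
    fn = int(np.sum((yp == 0) & (yt == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def auprc(probabilities, true) -> float:
    """Area under the precision-recall curve, average-precision rule.

    The rectangular (average-precision) rule sums precision at each recall
    step and avoids the optimism of trapezoidal interpolation.  Invariant to
    strictly monotone transforms of the scores.
    """
    y = np.asarray(true).astype(int)
    if len(np.unique(y)) < 2:
        raise DomainError("AUPRC requires both classes in the evaluation set")
    return float(average_precision_score(y, np.asarray(probabilities, dtype=float)))


def calibration_bins(probabilities, true, m: int = 10):
    """Per-bin (o_k, e_k, P(k)) diagnostics over M equal-width bins."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("probabilities must lie in [0, 1]")
    idx = np.minimum((p * m).astype(int), m - 1)
    o = np.zeros(m)
    e = np.zeros(m)
    frac = np.zeros(m)
    for k in range(m):
        mask = idx == k
        if mask.any():
            o[k] = y[mask].mean()
            e[k] = p[mask].mean()
            frac[k] = mask.mean()
    return o, e, frac


def expected_calibration_error(probabilities, true, m: int = 10) -> float:
    """ECE over M equal-width bins; empty bins contribute zero."""
    o, e, frac = calibration_bins(probabilities, true, m)
    return float(np.sum(frac * np.abs(o - e)))


@dataclass
class MetricBundle:
    """All evaluation metrics of one scored fold."""

    precision: float
    recall: float
    f1: float
    auprc: float
    ece: float
    bin_count: int = 10
    bins_o: list = field(default_factory=list)
    bins_e: list = field(default_factory=list)
    bins_p: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auprc": self.auprc,
            "ece": self.ece,
            "bin_count": self.bin_count,
        }


def compute_metrics(
    probabilities, true, threshold: float = 0.5, ece_bins: int = 10
) -> MetricBundle:
    """Score calibrated probabilities against true labels.

    Class predictions use the default 0.5 threshold (movable downstream by
    threshold-moving; AUPRC and ECE are threshold-free).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true).astype(int)
    prec, rec, f1 = precision_recall_f1((p >= threshold).astype(int), y)
    o, e, frac = calibration_bins(p, y, ece_bins)
    return MetricBundle(
        precision=prec,
        recall=rec,
        f1=f1,
        auprc=auprc(p, y),
        ece=float(np.sum(frac * np.abs(o - e))),
        bin_count=ece_bins,
        bins_o=list(o),
        bins_e=list(e),
        bins_p=list(frac),
    )
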