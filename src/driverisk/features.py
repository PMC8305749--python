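"""Spectral and summary features of per-driver kinematic signals.

Three signals describe each driver: longitudinal speed, lateral speed, and
the gap to the preceding vehicle.  Each signal is converted to a fixed-length
amplitude spectrum via the discrete Fourier transform

    DFT_k = sum_{n=0}^{N-1} x_n exp(-2 pi i k n / N),

evaluated on the mean-removed series, normalised by N, and linearly
interpolated from the natural bin frequencies k/(N dt) onto a fixed grid
0.04, 0.08, ..., 0.80 Hz.  The fixed grid makes drivers with different
observation lengths comparable: the same underlying oscillation lands on the
same feature regardless of how long the vehicle stayed in view.  The mean,
standard deviation and coefficient of variation of each signal complete the
per-driver feature vector (3 signals x (20 amplitudes + 3 stats) = 69
features by default; ``n_dft=21`` gives 72 for anyone reproducing that
count).

Recursive feature elimination on the boosted classifier's importances is
provided as an optional reduction step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

SIGNAL_NAMES = ("lon_speed", "lat_speed", "gap")
GRID_SPACING = 0.04  # Hz
N_DFT_DEFAULT = 20


def dft_amplitudes(
    series,
    n_coeffs: int = N_DFT_DEFAULT,
    freq_spacing: float = GRID_SPACING,
    dt: float = 0.04,
) -> np.ndarray:
    """Amplitude spectrum on the fixed frequency grid.

    The series is mean-removed (the mean is a separate feature and would
    otherwise swamp the spectrum through the DC bin), transformed, and the
    N-normalised magnitudes are interpolated onto
    f = freq_spacing, 2*freq_spacing, ..., n_coeffs*freq_spacing (Hz).

    Amplitudes scale with the signal (|c x| spectrum = |c| times the
    spectrum of x) and are invariant to constant offsets.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DomainError("series must be 1-D with length >= 2")
    n = len(x)
    spec = np.abs(np.fft.rfft(x - x.mean())) / n
    bin_freqs = np.arange(len(spec)) / (n * dt)
    grid = freq_spacing * np.arange(1, n_coeffs + 1)
    return np.interp(grid, bin_freqs, spec)


def summary_stats(series) -> tuple[float, float, float]:
    """Mean, sample (n-1) standard deviation, and coefficient of variation.

    The CV is defined as sd/mean and guarded to 0 when |mean| <= 1e-12.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DomainError("series must be 1-D with length >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = sd / mean if abs(mean) > 1e-12 else 0.0
    return mean, sd, cv


def feature_columns(n_dft: int = N_DFT_DEFAULT) -> list[str]:
    """Deterministic column order: signal-major, DFT index then stats."""
    cols = []
    for sig in SIGNAL_NAMES:
        cols += [f"{sig}_dft{k}" for k in range(1, n_dft + 1)]
        cols += [f"{sig}_mean", f"{sig}_sd", f"{sig}_cv"]
    return cols


def driver_signals(traj, gap_cap: float = 50.0) -> dict[str, np.ndarray]:
    """The three per-driver signals from a Trajectory (gap capped/imputed at 50 m)."""
    return {
        "lon_speed": np.asarray(traj.vx, dtype=float),
        "lat_speed": np.asarray(traj.vy, dtype=float),
        "gap": traj.gap_series(gap_cap),
    }


def build_feature_table(
    signals: dict[int, dict[str, np.ndarray]],
    labels: dict[int, int] | pd.Series,
    n_dft: int = N_DFT_DEFAULT,
    dt: float = 0.04,
) -> pd.DataFrame:
    """Assemble the per-driver feature table.

    Parameters
    ----------
    signals : dict
        ``{vehicle_id: {signal_name: series}}`` with all of
        ``lon_speed``, ``lat_speed``, ``gap`` present per driver.
    labels : mapping
        ``{vehicle_id: 0|1}`` (1 = risky minority).

    Returns
    -------
    DataFrame indexed by vehicle_id with ``3*(n_dft+3)`` feature columns and
    a final ``label`` column.
    """
    ids = list(signals)
    if len(set(ids)) != len(ids):
        raise DataError("duplicated driver ids")
    missing = {
        vid: sorted(set(SIGNAL_NAMES) - set(sigs))
        for vid, sigs in signals.items()
        if set(SIGNAL_NAMES) - set(sigs)
    }
    if missing:
        raise DataError(f"drivers missing signals: {missing}")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()

    cols = feature_columns(n_dft)
    rows = []
    for vid in ids:
        row = []
        for sig in SIGNAL_NAMES:
            s = signals[vid][sig]
            row.extend(dft_amplitudes(s, n_coeffs=n_dft, dt=dt))
            row.extend(summary_stats(s))
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="vehicle_id"), columns=cols)
    df["label"] = [int(labels[vid]) for vid in ids]
    return df


def extract_features(
    trajectories: dict,
    labels: dict[int, int],
    n_dft: int = N_DFT_DEFAULT,
    eligible_only: bool = True,
) -> pd.DataFrame:
    """Feature table straight from Trajectory objects (eligible vehicles only)."""
    sigs = {
        vid: driver_signals(t)
        for vid, t in trajectories.items()
        if (t.eligible or not eligible_only) and vid in labels
    }
    return build_feature_table(sigs, labels, n_dft=n_dft)


@dataclass
class RFEResult:
    """Outcome of recursive feature elimination.

    ``elimination_order`` lists features least- to most-expendable-first as
    they were removed; ``selected`` is the surviving set at the best score;
    ``score_trace`` holds the CV objective after 0, 1, 2, ... eliminations.
    """

    elimination_order: list[str]
    selected: list[str]
    score_trace: list[float]


def recursive_feature_elimination(
    table: pd.DataFrame,
    evaluator=None,
    cv: int = 3,
    patience: int = 3,
    seed: int = 0,
    label_col: str = "label",
) -> RFEResult:
    """Backward feature selection driven by booster importances.

    Fits the boosted classifier on the current pool, scores it by stratified
    CV area under the precision-recall curve, drops the least important
    feature, and repeats.  Stops when the score has not improved for
    ``patience`` consecutive eliminations (ties break toward fewer features)
    or the pool is exhausted.  ``patience=None`` runs to a single feature.
    """
    from sklearn.model_selection import StratifiedKFold

    from .calibration import auprc
    from .losses import BoosterParams, LossSpec, train_boosted_classifier

    y = table[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise DomainError("labels are single-class")
    feats = [c for c in table.columns if c != label_col]
    if len(feats) < 2:
        raise DomainError("need at least 2 features")
    params = evaluator or BoosterParams(
        n_estimators=50, max_depth=3, learning_rate=0.3, subsample=1.0, colsample_bytree=1.0
    )
    loss = LossSpec(kind="cross_entropy", weight=1.0)

    def cv_score(cols: list[str]) -> float:
        X = table[cols].to_numpy(dtype=float)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        scores = []
        for tr, te in skf.split(X, y):
            model = train_boosted_classifier(X[tr], y[tr], loss, params, seed=seed)
            scores.append(auprc(model.predict_proba(X[te]), y[te]))
        return float(np.mean(scores))

    def importances(cols: list[str]) -> np.ndarray:
        X = table[cols].to_numpy(dtype=float)
        model = train_boosted_classifier(X, y, loss, params, seed=seed)
        return model.feature_importances(len(cols))

    pool = list(feats)
    trace = [cv_score(pool)]
    order: list[str] = []
    best_score, best_pool, since_best = trace[0], list(pool), 0
    while len(pool) > 1:
        imp = importances(pool)
        drop = pool[int(np.argmin(imp))]
        pool.remove(drop)
        order.append(drop)
        score = cv_score(pool)
        trace.append(score)
        if score >= best_score:  # ties prefer the smaller pool
            best_score, best_pool, since_best = score, list(pool), 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                break
    return RFEResult(order, best_pool, trace)
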