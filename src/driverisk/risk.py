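"""Rear-end collision-risk evaluation and risky-driver labeling.

The risk of a car-following pair at time t is judged by the braking-distance
margin

    DSS(t) = (v_l^2 - v_f^2) / (2 mu g) + d(t) - tau v_f(t)

the Difference between the Space distance available and the Stopping distance
required: v_l and v_f are the leading and following vehicles' longitudinal
speeds, mu the friction rate (0.7), g gravity (9.8 m/s^2), d the longitudinal
gap and tau the driver reaction time (1.5 s while accelerating, 0.7 s while
decelerating or idling).  A negative DSS means the follower cannot stop in
time; the collision risk

    CR(t) = 0             if DSS(t) >= 0
          = |DSS(t)|/v_f  if DSS(t) <  0

is the extra reaction time (s) the follower would need.  Averaging both the
leader-side and the (lane-change-only) follower-side risk over the observed
duration T gives the Average Collision Risk

    ACR = (1/T) sum_t [CR_L(t) + CR_F(t)] dt,

a per-driver scalar.  Drivers whose ACR exceeds the interquartile-range
outlier threshold of the non-zero ACR distribution,

    Threshold = Q3 + 1.5 (Q3 - Q1),

are labeled risky; the rest are normal.  On the highway population this
yields a strongly imbalanced binary outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, InsufficientDataError
from .trajectory import (
    LaneChangeInterval,
    PairSignals,
    Trajectory,
    accel_state,
    detect_lane_changes,
    pair_signals,
)


@dataclass
class RiskConstants:
    """Physical constants of the stopping-distance model.

    mu : friction rate (dimensionless), 0.7
    g : gravitational acceleration, 9.8 m/s^2
    tau_accel : driver reaction time while accelerating, 1.5 s
    tau_decel : reaction time while decelerating or idling, 0.7 s
    dt : trajectory sampling interval, 0.04 s
    """

    mu: float = 0.7
    g: float = 9.8
    tau_accel: float = 1.5
    tau_decel: float = 0.7
    dt: float = 0.04

    def __post_init__(self) -> None:
        for name in ("mu", "g", "tau_accel", "tau_decel", "dt"):
            if getattr(self, name) <= 0:
                raise DomainError(f"RiskConstants.{name} must be strictly positive")


@dataclass
class RiskProfile:
    """Per-vehicle risk summary: the two CR series, the ACR scalar and the label."""

    vehicle_id: int
    cr_leader: np.ndarray
    cr_follower: np.ndarray
    acr: float
    label: str | None = None  # 'risky' | 'normal' | None before thresholding


@dataclass
class ThresholdReport:
    """IQR-rule threshold on the non-zero ACR distribution and the class counts."""

    q1: float
    q3: float
    threshold: float
    n_risky: int
    n_normal: int
    imbalance_ratio: float
    quartile_method: str = "linear"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "q1": self.q1,
                    "q3": self.q3,
                    "threshold": self.threshold,
                    "n_risky": self.n_risky,
                    "n_normal": self.n_normal,
                    "imbalance_ratio": self.imbalance_ratio,
                    "quartile_method": self.quartile_method,
                },
                fh,
                indent=2,
            )


def compute_dss(v_l, v_f, d, accelerating, c: RiskConstants | None = None):
    """Braking-distance margin (m) of a leader/follower pair.

    Parameters
    ----------
    v_l, v_f : float or array
        Leading and following longitudinal speeds, m/s, non-negative.
    d : float or array
        Longitudinal gap, m, non-negative.
    accelerating : bool or array
        Follower state: True selects the accelerating reaction time (1.5 s),
        False the decelerating-or-idling one (0.7 s).
    """
    c = c or RiskConstants()
    v_l = np.asarray(v_l, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(v_l < 0) or np.any(v_f < 0):
        raise DomainError("speeds must be non-negative")
    if np.any(d < 0):
        raise DomainError("gap must be non-negative")
    tau = np.where(np.asarray(accelerating, dtype=bool), c.tau_accel, c.tau_decel)
    out = (v_l**2 - v_f**2) / (2.0 * c.mu * c.g) + d - tau * v_f
    return float(out) if out.ndim == 0 else out


def compute_cr(dss, v_f):
    """Collision risk (s): extra reaction time needed when the margin is negative.

    Zero when DSS >= 0.  A stopped follower (v_f = 0) with a negative margin
    is returned as zero as well: it cannot close the gap, and the defining
    ratio is undefined there.
    """
    dss = np.asarray(dss, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    if np.any(v_f < 0):
        raise DomainError("follower speed must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.where((dss < 0) & (v_f > 0), np.abs(dss) / np.where(v_f > 0, v_f, 1.0), 0.0)
    return float(cr) if cr.ndim == 0 else cr


def compute_cr_series(pairs: PairSignals, c: RiskConstants | None = None):
    """Element-wise CR over the aligned pair series.

    Returns ``(cr_leader, cr_follower)`` arrays of the target's frame length;
    frames without a qualifying partner contribute 0.
    """
    c = c or RiskConstants()
    n = pairs.n_frames
    cr_l = np.zeros(n)
    cr_f = np.zeros(n)
    m = pairs.leader_valid
    if m.any():
        dss = compute_dss(
            pairs.leader_v_l[m],
            pairs.leader_v_f[m],
            pairs.leader_d[m],
            accel_state(pairs.leader_a_f[m]),
            c,
        )
        cr_l[m] = compute_cr(dss, pairs.leader_v_f[m])
    m = pairs.follower_valid
    if m.any():
        dss = compute_dss(
            pairs.follower_v_l[m],
            pairs.follower_v_f[m],
            pairs.follower_d[m],
            accel_state(pairs.follower_a_f[m]),
            c,
        )
        cr_f[m] = compute_cr(dss, pairs.follower_v_f[m])
    return cr_l, cr_f


def compute_acr(
    cr_leader, cr_follower, c: RiskConstants | None = None, T: float | None = None
) -> float:
    """Average collision risk: time-averaged sum of both CR series.

    ``T`` defaults to ``(n - 1) * dt``, the duration between the first and
    last frame, matching ``Trajectory.duration``.
    """
    c = c or RiskConstants()
    cr_leader = np.asarray(cr_leader, dtype=float)
    cr_follower = np.asarray(cr_follower, dtype=float)
    if cr_leader.shape != cr_follower.shape:
        raise DataError("CR series must have equal length")
    if T is None:
        T = (len(cr_leader) - 1) * c.dt
    if T <= 0:
        raise DomainError("observation duration T must be positive")
    return float(c.dt / T * np.sum(cr_leader + cr_follower))


def risk_profile(
    traj: Trajectory,
    all_trajectories: dict[int, Trajectory],
    lane_line_positions=None,
    c: RiskConstants | None = None,
    lane_changes: list[LaneChangeInterval] | None = None,
) -> RiskProfile:
    """Full risk evaluation of one vehicle against the traffic context."""
    c = c or RiskConstants()
    if lane_changes is None:
        lane_changes = (
            detect_lane_changes(traj, lane_line_positions)
            if lane_line_positions is not None
            else []
        )
    pairs = pair_signals(traj, all_trajectories, lane_changes=lane_changes)
    cr_l, cr_f = compute_cr_series(pairs, c)
    acr = compute_acr(cr_l, cr_f, c, T=traj.duration if traj.n_frames > 1 else None)
    return RiskProfile(traj.vehicle_id, cr_l, cr_f, acr)


def iqr_threshold(acrs) -> ThresholdReport:
    """IQR-rule risky-driver threshold on the non-zero ACR values.

    Quartiles are computed by linear interpolation on the non-zero subset
    only (zero-ACR drivers are safe by construction and excluded from the
    outlier rule).  A driver is risky iff ACR > threshold.
    """
    acrs = np.asarray(list(acrs), dtype=float)
    nz = acrs[acrs > 0]
    if len(nz) < 4:
        raise InsufficientDataError(
            f"need at least 4 non-zero ACR values, got {len(nz)}"
        )
    q1 = float(np.quantile(nz, 0.25))
    q3 = float(np.quantile(nz, 0.75))
    threshold = q3 + 1.5 * (q3 - q1)
    n_risky = int(np.sum(acrs > threshold))
    n_normal = len(acrs) - n_risky
    ratio = n_normal / n_risky if n_risky else float("inf")
    return ThresholdReport(q1, q3, threshold, n_risky, n_normal, ratio)


def label_profiles(
    profiles: list[RiskProfile], threshold: float | None = None
) -> tuple[list[RiskProfile], ThresholdReport | None]:
    """Attach risky/normal labels, deriving the IQR threshold if not given."""
    report = None
    if threshold is None:
        report = iqr_threshold([p.acr for p in profiles])
        threshold = report.threshold
    for p in profiles:
        p.label = "risky" if p.acr > threshold else "normal"
    if report is None:
        n_risky = sum(p.label == "risky" for p in profiles)
        n_normal = len(profiles) - n_risky
        report = ThresholdReport(
            float("nan"),
            float("nan"),
            threshold,
            n_risky,
            n_normal,
            n_normal / n_risky if n_risky else float("inf"),
        )
    return profiles, report


def profiles_to_frame(profiles: list[RiskProfile]) -> pd.DataFrame:
    """Per-driver table (vehicle_id, acr, label) for the CSV interface."""
    return pd.DataFrame(
        {
            "vehicle_id": [p.vehicle_id for p in profiles],
            "acr": [p.acr for p in profiles],
            "label": [p.label for p in profiles],
        }
    )
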