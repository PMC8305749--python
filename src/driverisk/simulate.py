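"""Synthetic data generators: a car-following traffic simulator and an
imbalanced classification sampler.

The traffic simulator emulates the drone-recorded highway schema so that the
whole trajectory -> risk-label -> feature pipeline is exercisable without the
restricted source data.  Vehicles drive in per-lane platoons behind a head
vehicle whose speed follows a slow sinusoidal perturbation; followers run a
time-gap-seeking proportional controller with bounded acceleration and an
emergency-stop guard that keeps gaps non-negative.  A planted fraction of
*aggressive* drivers holds a much smaller desired time gap, so braking-margin
violations (negative DSS) occur for them during the leader's deceleration
phases while ordinary drivers stay near zero risk.  A subset of vehicles
performs one lane change, producing centre-line crossings for the
lane-change detector.  The controller is deliberately a simple proportional
rule, not a named traffic-flow model: the goal is plantable risk with a
realistic schema, not flow fidelity.

The classification generator draws two multivariate Gaussian classes at a
controlled Mahalanobis separation and minority fraction, returns the exact
Bayes posterior of each sample, and exposes a power-law miscalibrated score
p_raw = p_true^(1/beta) (so the "true probability" is p_raw^beta): beta = 1
is perfectly calibrated, beta != 1 is a monotone distortion for calibration
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trajectory import Trajectory

LANE_WIDTH = 3.75  # m
VEHICLE_LENGTH = 5.0  # m


@dataclass
class TrafficSimParams:
    """Traffic simulator settings.

    The defaults emulate the recorded study conditions: one direction of a
    six-lane highway (3 lanes), a 420 m camera window's worth of initial
    platoon spacing, 0.04 s sampling, and a planted 5% aggressive-driver
    fraction (near the 4.29% risky share of the source population).
    """

    n_vehicles: int = 500
    n_lanes: int = 3
    road_length: float = 420.0
    dt: float = 0.04
    duration: float = 60.0
    aggressive_fraction: float = 0.05
    platoon_size: int = 12
    # desired time gap (s): mean/sd/floor per driver class
    normal_time_gap: tuple = (1.5, 0.3, 0.85)
    aggressive_time_gap: tuple = (0.55, 0.08, 0.35)
    desired_speed: tuple = (25.0, 2.0)  # mean, sd (m/s)
    max_accel: float = 2.0
    max_decel: float = 4.0
    aggressive_max_accel: float = 3.0
    aggressive_max_decel: float = 6.0
    # leader speed perturbation: amplitude (m/s), period (s)
    perturb_amplitude: float = 3.0
    perturb_period: float = 25.0
    lane_change_fraction: float = 0.1
    lane_change_duration: float = 4.0
    min_gap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggressive_time_gap[0] >= self.normal_time_gap[0]:
            raise ConfigError("aggressive drivers must have a smaller desired time gap")
        for name in ("n_vehicles", "n_lanes", "dt", "duration", "platoon_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.max_decel <= 0 or self.min_gap <= 0:
            raise ConfigError("decel bound and minimum gap must be positive")


@dataclass
class TrafficSample:
    """Simulator output: trajectories plus the planted ground truth."""

    trajectories: dict[int, Trajectory]
    ground_truth: pd.DataFrame  # vehicle_id, driver_class in {normal, aggressive}
    lane_lines: np.ndarray


def simulate_traffic(params: TrafficSimParams) -> TrafficSample:
    """Run the car-following simulation; deterministic given ``params.seed``."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_vehicles
    n_steps = int(round(p.duration / p.dt)) + 1

    # --- driver population -------------------------------------------------
    aggressive = rng.random(n) < p.aggressive_fraction
    mu, sd, floor = p.normal_time_gap
    tgap = np.maximum(rng.normal(mu, sd, n), floor)
    mu, sd, floor = p.aggressive_time_gap
    tgap[aggressive] = np.maximum(rng.normal(mu, sd, int(aggressive.sum())), floor)
    v_des = np.maximum(rng.normal(*p.desired_speed, size=n), 10.0)
    a_max = np.where(aggressive, p.aggressive_max_accel, p.max_accel)
    b_max = np.where(aggressive, p.aggressive_max_decel, p.max_decel)

    # --- initial layout: platoons per lane ---------------------------------
    lane0 = np.arange(n) % p.n_lanes
    x = np.zeros(n)
    platoon = np.zeros(n, dtype=int)
    head = np.zeros(n, dtype=bool)
    for lane in range(p.n_lanes):
        ids = np.nonzero(lane0 == lane)[0]
        pos = 0.0
        for i, vid in enumerate(ids):
            if i % p.platoon_size == 0:
                if i:
                    pos -= 120.0  # inter-platoon clearance
                head[vid] = True
            else:
                pos -= tgap[vid] * v_des[vid] + VEHICLE_LENGTH + p.min_gap + rng.uniform(0, 4)
            platoon[vid] = i // p.platoon_size
            x[vid] = pos
            pos = x[vid]
    v = v_des.copy()
    phase = rng.uniform(0, 2 * np.pi, size=n)  # per-head perturbation phase

    # --- lane-change schedule ----------------------------------------------
    centers = LANE_WIDTH * (np.arange(p.n_lanes) + 0.5)
    lines = LANE_WIDTH * np.arange(p.n_lanes + 1)
    cur_lane = lane0.copy()
    y = centers[cur_lane].astype(float)
    changers = rng.random(n) < p.lane_change_fraction
    changers &= ~head  # heads keep their lane; followers may merge
    t_change = rng.uniform(0.15, 0.75, size=n) * p.duration
    direction = np.where(
        cur_lane == 0, 1, np.where(cur_lane == p.n_lanes - 1, -1, rng.choice((-1, 1), n))
    )
    lc_from = cur_lane.copy()
    lc_done = np.zeros(n, dtype=bool)

    # --- storage ------------------------------------------------------------
    X = np.empty((n_steps, n))
    Y = np.empty((n_steps, n))
    V = np.empty((n_steps, n))
    VY = np.empty((n_steps, n))
    LN = np.empty((n_steps, n), dtype=np.int64)
    PREC = np.zeros((n_steps, n), dtype=np.int64)
    FOLL = np.zeros((n_steps, n), dtype=np.int64)
    GAP = np.full((n_steps, n), np.nan)

    kv, kg = 0.9, 0.35  # controller gains: speed tracking, gap closure

    for step in range(n_steps):
        t = step * p.dt

        # lateral kinematics of scheduled lane changes
        active = changers & ~lc_done & (t >= t_change)
        frac = np.clip((t - t_change) / p.lane_change_duration, 0.0, 1.0)
        y_new = centers[lc_from] + direction * LANE_WIDTH * frac
        y = np.where(active, y_new, y)
        lc_done |= changers & (frac >= 1.0)
        cur_lane = np.clip((y // LANE_WIDTH).astype(int), 0, p.n_lanes - 1)

        # neighbour structure per lane
        prec = np.full(n, -1)
        foll = np.full(n, -1)
        gap = np.full(n, np.nan)
        for lane in range(p.n_lanes):
            ids = np.nonzero(cur_lane == lane)[0]
            if len(ids) < 2:
                continue
            order = ids[np.argsort(-x[ids])]  # front to back
            prec[order[1:]] = order[:-1]
            foll[order[:-1]] = order[1:]
            gap[order[1:]] = x[order[:-1]] - x[order[1:]] - VEHICLE_LENGTH

        # record (ids are 1-based in the output dialect; 0 = none)
        X[step], Y[step], V[step], LN[step] = x, y, v, cur_lane + 1
        PREC[step] = np.where(prec >= 0, prec + 1, 0)
        FOLL[step] = np.where(foll >= 0, foll + 1, 0)
        GAP[step] = gap

        # longitudinal control
        has_lead = prec >= 0
        v_lead = np.where(has_lead, v[np.maximum(prec, 0)], 0.0)
        target_head = v_des + p.perturb_amplitude * np.sin(
            2 * np.pi * t / p.perturb_period + phase
        )
        a_free = kv * (target_head - v)
        desired_gap = tgap * v + p.min_gap
        a_follow = kv * (v_lead - v) + kg * (gap - desired_gap)
        a = np.where(has_lead, a_follow, a_free)
        a = np.clip(a, -b_max, a_max)
        v = np.maximum(v + a * p.dt, 0.0)
        x = x + v * p.dt

        # emergency guard: never overlap the leader
        for lane in range(p.n_lanes):
            ids = np.nonzero(cur_lane == lane)[0]
            if len(ids) < 2:
                continue
            order = ids[np.argsort(-x[ids])]
            for i in range(1, len(order)):
                me, lead = order[i], order[i - 1]
                limit = x[lead] - VEHICLE_LENGTH - 0.5
                if x[me] > limit:
                    x[me] = limit
                    v[me] = min(v[me], v[lead])

    VY[:] = np.gradient(Y, p.dt, axis=0)

    trajectories = {
        i + 1: Trajectory(
            vehicle_id=i + 1,
            frame=np.arange(n_steps, dtype=np.int64),
            x=X[:, i].copy(),
            y=Y[:, i].copy(),
            vx=V[:, i].copy(),
            vy=VY[:, i].copy(),
            lane_id=LN[:, i].copy(),
            preceding_id=PREC[:, i].copy(),
            following_id=FOLL[:, i].copy(),
            gap=GAP[:, i].copy(),
            dt=p.dt,
        )
        for i in range(n)
    }
    truth = pd.DataFrame(
        {
            "vehicle_id": np.arange(1, n + 1),
            "driver_class": np.where(aggressive, "aggressive", "normal"),
        }
    )
    return TrafficSample(trajectories, truth, lines)


# ---------------------------------------------------------------------------
# imbalanced classification generator


@dataclass
class ClassSimParams:
    """Imbalanced two-Gaussian classification problem.

    minority_fraction defaults to 1/23.3 so the majority/minority count
    ratio is 22.3, the study condition of the source population.
    separation is the Mahalanobis distance between the class means;
    beta is the power-law miscalibration exponent (1 = calibrated).
    """

    n_samples: int = 2427
    n_features: int = 69
    minority_fraction: float = 1.0 / 23.3
    separation: float = 3.0
    covariance_scale: float = 1.0
    label_noise: float = 0.0
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.minority_fraction <= 0.5):
            raise ConfigError("minority_fraction must lie in (0, 0.5]")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if self.covariance_scale <= 0:
            raise ConfigError("covariance_scale must be positive")


@dataclass
class ClassSample:
    """Generated dataset with the exact Bayes posterior and the distorted score."""

    X: np.ndarray
    y: np.ndarray
    p_true: np.ndarray  # exact Bayes posterior P(y=1 | x)
    p_raw: np.ndarray  # miscalibrated score: p_true = p_raw ** beta

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.X, columns=[f"f{j}" for j in range(self.X.shape[1])]
        )
        df["label"] = self.y
        return df


def generate_classification(params: ClassSimParams) -> ClassSample:
    """Draw the two-Gaussian imbalanced sample.

    Class 0 is N(0, s I), class 1 is N(mu, s I) with |mu|/sqrt(s) equal to
    ``separation``; the minority count is the rounded requested fraction
    exactly.  The returned ``p_true`` is the analytic posterior under the
    generating model (including the prior odds); ``p_raw`` applies the
    monotone power distortion.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n1 = max(1, int(round(p.n_samples * p.minority_fraction)))
    n0 = p.n_samples - n1
    s = np.sqrt(p.covariance_scale)
    mu = np.zeros(p.n_features)
    mu[:] = p.separation * s / np.sqrt(p.n_features)

    X0 = rng.normal(0.0, s, size=(n0, p.n_features))
    X1 = rng.normal(0.0, s, size=(n1, p.n_features)) + mu
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    perm = rng.permutation(p.n_samples)
    X, y = X[perm], y[perm]

    # exact posterior: log-odds = x^T Sigma^-1 mu - mu^T Sigma^-1 mu / 2 + log(pi1/pi0)
    prior_logodds = np.log(n1 / n0)
    z = (X @ mu - 0.5 * mu @ mu) / p.covariance_scale + prior_logodds
    p_true = 1.0 / (1.0 + np.exp(-z))

    if p.label_noise > 0:
        flip = rng.random(p.n_samples) < p.label_noise
        y = np.where(flip, 1 - y, y)

    p_raw = p_true ** (1.0 / p.beta)
    return ClassSample(X, y, p_true, p_raw)
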