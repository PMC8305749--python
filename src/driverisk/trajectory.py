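"""Vehicle-trajectory ingestion and kinematic signal derivation.

Trajectories follow the drone-recorded highway CSV dialect: one row per
(frame, vehicle), with longitudinal/lateral position and speed, the lane id,
the ids of the preceding and following vehicles in the same lane, and the
precomputed gap (distance headway) to the preceding vehicle.  Frames are
sampled every 0.04 s.  A vehicle is eligible for risk modelling only when it
was observed for more than 10 s.

This module turns those tables into per-vehicle :class:`Trajectory` objects,
detects lane-change intervals from the lateral position, and joins
leader/follower pairs into the aligned speed-and-gap series that the risk
equations and the feature extractor consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

DT = 0.04
"""Sampling interval of the trajectory recordings, seconds."""

MIN_DURATION = 10.0
"""Minimum observed duration (s) for a vehicle to be eligible for modelling."""

LEADER_RANGE = 50.0
"""Maximum gap (m) at which a preceding vehicle counts as a leader."""

#: Default column names of the input CSV; remap via the ``dialect`` argument.
DEFAULT_DIALECT = {
    "frame": "frame",
    "id": "id",
    "x": "x",
    "y": "y",
    "vx": "xVelocity",
    "vy": "yVelocity",
    "lane_id": "laneId",
    "preceding_id": "precedingId",
    "following_id": "followingId",
    "gap": "dhw",
}

_ACCEL_DEADBAND = 0.05  # m/s^2; |a| below this counts as idling


@dataclass
class Trajectory:
    """Kinematic time series of one vehicle.

    Frame indices are stored 0-based and strictly increasing; ``preceding_id``
    and ``following_id`` use 0 for "no such vehicle" as in the source dialect.
    ``gap`` is NaN when there is no preceding vehicle.
    """

    vehicle_id: int
    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    lane_id: np.ndarray
    preceding_id: np.ndarray
    following_id: np.ndarray
    gap: np.ndarray
    dt: float = DT

    def __post_init__(self) -> None:
        if len(self.frame) >= 2 and not np.all(np.diff(self.frame) > 0):
            raise DataError(
                f"vehicle {self.vehicle_id}: frame indices not strictly increasing"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def duration(self) -> float:
        """Observed duration (s): (n_frames - 1) * dt."""
        return (self.n_frames - 1) * self.dt

    @property
    def eligible(self) -> bool:
        """True when the vehicle was observed for more than 10 s."""
        return self.duration > MIN_DURATION

    def accel(self) -> np.ndarray:
        """Longitudinal acceleration (m/s^2) by central differences of vx."""
        if self.n_frames < 2:
            return np.zeros(self.n_frames)
        return np.gradient(self.vx, self.dt)

    def gap_series(self, cap: float = LEADER_RANGE) -> np.ndarray:
        """Gap signal for feature extraction, capped at ``cap``.

        Frames without a leader within range are imputed at the cap, which
        bounds the spectral input without sentinel spikes.
        """
        g = np.where(np.isfinite(self.gap), self.gap, cap)
        return np.minimum(g, cap)


@dataclass
class LaneChangeInterval:
    """A lane-change manoeuvre: from the frame where the vehicle centre
    crosses a lane line to the first frame where its distance to that line
    exceeds 0.5 m (or the end of the trajectory)."""

    vehicle_id: int
    start_frame: int
    end_frame: int
    target_lane_id: int
    line_position: float = field(default=np.nan, compare=False)


def _resolve_dialect(dialect: dict[str, str] | None) -> dict[str, str]:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(d)
        if unknown:
            raise SchemaError(f"unknown dialect keys: {sorted(unknown)}")
        d.update(dialect)
    return d


def read_trajectories(
    path, dialect: dict[str, str] | None = None
) -> dict[int, Trajectory]:
    """Read a highway-trajectory CSV into per-vehicle :class:`Trajectory` objects.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row.
    dialect : dict, optional
        Mapping from canonical field names (``frame``, ``id``, ``x``, ``y``,
        ``vx``, ``vy``, ``lane_id``, ``preceding_id``, ``following_id``,
        ``gap``) to the column names used in the file.

    Returns
    -------
    dict
        ``{vehicle_id: Trajectory}`` with frames sorted.  Vehicles observed
        for 10 s or less are kept but flagged via ``Trajectory.eligible``.
    """
    cols = _resolve_dialect(dialect)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    inv = {v: k for k, v in cols.items()}
    df = df[list(cols.values())].rename(columns=inv)

    out: dict[int, Trajectory] = {}
    for vid, g in df.groupby("id", sort=True):
        g = g.sort_values("frame")
        frame = g["frame"].to_numpy(dtype=np.int64)
        if len(frame) >= 2 and not np.all(np.diff(frame) > 0):
            raise DataError(f"vehicle {vid}: duplicate or non-monotone frames")
        gap = g["gap"].to_numpy(dtype=float)
        out[int(vid)] = Trajectory(
            vehicle_id=int(vid),
            frame=frame - frame[0],
            x=g["x"].to_numpy(dtype=float),
            y=g["y"].to_numpy(dtype=float),
            vx=g["vx"].to_numpy(dtype=float),
            vy=g["vy"].to_numpy(dtype=float),
            lane_id=g["lane_id"].to_numpy(dtype=np.int64),
            preceding_id=g["preceding_id"].fillna(0).to_numpy(dtype=np.int64),
            following_id=g["following_id"].fillna(0).to_numpy(dtype=np.int64),
            gap=gap,
        )
    return out


def write_trajectories(
    trajectories: dict[int, Trajectory] | list[Trajectory],
    path,
    dialect: dict[str, str] | None = None,
) -> None:
    """Write trajectories back to the CSV dialect used by :func:`read_trajectories`."""
    cols = _resolve_dialect(dialect)
    if isinstance(trajectories, dict):
        trajectories = list(trajectories.values())
    parts = []
    for t in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    cols["frame"]: t.frame,
                    cols["id"]: t.vehicle_id,
                    cols["x"]: t.x,
                    cols["y"]: t.y,
                    cols["vx"]: t.vx,
                    cols["vy"]: t.vy,
                    cols["lane_id"]: t.lane_id,
                    cols["preceding_id"]: t.preceding_id,
                    cols["following_id"]: t.following_id,
                    cols["gap"]: t.gap,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def detect_lane_changes(
    traj: Trajectory, lane_line_positions
) -> list[LaneChangeInterval]:
    """Detect lane-change intervals from the lateral position signal.

    A manoeuvre starts at the first frame after the vehicle centre crosses a
    lane line (sign change of ``y - line`` between consecutive frames) and
    ends at the first subsequent frame whose distance to that line exceeds
    0.5 m, or at the end of the trajectory if the excursion never completes.
    The rule is invariant to a common lateral translation of ``y`` and the
    line positions.
    """
    lines = np.sort(np.asarray(lane_line_positions, dtype=float))
    y = traj.y
    n = len(y)
    intervals: list[LaneChangeInterval] = []
    if n < 2:
        return intervals
    last_end = -1
    for i in range(1, n):
        if i <= last_end:
            continue
        for line in lines:
            s0, s1 = y[i - 1] - line, y[i] - line
            if (s0 < 0 <= s1) or (s0 > 0 >= s1):
                beyond = np.nonzero(np.abs(y[i:] - line) > 0.5)[0]
                end = i + beyond[0] if len(beyond) else n - 1
                intervals.append(
                    LaneChangeInterval(
                        vehicle_id=traj.vehicle_id,
                        start_frame=i,
                        end_frame=int(end),
                        target_lane_id=int(traj.lane_id[int(end)]),
                        line_position=float(line),
                    )
                )
                last_end = int(end)
                break
    return intervals


@dataclass
class PairSignals:
    """Leader/follower speed-and-gap series aligned to a target trajectory.

    For each frame of the target vehicle two (leading-speed, following-speed,
    gap, follower-acceleration) tuples may exist:

    * the *leader pair* — target follows its preceding vehicle, valid when the
      gap is at most 50 m;
    * the *follower pair* — the rear vehicle in the target lane follows the
      target, valid only during a lane-change interval of the target.

    Invalid frames are masked out; downstream they contribute zero risk.
    """

    frames: np.ndarray
    leader_valid: np.ndarray
    leader_v_l: np.ndarray
    leader_v_f: np.ndarray
    leader_d: np.ndarray
    leader_a_f: np.ndarray
    follower_valid: np.ndarray
    follower_v_l: np.ndarray
    follower_v_f: np.ndarray
    follower_d: np.ndarray
    follower_a_f: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _frame_lookup(t: Trajectory) -> dict[int, int]:
    return {int(f): i for i, f in enumerate(t.frame)}


def pair_signals(
    traj: Trajectory,
    all_trajectories: dict[int, Trajectory],
    max_range: float = LEADER_RANGE,
    lane_changes: list[LaneChangeInterval] | None = None,
) -> PairSignals:
    """Join the target vehicle with its leader and (during lane changes) its
    follower into aligned per-frame series.

    The leader pair is emitted wherever the preceding vehicle exists and the
    gap is within ``max_range``.  The follower pair is emitted only inside
    the supplied lane-change intervals, with the target acting as the leading
    vehicle.  Dangling partner ids raise :class:`DataError`.
    """
    n = traj.n_frames
    lv = np.zeros(n, bool)
    lvl = np.zeros(n)
    lvf = np.zeros(n)
    ld = np.zeros(n)
    laf = np.zeros(n)
    fv = np.zeros(n, bool)
    fvl = np.zeros(n)
    fvf = np.zeros(n)
    fd = np.zeros(n)
    faf = np.zeros(n)

    own_accel = traj.accel()
    dangling: set[int] = set()
    lookups: dict[int, dict[int, int]] = {}

    def _idx(pid: int, frame: int) -> int | None:
        t = all_trajectories.get(pid)
        if t is None:
            dangling.add(pid)
            return None
        if pid not in lookups:
            lookups[pid] = _frame_lookup(t)
        return lookups[pid].get(frame)

    for i in range(n):
        pid = int(traj.preceding_id[i])
        if pid != 0:
            j = _idx(pid, int(traj.frame[i]))
            if j is not None:
                d = traj.gap[i]
                if not np.isfinite(d):
                    lead = all_trajectories[pid]
                    d = lead.x[j] - traj.x[i]
                if 0 <= d <= max_range:
                    lv[i] = True
                    lvl[i] = all_trajectories[pid].vx[j]
                    lvf[i] = traj.vx[i]
                    ld[i] = d
                    laf[i] = own_accel[i]

    if lane_changes:
        in_change = np.zeros(n, bool)
        for iv in lane_changes:
            in_change[iv.start_frame : iv.end_frame + 1] = True
        accels: dict[int, np.ndarray] = {}
        for i in np.nonzero(in_change)[0]:
            fid = int(traj.following_id[i])
            if fid == 0:
                continue
            j = _idx(fid, int(traj.frame[i]))
            if j is None:
                continue
            rear = all_trajectories[fid]
            d = rear.gap[j]
            if not np.isfinite(d):
                d = traj.x[i] - rear.x[j]
            if d < 0:
                continue
            if fid not in accels:
                accels[fid] = rear.accel()
            fv[i] = True
            fvl[i] = traj.vx[i]
            fvf[i] = rear.vx[j]
            fd[i] = d
            faf[i] = accels[fid][j]

    if dangling:
        raise DataError(f"dangling partner vehicle id(s): {sorted(dangling)}")

    return PairSignals(
        frames=traj.frame.copy(),
        leader_valid=lv,
        leader_v_l=lvl,
        leader_v_f=lvf,
        leader_d=ld,
        leader_a_f=laf,
        follower_valid=fv,
        follower_v_l=fvl,
        follower_v_f=fvf,
        follower_d=fd,
        follower_a_f=faf,
    )


def accel_state(a: np.ndarray, deadband: float = _ACCEL_DEADBAND) -> np.ndarray:
    """Classify acceleration into follower states.

    Returns a boolean array: True where the vehicle is accelerating
    (a > +deadband), False where decelerating or idling.  The dead-band
    avoids chattering between the two reaction times at a ≈ 0.
    """
    return np.asarray(a) > deadband


def write_intervals(intervals: list[LaneChangeInterval], path) -> None:
    """Write lane-change intervals as CSV (vehicle_id,start_frame,end_frame,target_lane)."""
    pd.DataFrame(
        [
            {
                "vehicle_id": iv.vehicle_id,
                "start_frame": iv.start_frame,
                "end_frame": iv.end_frame,
                "target_lane": iv.target_lane_id,
            }
            for iv in intervals
        ]
    ).to_csv(path, index=False)
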