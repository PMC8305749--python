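import numpy as np
import pandas as pd
import pytest

from driverisk.losses import BoosterParams
from driverisk.simulate import ClassSimParams, generate_classification


@pytest.fixture(scope="session")
def small_booster() -> BoosterParams:
    """A light booster configuration for fast CV loops."""
    return BoosterParams(
        n_estimators=40, max_depth=3, learning_rate=0.3, subsample=1.0, colsample_bytree=1.0
    )


@pytest.fixture(scope="session")
def imbalanced_sample():
    """Separable imbalanced two-Gaussian sample (n=600, 15% minority)."""
    return generate_classification(
        ClassSimParams(
            n_samples=600, n_features=8, minority_fraction=0.15, separation=3.0, seed=2
        )
    )


@pytest.fixture()
def toy_trajectory_csv(tmp_path):
    """Two vehicles, three frames each, vehicle 2 leading vehicle 1."""
    rows = []
    for f in range(3):
        rows.append(
            dict(frame=f, id=1, x=10.0 + f, y=1.875, xVelocity=25.0, yVelocity=0.0,
                 laneId=1, precedingId=2, followingId=0, dhw=20.0)
        )
        rows.append(
            dict(frame=f, id=2, x=35.0 + f, y=1.875, xVelocity=25.0, yVelocity=0.0,
                 laneId=1, precedingId=0, followingId=1, dhw=np.nan)
        )
    path = tmp_path / "toy.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def make_trajectory(vehicle_id=1, n=300, y=None, vx=None, gap=None, lane_id=None,
                    preceding=0, following=0, dt=0.04):
    """Helper constructing a Trajectory with simple defaults."""
    from driverisk.trajectory import Trajectory

    frame = np.arange(n, dtype=np.int64)
    return Trajectory(
        vehicle_id=vehicle_id,
        frame=frame,
        x=np.cumsum(np.full(n, 25.0 * dt)),
        y=np.full(n, 1.875) if y is None else np.asarray(y, dtype=float),
        vx=np.full(n, 25.0) if vx is None else np.asarray(vx, dtype=float),
        vy=np.zeros(n),
        lane_id=np.ones(n, dtype=np.int64) if lane_id is None else np.asarray(lane_id),
        preceding_id=np.full(n, preceding, dtype=np.int64),
        following_id=np.full(n, following, dtype=np.int64),
        gap=np.full(n, np.nan) if gap is None else np.asarray(gap, dtype=float),
        dt=dt,
    )
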