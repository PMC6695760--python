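import numpy as np
import pytest

from pmspt.tracking import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_trajectory(rng, n_points=10, with_gaps=False) -> Trajectory:
    """A random walk trajectory for oracle-equivalence checks."""
    n = int(n_points)
    frames = np.arange(n)
    if with_gaps and n > 4:
        drop = rng.choice(np.arange(1, n - 1), size=rng.integers(0, 2),
                          replace=False)
        frames = np.delete(frames, drop)
    m = len(frames)
    x = np.cumsum(rng.normal(0, 0.05, m))
    y = np.cumsum(rng.normal(0, 0.05, m))
    return Trajectory(0, frames, x, y, np.ones(m))


def msd_bruteforce(traj: Trajectory, max_lag: int, dt: float):
    """Independent double-loop MSD oracle (contiguous pairs only)."""
    frames, x, y = traj.frames, traj.x_um, traj.y_um
    out = []
    for k in range(1, max_lag + 1):
        vals = []
        for i in range(len(frames)):
            for j in range(len(frames)):
                if frames[j] - frames[i] == k and j - i == k:
                    vals.append((x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2)
        out.append((k * dt, float(np.mean(vals)) if vals else 0.0, len(vals)))
    return out
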