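import numpy as np
import pytest

from motioncomplexity.trajectory_core import MotionPattern, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ellipse_trajectory(T=150, a=3.0, b=2.0, center=(5.0, 5.0), noise=0.0, rng=None):
    s = np.linspace(0.0, 1.0, T)
    xs = center[0] + a * np.cos(2 * np.pi * s)
    ys = center[1] + b * np.sin(2 * np.pi * s)
    if noise > 0.0:
        xs = xs + rng.normal(0.0, noise, T)
        ys = ys + rng.normal(0.0, noise, T)
    return Trajectory(np.arange(1, T + 1, dtype=float), xs, ys)


@pytest.fixture
def ellipse_pattern(rng):
    """Ten noisy repetitions of one ellipse, resampled to T=150."""
    reps = tuple(make_ellipse_trajectory(noise=0.05, rng=rng) for _ in range(10))
    return MotionPattern("s01", 1, reps)


@pytest.fixture
def tiny_pattern():
    """Two tiny constant-offset repetitions for hand-checkable variance."""
    t = np.arange(1, 6, dtype=float)
    rep_a = Trajectory(t, np.zeros(5), np.zeros(5))
    rep_b = Trajectory(t, np.full(5, 2.0), np.zeros(5))
    return MotionPattern("s01", 1, (rep_a, rep_b))
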