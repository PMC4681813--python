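"""Core data model for 2-D hand-motion trajectories.

A *trajectory* is one time-ordered pass through the workspace; a *motion
pattern* is the set of N repetitions of one self-chosen closed-form movement
(one experimental trial).  All positions are in centimetres inside a
``width x height`` workspace with the origin at the lower-left corner,
x rightward and y upward.

This module owns time-resampling, the across-repetition variance measure,
and the tabular file format shared by the command-line tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "MotionPattern",
    "Workspace",
    "FormatError",
    "resample_trajectory",
    "pattern_variance",
    "read_patterns",
    "write_patterns",
    "DEFAULT_T",
    "DEFAULT_N",
]

#: default number of equidistant samples per trajectory after resampling
DEFAULT_T = 150
#: default number of repetitions per motion pattern
DEFAULT_N = 10

PATTERN_COLUMNS = ["subject", "trial", "repetition", "t", "x", "y"]


class FormatError(ValueError):
    """Raised when a trajectory table violates the documented dialect."""


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered sequence of 2-D positions.

    Parameters
    ----------
    times
        Strictly increasing sample times (arbitrary units).
    xs, ys
        Horizontal / vertical position in cm, same length as ``times``.
    """

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.xs, dtype=float)
        y = np.asarray(self.ys, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise ValueError("times, xs, ys must be 1-D")
        if not (len(t) == len(x) == len(y)):
            raise ValueError("times, xs, ys must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in trajectory")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xs", x)
        object.__setattr__(self, "ys", y)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def positions(self) -> np.ndarray:
        """(T, 2) array of [x, y] rows."""
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class MotionPattern:
    """The N repeated trajectories of one trial."""

    subject_id: str
    trial_id: int
    repetitions: tuple[Trajectory, ...]

    def __post_init__(self) -> None:
        reps = tuple(self.repetitions)
        if len(reps) < 2:
            raise ValueError("a motion pattern needs at least 2 repetitions")
        object.__setattr__(self, "repetitions", reps)

    @property
    def n_repetitions(self) -> int:
        return len(self.repetitions)

    def resampled(self, T: int = DEFAULT_T) -> "MotionPattern":
        """Return a copy with every repetition resampled to ``T`` points."""
        return MotionPattern(
            self.subject_id,
            self.trial_id,
            tuple(resample_trajectory(r, T) for r in self.repetitions),
        )

    def common_length(self) -> int:
        lengths = {len(r) for r in self.repetitions}
        if len(lengths) != 1:
            raise ValueError("repetitions have unequal lengths; resample first")
        return lengths.pop()


@dataclass(frozen=True)
class Workspace:
    """Rectangular drawing area tessellated into square grid cells."""

    width: float = 10.0
    height: float = 10.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.cell_size <= 0:
            raise ValueError("workspace dimensions must be positive")
        for extent in (self.width, self.height):
            ratio = extent / self.cell_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError("width and height must be integer multiples of cell_size")

    @property
    def n_cols(self) -> int:
        return int(round(self.width / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(round(self.height / self.cell_size))


def resample_trajectory(traj: Trajectory, T: int) -> Trajectory:
    """Resample to ``T`` points equidistant in recorded time.

    Positions are linearly interpolated; the first and last samples are
    preserved exactly.  Resampling is equidistant in *time*, not arc length.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if len(traj) < 2:
        raise ValueError("cannot resample a trajectory with fewer than 2 samples")
    new_t = np.linspace(traj.times[0], traj.times[-1], T)
    # exact endpoints regardless of float rounding in linspace
    new_t[0], new_t[-1] = traj.times[0], traj.times[-1]
    xs = np.interp(new_t, traj.times, traj.xs)
    ys = np.interp(new_t, traj.times, traj.ys)
    return Trajectory(new_t, xs, ys)


def pattern_variance(pattern: MotionPattern) -> float:
    """Across-repetition variance of a motion pattern (cm^2).

    For each time index and each spatial dimension the unbiased sample
    variance across the N repetitions is computed; variances are summed over
    x and y and averaged over the time indices.  The measure is invariant
    under rigid translation and scales quadratically with uniform scaling.
    """
    if pattern.n_repetitions < 2:
        raise ValueError("variance needs at least 2 repetitions")
    pattern.common_length()
    stack = np.stack([r.positions for r in pattern.repetitions])  # (N, T, 2)
    per_point = stack.var(axis=0, ddof=1)  # (T, 2)
    return float(per_point.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# tabular I/O


def write_patterns(patterns: Iterable[MotionPattern], path) -> None:
    """Write patterns as a CSV with columns subject,trial,repetition,t,x,y."""
    frames = []
    for p in patterns:
        for k, rep in enumerate(p.repetitions):
            frames.append(
                pd.DataFrame(
                    {
                        "subject": p.subject_id,
                        "trial": p.trial_id,
                        "repetition": k,
                        "t": rep.times,
                        "x": rep.xs,
                        "y": rep.ys,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False, float_format="%.17g")


def read_patterns(path) -> list[MotionPattern]:
    """Read motion patterns from the documented CSV dialect.

    Rows are grouped by (subject, trial, repetition) and sorted by time;
    duplicate time stamps within a repetition, missing columns or
    non-numeric coordinates raise :class:`FormatError`.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PATTERN_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    for col in ("t", "x", "y"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()]
        if len(bad):
            raise FormatError(f"non-numeric value in column {col!r} at row {bad[0]}")
        table[col] = vals
    dup = table.duplicated(subset=["subject", "trial", "repetition", "t"])
    if dup.any():
        raise FormatError(
            f"duplicate (subject, trial, repetition, t) key at row {table.index[dup][0]}"
        )
    patterns: list[MotionPattern] = []
    for (subject, trial), group in table.groupby(["subject", "trial"], sort=True):
        reps = []
        for rep_idx, rep_rows in group.groupby("repetition", sort=True):
            rep_rows = rep_rows.sort_values("t")
            if len(rep_rows) < 2:
                raise FormatError(
                    f"repetition {rep_idx} of subject {subject} trial {trial} "
                    f"has fewer than 2 samples"
                )
            reps.append(
                Trajectory(
                    rep_rows["t"].to_numpy(),
                    rep_rows["x"].to_numpy(),
                    rep_rows["y"].to_numpy(),
                )
            )
        patterns.append(MotionPattern(str(subject), int(trial), tuple(reps)))
    return patterns
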