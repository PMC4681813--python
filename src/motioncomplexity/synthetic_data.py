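"""Synthetic motion patterns with controlled complexity and variability.

Four canonical pattern classes dissociate spatial complexity (frequency
content of the base curve) from across-repetition variability (amplitude of
a smooth per-repetition perturbation):

``random_high_var``
    no repeatable base curve: each repetition is an independent lightly
    smoothed random walk, closed by detrending.
``complex_low_var``
    a closed multi-harmonic base curve, repeated almost exactly.
``ellipse_high_var`` / ``ellipse_low_var``
    a plain ellipse with large / small repetition variability.
``graded``
    harmonic base curves whose frequency content grows with a continuous
    ``complexity_grade``, for dose-response experiments.

Per-repetition variability is a smooth (low-pass filtered, periodic)
Gaussian field rather than i.i.d. point noise, mimicking imperfect motor
memory rather than sensor jitter.  All patterns are scaled into the
workspace and clipped so bounds are respected exactly.

The module also simulates whole experiments (subjects x trials) and noisy
jury rankings so the correlation pipeline can be exercised end to end with
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .trajectory_core import DEFAULT_N, DEFAULT_T, MotionPattern, Trajectory, Workspace

__all__ = [
    "PatternSpec",
    "generate_pattern",
    "generate_experiment",
    "simulate_jury",
    "JuryResult",
    "PATTERN_CLASSES",
]

PATTERN_CLASSES = (
    "random_high_var",
    "complex_low_var",
    "ellipse_high_var",
    "ellipse_low_var",
    "graded",
)

#: repetition-variability defaults (cm): large vs small smooth perturbations
SIGMA_HIGH = 0.4
SIGMA_LOW = 0.1
#: harmonics in the complex base curve
COMPLEX_HARMONICS = 10
#: margin (cm) kept between the base curve and the workspace edge
MARGIN = 1.5


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for one synthetic motion pattern."""

    pattern_class: str = "ellipse_low_var"
    complexity_grade: float = 0.0
    sigma_rep: float | None = None
    n_rep: int = DEFAULT_N
    T: int = DEFAULT_T
    seed: int | None = None
    workspace: Workspace = field(default_factory=Workspace)

    def __post_init__(self) -> None:
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern class {self.pattern_class!r}")
        if self.complexity_grade < 0:
            raise ValueError("complexity_grade must be >= 0")
        if self.n_rep < 2 or self.T < 2:
            raise ValueError("need n_rep >= 2 and T >= 2")
        if self.sigma_rep is not None and self.sigma_rep < 0:
            raise ValueError("sigma_rep must be >= 0")

    @property
    def effective_sigma(self) -> float:
        if self.sigma_rep is not None:
            return self.sigma_rep
        return SIGMA_HIGH if self.pattern_class.endswith("high_var") else SIGMA_LOW


def _harmonic_curve(rng: np.random.Generator, s: np.ndarray, K: int) -> np.ndarray:
    """Random closed curve from K equal-amplitude harmonics.

    The flat spectrum keeps high harmonics fully visible, so larger K
    genuinely shortens the curve's correlation length.
    """
    out = np.zeros((len(s), 2))
    for k in range(1, K + 1):
        amp = 1.0
        coeffs = rng.normal(0.0, amp, size=4)  # a_x, b_x, a_y, b_y
        arg = 2.0 * np.pi * k * s
        out[:, 0] += coeffs[0] * np.cos(arg) + coeffs[1] * np.sin(arg)
        out[:, 1] += coeffs[2] * np.cos(arg) + coeffs[3] * np.sin(arg)
    return out


def _smooth_field(rng: np.random.Generator, T: int, sigma: float) -> np.ndarray:
    """Smooth periodic perturbation field, sd ``sigma`` per coordinate (cm)."""
    if sigma == 0.0:
        return np.zeros((T, 2))
    noise = rng.standard_normal((T, 2))
    # long correlation length: variability displaces whole curve sections
    # smoothly (imperfect memory), it does not add wiggliness
    smooth = gaussian_filter1d(noise, sigma=T / 8.0, axis=0, mode="wrap")
    sd = smooth.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return sigma * smooth / sd


def _fit_to_box(xy: np.ndarray, ws: Workspace, margin: float) -> np.ndarray:
    """Affinely map a curve into the workspace minus a margin."""
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    target_lo = np.array([margin, margin])
    target_hi = np.array([ws.width - margin, ws.height - margin])
    return target_lo + (xy - lo) / span * (target_hi - target_lo)


def generate_pattern(spec: PatternSpec) -> MotionPattern:
    """Generate one seeded motion pattern according to its spec."""
    rng = np.random.default_rng(spec.seed)
    ws = spec.workspace
    T, n_rep = spec.T, spec.n_rep
    s = np.linspace(0.0, 1.0, T)
    times = np.arange(1, T + 1, dtype=float)
    sigma = spec.effective_sigma

    reps: list[Trajectory] = []
    if spec.pattern_class == "random_high_var":
        # independent smoothed random walks; no shared base curve
        for _ in range(n_rep):
            steps = rng.standard_normal((T, 2))
            walk = np.cumsum(steps, axis=0)
            # strong low-pass: erratic but locally smooth meander, so the
            # roughness a GP must explain sits in the noise, not the signal
            walk = gaussian_filter1d(walk, sigma=8.0, axis=0, mode="nearest")
            # close the curve by removing the linear drift
            ramp = np.linspace(0.0, 1.0, T)[:, None]
            walk = walk - walk[0] - ramp * (walk[-1] - walk[0])
            xy = _fit_to_box(walk, ws, MARGIN)
            xy = np.clip(xy, [0.0, 0.0], [ws.width, ws.height])
            reps.append(Trajectory(times, xy[:, 0], xy[:, 1]))
        return MotionPattern("synthetic", 1, tuple(reps))

    if spec.pattern_class in ("ellipse_high_var", "ellipse_low_var"):
        # each pattern is a different simple ellipse, as each human pattern
        # is a different drawing: random aspect ratio and orientation
        aspect = rng.uniform(1.2, 2.0)
        angle = rng.uniform(0.0, np.pi)
        raw = np.column_stack([aspect * np.cos(2 * np.pi * s), np.sin(2 * np.pi * s)])
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        base = raw @ rot.T
    elif spec.pattern_class == "complex_low_var":
        base = _harmonic_curve(rng, s, COMPLEX_HARMONICS)
    else:  # graded
        K = max(1, int(round(1 + spec.complexity_grade)))
        base = _harmonic_curve(rng, s, K)

    base = _fit_to_box(base, ws, MARGIN)
    for _ in range(n_rep):
        xy = base + _smooth_field(rng, T, sigma)
        xy = np.clip(xy, [0.0, 0.0], [ws.width, ws.height])
        reps.append(Trajectory(times, xy[:, 0], xy[:, 1]))
    return MotionPattern("synthetic", 1, tuple(reps))


def generate_experiment(
    n_subjects: int,
    n_trials: int,
    grade_assignment: Mapping[str, float] | None = None,
    sigma_rep: float = SIGMA_LOW,
    seed: int | None = None,
    n_rep: int = DEFAULT_N,
    T: int = DEFAULT_T,
) -> tuple[list[MotionPattern], dict[str, float]]:
    """Simulate ``n_subjects x n_trials`` graded patterns with known grades.

    Each subject draws all its patterns at its assigned complexity grade
    (default: grades spread linearly over 0..4).  Returns the patterns,
    with subject/trial identifiers set, and the ground-truth grade map.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    subjects = [f"s{i + 1:02d}" for i in range(n_subjects)]
    if grade_assignment is None:
        grades = np.linspace(0.0, 4.0, n_subjects)
        grade_assignment = dict(zip(subjects, grades))
    else:
        subjects = list(grade_assignment)
    seeds = np.random.SeedSequence(seed).spawn(len(subjects) * n_trials)
    patterns: list[MotionPattern] = []
    k = 0
    for subject in subjects:
        for trial in range(1, n_trials + 1):
            spec = PatternSpec(
                pattern_class="graded",
                complexity_grade=float(grade_assignment[subject]),
                sigma_rep=sigma_rep,
                n_rep=n_rep,
                T=T,
                seed=seeds[k].generate_state(1)[0] % (2**31),
            )
            k += 1
            p = generate_pattern(spec)
            patterns.append(MotionPattern(subject, trial, p.repetitions))
    return patterns, dict(grade_assignment)


@dataclass(frozen=True)
class JuryResult:
    """Simulated jury rankings: raw per-juror ranks and their average."""

    per_juror: pd.DataFrame  # columns: trial, subject, juror, rank
    average: pd.DataFrame    # columns: trial, subject, average_rank


def simulate_jury(
    true_scores: pd.DataFrame,
    n_jurors: int = 10,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> JuryResult:
    """Rank patterns within each trial by noisy perceived score.

    ``true_scores`` has columns ``trial``, ``subject``, ``score``.  Each
    juror perceives ``score + N(0, noise_sd^2)`` and ranks the m patterns
    of a trial 1..m, highest perceived score getting the top rank m (10 =
    most creative in the canonical setup).  Exact ties are broken by
    subject order (earlier subject -> lower rank).
    """
    required = {"trial", "subject", "score"}
    if not required.issubset(true_scores.columns):
        raise ValueError(f"true_scores needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for trial, group in true_scores.groupby("trial", sort=True):
        m = len(group)
        if m < 2:
            raise ValueError(f"trial {trial} has fewer than 2 patterns")
        subjects = group["subject"].to_numpy()
        scores = group["score"].to_numpy(dtype=float)
        for juror in range(1, n_jurors + 1):
            perceived = scores + rng.normal(0.0, noise_sd, size=m)
            order = np.lexsort((np.arange(m), perceived))  # ascending, stable
            ranks = np.empty(m, dtype=int)
            ranks[order] = np.arange(1, m + 1)
            for subj, r in zip(subjects, ranks):
                rows.append((trial, subj, juror, int(r)))
    per_juror = pd.DataFrame(rows, columns=["trial", "subject", "juror", "rank"])
    average = (
        per_juror.groupby(["trial", "subject"], as_index=False)["rank"]
        .mean()
        .rename(columns={"rank": "average_rank"})
    )
    return JuryResult(per_juror=per_juror, average=average)
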