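"""Grid-cell symbolisation of trajectories.

The workspace is tessellated into square cells (1 x 1 cm by default) and a
trajectory becomes a string over {l, r, u, d}: one letter per cell-boundary
crossing, in traversal order.  Samples that stay in the same cell emit
nothing.  Segments that cross several boundaries between two samples are
subdivided at the exact line-grid intersections (rasterised), so diagonal
moves decompose into an x- and a y-crossing ordered by where the segment
meets each boundary; exact corner hits emit the x-crossing first.

Cells are half-open, [k c, (k+1) c) on both axes, with points on the
top/right workspace edge assigned to the last cell.
"""

from __future__ import annotations

import logging

import numpy as np

from .pmp_model import PMPModel, sample_trajectories
from .trajectory_core import Trajectory, Workspace

__all__ = ["symbolize", "build_corpus", "ALPHABET", "ProgressError"]

logger = logging.getLogger(__name__)

ALPHABET = "lrud"

#: cap on sampled trajectories before build_corpus reports no progress
MAX_CORPUS_TRAJECTORIES = 10_000


class ProgressError(RuntimeError):
    """Corpus construction failed to accumulate transitions."""


def _cell_index(v: float, cell: float, n_cells: int) -> int:
    idx = int(np.floor(v / cell))
    return min(max(idx, 0), n_cells - 1)


def symbolize(traj: Trajectory, ws: Workspace | None = None) -> str:
    """Convert a trajectory into its cell-transition symbol string."""
    ws = ws or Workspace()
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    xs = np.asarray(traj.xs, dtype=float)
    ys = np.asarray(traj.ys, dtype=float)
    if (
        xs.min() < 0 or xs.max() > ws.width or ys.min() < 0 or ys.max() > ws.height
    ):
        logger.warning("trajectory leaves the workspace; clipping to boundary")
        xs = np.clip(xs, 0.0, ws.width)
        ys = np.clip(ys, 0.0, ws.height)
    c = ws.cell_size
    out: list[str] = []
    cx = _cell_index(xs[0], c, ws.n_cols)
    cy = _cell_index(ys[0], c, ws.n_rows)
    for i in range(len(xs) - 1):
        x0, y0, x1, y1 = xs[i], ys[i], xs[i + 1], ys[i + 1]
        nx = _cell_index(x1, c, ws.n_cols)
        ny = _cell_index(y1, c, ws.n_rows)
        dx, dy = x1 - x0, y1 - y0
        events: list[tuple[float, int, str]] = []
        if nx != cx:
            step = 1 if nx > cx else -1
            sym = "r" if step > 0 else "l"
            for k in range(cx, nx, step):
                boundary = (k + 1) * c if step > 0 else k * c
                t = (boundary - x0) / dx if dx != 0 else 0.0
                events.append((t, 0, sym))
        if ny != cy:
            step = 1 if ny > cy else -1
            sym = "u" if step > 0 else "d"
            for k in range(cy, ny, step):
                boundary = (k + 1) * c if step > 0 else k * c
                t = (boundary - y0) / dy if dy != 0 else 0.0
                events.append((t, 1, sym))
        # traversal order; exact ties put the x-crossing first (axis key)
        events.sort(key=lambda e: (e[0], e[1]))
        out.extend(sym for _, _, sym in events)
        cx, cy = nx, ny
    return "".join(out)


def build_corpus(
    model: PMPModel,
    ws: Workspace | None = None,
    min_transitions: int = 10_000,
    seed: int | None = None,
    T: int = 150,
    batch: int = 20,
) -> str:
    """Concatenate symbolised samples from a fitted model.

    Trajectories are drawn from the model's predictive distribution,
    clipped to the workspace, symbolised and concatenated until at least
    ``min_transitions`` symbols have accumulated.  Deterministic for a
    fixed seed.
    """
    ws = ws or Workspace()
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    total = 0
    drawn = 0
    while total < min_transitions:
        if drawn >= MAX_CORPUS_TRAJECTORIES:
            raise ProgressError(
                f"{drawn} sampled trajectories yielded only {total} transitions "
                f"(< {min_transitions}); the model may be degenerate"
            )
        for traj in sample_trajectories(model, batch, T, seed=rng):
            s = symbolize(traj, ws)
            parts.append(s)
            total += len(s)
        drawn += batch
    return "".join(parts)
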