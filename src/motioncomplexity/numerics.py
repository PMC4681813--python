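"""Shared dense-Gaussian numerics: Cholesky with jitter escalation."""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["NumericalError", "robust_cholesky", "half_logdet", "LOG_2PI", "LOG_2PIE"]

LOG_2PI = float(np.log(2.0 * np.pi))
LOG_2PIE = float(np.log(2.0 * np.pi * np.e))

#: jitter ladder tried before giving up on a Cholesky factorization
JITTERS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


class NumericalError(RuntimeError):
    """A linear-algebra step failed beyond the documented jitter escalation."""


def robust_cholesky(mat: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a symmetric PSD matrix.

    Escalates a diagonal jitter from 1e-10 up to 1e-6 (scaled by the mean
    diagonal) before raising :class:`NumericalError`.
    """
    mat = np.asarray(mat, dtype=float)
    scale = max(float(np.mean(np.diag(mat))), 1.0)
    for jitter in JITTERS:
        try:
            return linalg.cholesky(mat + jitter * scale * np.eye(len(mat)), lower=True)
        except linalg.LinAlgError:
            continue
    raise NumericalError(
        f"Cholesky failed for {mat.shape} matrix even with jitter {JITTERS[-1]:g} "
        f"(diag range [{np.min(np.diag(mat)):.3g}, {np.max(np.diag(mat)):.3g}])"
    )


def half_logdet(chol_lower: np.ndarray) -> float:
    """(1/2) log det of the matrix whose lower Cholesky factor is given."""
    return float(np.sum(np.log(np.diag(chol_lower))))
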