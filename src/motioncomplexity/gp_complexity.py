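"""Gaussian-process model of a motion pattern and its entropic complexity.

Each spatial dimension of a pattern is modelled as a zero-mean GP over the
time index with a squared-exponential covariance

    k(t, t') = sigma_f^2 * exp(-|t - t'|^2 / lambda^2)

observed under i.i.d. Gaussian noise sigma_n^2.  The log marginal likelihood
of the concatenated repetitions splits into a data-dependent goodness-of-fit
term and a data-independent model-complexity term.  The complexity *score*
reported per pattern is the differential entropy of the model's marginal
observation distribution evaluated at the fitted length scale under a fixed
reference noise level, (1/2) log det(2 pi e (K_lambda + s_ref^2 I)), summed
over x and y.  Holding the noise at a common reference makes the score a
function of the length scale alone -- the model property that carries the
pattern's complexity -- rather than of the pattern's repetition variability,
and the entropy is monotonically decreasing in lambda.

The length scale and noise variance are fitted per dimension by maximising
the marginal likelihood (grid search plus Nelder-Mead refinement) after the
concatenated observations are standardised, which fixes sigma_f^2 = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, linalg

from .numerics import LOG_2PI, LOG_2PIE, half_logdet, robust_cholesky
from .trajectory_core import MotionPattern

__all__ = [
    "GPConfig",
    "GPFitResult",
    "se_kernel_matrix",
    "gp_log_marginal",
    "gp_entropy",
    "fit_gp_dimension",
    "fit_gp_pattern",
]

logger = logging.getLogger(__name__)

#: lambda grid used for the coarse search, in time-index units
LAMBDA_GRID = np.geomspace(0.5, 500.0, 30)
#: noise-variance grid (observations are standardised to unit variance)
NOISE_GRID = np.geomspace(1e-4, 1.0, 10)
#: reference noise variance at which the entropy score is evaluated, so the
#: score is a function of the fitted length scale alone
SCORE_NOISE_VARIANCE = 1e-2


@dataclass(frozen=True)
class GPConfig:
    """Squared-exponential GP hyperparameters (zero mean)."""

    signal_variance: float = 1.0
    noise_variance: float = 1e-2
    length_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.signal_variance <= 0 or self.noise_variance <= 0 or self.length_scale <= 0:
            raise ValueError("GP hyperparameters must be positive")


@dataclass(frozen=True)
class GPFitResult:
    """Per-dimension fits and the summed entropic complexity of a pattern."""

    lambda_x: float
    lambda_y: float
    sigma_n2_x: float
    sigma_n2_y: float
    log_marginal_x: float
    log_marginal_y: float
    goodness_of_fit_x: float
    goodness_of_fit_y: float
    model_complexity_x: float
    model_complexity_y: float
    entropy_x: float
    entropy_y: float
    boundary_flag: bool = False

    @property
    def log_marginal(self) -> float:
        return self.log_marginal_x + self.log_marginal_y

    @property
    def complexity(self) -> float:
        """Total entropic complexity: entropy_x + entropy_y."""
        return self.entropy_x + self.entropy_y


def se_kernel_matrix(t: np.ndarray, length_scale: float, signal_variance: float = 1.0) -> np.ndarray:
    """Squared-exponential kernel matrix K[i,j] = s_f^2 exp(-|ti-tj|^2/lambda^2)."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    if signal_variance <= 0:
        raise ValueError("signal_variance must be positive")
    t = np.asarray(t, dtype=float).ravel()
    sq = (t[:, None] - t[None, :]) ** 2
    return signal_variance * np.exp(-sq / length_scale**2)


def gp_log_marginal(
    y: np.ndarray,
    t: np.ndarray,
    length_scale: float,
    signal_variance: float = 1.0,
    noise_variance: float = 1e-2,
) -> tuple[float, float, float]:
    """Log marginal likelihood of observations under the zero-mean GP.

    Returns ``(log_marginal, goodness_of_fit, model_complexity)`` with

        goodness_of_fit  = -1/2 y^T (K + s_n^2 I)^-1 y
        model_complexity = -1/2 log det(K + s_n^2 I) - (M/2) log(2 pi)

    so that their sum is the multivariate-normal log density at ``y``
    (the standard marginal-likelihood decomposition).
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observations")
    if len(y) != len(np.asarray(t).ravel()):
        raise ValueError("y and t must have equal length")
    cov = se_kernel_matrix(t, length_scale, signal_variance)
    cov[np.diag_indices_from(cov)] += noise_variance
    chol = robust_cholesky(cov)
    alpha = linalg.cho_solve((chol, True), y)
    gof = -0.5 * float(y @ alpha)
    m = len(y)
    model_complexity = -half_logdet(chol) - 0.5 * m * LOG_2PI
    return gof + model_complexity, gof, model_complexity


def gp_entropy(
    t: np.ndarray, length_scale: float, signal_variance: float = 1.0, noise_variance: float = 1e-2
) -> float:
    """Differential entropy (nats) of N(0, K + sigma_n^2 I) at the time points."""
    cov = se_kernel_matrix(t, length_scale, signal_variance)
    cov[np.diag_indices_from(cov)] += noise_variance
    chol = robust_cholesky(cov)
    return half_logdet(chol) + 0.5 * len(cov) * LOG_2PIE


def _block_log_marginal(reps: np.ndarray, t: np.ndarray, lam: float, s_n2: float) -> float:
    """Sum of per-repetition log marginals with shared hyperparameters."""
    cov = se_kernel_matrix(t, lam, 1.0)
    cov[np.diag_indices_from(cov)] += s_n2
    try:
        chol = robust_cholesky(cov)
    except Exception:
        return -np.inf
    alpha = linalg.cho_solve((chol, True), reps.T)  # (T, N)
    gof = -0.5 * float(np.sum(reps.T * alpha))
    n, T = reps.shape
    return gof + n * (-half_logdet(chol) - 0.5 * T * LOG_2PI)


def fit_gp_dimension(
    reps: np.ndarray,
    concat: str = "block",
) -> dict:
    """Fit (lambda, sigma_n^2) for one spatial dimension of a pattern.

    Parameters
    ----------
    reps
        (N, T) array, one row per repetition, already resampled.
    concat
        ``"block"`` treats repetitions as independent realisations sharing
        hyperparameters (block-diagonal covariance); ``"continuous"``
        concatenates them on one running time index 1..N*T.

    The concatenated observations are centred and scaled to unit variance
    (fixing sigma_f^2 = 1) before the marginal likelihood is maximised by a
    log-spaced grid search followed by Nelder-Mead refinement.
    """
    reps = np.asarray(reps, dtype=float)
    if reps.ndim != 2:
        raise ValueError("reps must be (N, T)")
    n, T = reps.shape
    flat = reps.ravel()
    scale = flat.std()
    if scale < 1e-12:
        scale = 1.0
    z = (reps - flat.mean()) / scale

    if concat == "block":
        t = np.arange(1, T + 1, dtype=float)

        def nll(params: np.ndarray) -> float:
            lam, s_n2 = np.exp(params)
            return -_block_log_marginal(z, t, lam, s_n2)

    elif concat == "continuous":
        t = np.arange(1, n * T + 1, dtype=float)
        zc = z.ravel()

        def nll(params: np.ndarray) -> float:
            lam, s_n2 = np.exp(params)
            try:
                lm, _, _ = gp_log_marginal(zc, t, lam, 1.0, s_n2)
            except Exception:
                return np.inf
            return -lm

    else:
        raise ValueError(f"unknown concat mode {concat!r}")

    # coarse grid; ties broken toward the smallest length scale
    best = (np.inf, None)
    for lam in LAMBDA_GRID:
        for s_n2 in NOISE_GRID:
            val = nll(np.log([lam, s_n2]))
            if val < best[0] - 1e-12:
                best = (val, (lam, s_n2))
    lam0, s_n20 = best[1]
    boundary = bool(
        np.isclose(lam0, LAMBDA_GRID[0])
        or np.isclose(lam0, LAMBDA_GRID[-1])
        or np.isclose(s_n20, NOISE_GRID[0])
        or np.isclose(s_n20, NOISE_GRID[-1])
    )
    if boundary:
        logger.warning(
            "GP grid optimum on boundary (lambda=%.3g, sigma_n^2=%.3g)", lam0, s_n20
        )

    res = optimize.minimize(
        nll, np.log([lam0, s_n20]), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
    )
    lam, s_n2 = np.exp(res.x)
    lam = float(np.clip(lam, 1e-3, 1e5))
    s_n2 = float(np.clip(s_n2, 1e-12, 1e3))

    if concat == "block":
        cov_t = np.arange(1, T + 1, dtype=float)
        block_cov = se_kernel_matrix(cov_t, lam, 1.0)
        block_cov[np.diag_indices_from(block_cov)] += s_n2
        chol = robust_cholesky(block_cov)
        # decomposition on the full block-diagonal covariance (N blocks)
        alpha = linalg.cho_solve((chol, True), z.T)
        gof = -0.5 * float(np.sum(z.T * alpha))
        model_complexity = n * (-half_logdet(chol)) - 0.5 * n * T * LOG_2PI
        lm = gof + model_complexity
        # score: entropy at the fitted length scale under the shared
        # reference noise level, so it depends on lambda alone
        entropy = n * gp_entropy(cov_t, lam, 1.0, SCORE_NOISE_VARIANCE)
    else:
        tt = np.arange(1, n * T + 1, dtype=float)
        lm, gof, model_complexity = gp_log_marginal(z.ravel(), tt, lam, 1.0, s_n2)
        entropy = gp_entropy(tt, lam, 1.0, SCORE_NOISE_VARIANCE)

    return {
        "length_scale": lam,
        "noise_variance": s_n2,
        "log_marginal": float(lm),
        "goodness_of_fit": float(gof),
        "model_complexity": float(model_complexity),
        "entropy": float(entropy),
        "boundary": boundary,
    }


def fit_gp_pattern(pattern: MotionPattern, concat: str = "block") -> GPFitResult:
    """Fit both spatial dimensions of a pattern and sum their entropies."""
    T = pattern.common_length()
    xs = np.stack([r.xs for r in pattern.repetitions])
    ys = np.stack([r.ys for r in pattern.repetitions])
    fx = fit_gp_dimension(xs, concat=concat)
    fy = fit_gp_dimension(ys, concat=concat)
    return GPFitResult(
        lambda_x=fx["length_scale"],
        lambda_y=fy["length_scale"],
        sigma_n2_x=fx["noise_variance"],
        sigma_n2_y=fy["noise_variance"],
        log_marginal_x=fx["log_marginal"],
        log_marginal_y=fy["log_marginal"],
        goodness_of_fit_x=fx["goodness_of_fit"],
        goodness_of_fit_y=fy["goodness_of_fit"],
        model_complexity_x=fx["model_complexity"],
        model_complexity_y=fy["model_complexity"],
        entropy_x=fx["entropy"],
        entropy_y=fy["entropy"],
        boundary_flag=fx["boundary"] or fy["boundary"],
    )
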