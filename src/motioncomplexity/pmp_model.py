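"""Probabilistic movement primitives for repeated 2-D trajectories.

A trajectory tau = [x_1..x_T, y_1..y_T] is compressed onto normalised
Gaussian basis functions of a linear phase z in [0, 1]:

    b_i(z) = exp(-(z - c_i)^2 / (2 h^2)),   phi_i(z) = b_i(z) / sum_j b_j(z)

with per-dimension weight vectors stacked as omega = [omega_x; omega_y]
(n = 20 bases per dimension by default, so omega in R^40).  The repetitions
of one pattern induce a Gaussian over omega whose mean and covariance are
inferred with a conjugate Normal-inverse-Wishart prior; the MAP estimate
(mu, Psi/nu) defines the predictive trajectory distribution

    p(tau) = N(Psi_blk mu_omega, Psi_blk Sigma_omega Psi_blk^T + Sigma_tau)

whose differential entropy is the pattern's PMP complexity.  Sigma_tau is a
tiny isotropic observation noise (1e-10 I) so the predictive covariance is
full rank; the entropy is computed with the matrix-determinant lemma so only
a 2n x 2n determinant is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .numerics import LOG_2PIE, NumericalError, half_logdet, robust_cholesky
from .trajectory_core import MotionPattern, Trajectory

__all__ = [
    "BasisConfig",
    "PMPModel",
    "NIWState",
    "basis_matrix",
    "fit_weights",
    "empirical_prior",
    "niw_posterior",
    "map_estimate",
    "pmp_complexity",
    "sample_trajectories",
    "fit_pmp_pattern",
    "fit_pmp_patterns",
]

DEFAULT_SIGMA_TAU = 1e-10
DEFAULT_KAPPA0 = 0.1
DEFAULT_NU0 = 10.0
RIDGE = 1e-10


@dataclass(frozen=True)
class BasisConfig:
    """Normalised Gaussian bases on a linear phase map z(t): [1,T] -> [0,1]."""

    n: int = 20
    h: float | None = None  # default 1/(n-1): adjacent-basis overlap exp(-1/2)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 basis functions")
        h = self.h if self.h is not None else 1.0 / (self.n - 1)
        if h <= 0:
            raise ValueError("basis width h must be positive")
        object.__setattr__(self, "h", float(h))

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n)


@dataclass(frozen=True)
class PMPModel:
    """Gaussian over basis weights plus trajectory observation noise."""

    basis: BasisConfig
    mu_w: np.ndarray          # (2n,)
    sigma_w: np.ndarray       # (2n, 2n), symmetric PD
    sigma_tau: float = DEFAULT_SIGMA_TAU

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_w, dtype=float)
        cov = np.asarray(self.sigma_w, dtype=float)
        if mu.shape != (2 * self.basis.n,):
            raise ValueError("mu_w must have length 2n")
        if cov.shape != (2 * self.basis.n, 2 * self.basis.n):
            raise ValueError("sigma_w must be 2n x 2n")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("sigma_w must be symmetric")
        object.__setattr__(self, "mu_w", mu)
        object.__setattr__(self, "sigma_w", 0.5 * (cov + cov.T))


@dataclass(frozen=True)
class NIWState:
    """Normal-inverse-Wishart parameters over (mean, covariance) of omega."""

    mu: np.ndarray
    kappa: float
    nu: float
    psi: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        d = len(mu)
        if psi.shape != (d, d):
            raise ValueError("psi must be d x d")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        # nu_0 = 10 with d = 40 is the canonical setting: the prior is then
        # improper as a distribution, but the MAP formulas only need nu > 0
        # and a positive-definite scale matrix.
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "psi", 0.5 * (psi + psi.T))


def basis_matrix(T: int, basis: BasisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix Phi (T x n) and block-diagonal Psi_blk (2T x 2n).

    Each row of Phi sums to one (normalised bases), so constants are
    reproduced exactly by the feature expansion.
    """
    z = np.linspace(0.0, 1.0, T)
    c = basis.centers
    b = np.exp(-((z[:, None] - c[None, :]) ** 2) / (2.0 * basis.h**2))
    phi = b / b.sum(axis=1, keepdims=True)
    psi_blk = np.zeros((2 * T, 2 * basis.n))
    psi_blk[:T, : basis.n] = phi
    psi_blk[T:, basis.n :] = phi
    return phi, psi_blk


def fit_weights(traj: Trajectory, basis: BasisConfig) -> np.ndarray:
    """Ridge least-squares weights for one trajectory (length 2n).

    The two dimensions decouple because the feature matrix is block
    diagonal; a tiny ridge (1e-10) guards against rank deficiency.
    """
    T = len(traj)
    phi, _ = basis_matrix(T, basis)
    gram = phi.T @ phi + RIDGE * np.eye(basis.n)
    chol = robust_cholesky(gram)
    wx = linalg.cho_solve((chol, True), phi.T @ traj.xs)
    wy = linalg.cho_solve((chol, True), phi.T @ traj.ys)
    return np.concatenate([wx, wy])


def empirical_prior(
    weights: Sequence[np.ndarray],
    kappa0: float = DEFAULT_KAPPA0,
    nu0: float = DEFAULT_NU0,
) -> NIWState:
    """Empirical-Bayes NIW prior pooled over all patterns' weight vectors.

    mu_0 and Psi_0 are the maximum-likelihood mean and covariance of the
    pooled weight vectors.  A small ridge keeps Psi_0 positive definite
    when fewer vectors than dimensions are pooled.
    """
    W = np.asarray(list(weights), dtype=float)
    if W.ndim != 2 or len(W) < 1:
        raise ValueError("need at least one weight vector")
    d = W.shape[1]
    mu0 = W.mean(axis=0)
    cov = np.cov(W.T, bias=True) if len(W) > 1 else np.zeros((d, d))
    cov = np.atleast_2d(cov)
    ridge = max(np.trace(cov) / d, 1.0) * 1e-8
    psi0 = cov + ridge * np.eye(d)
    return NIWState(mu=mu0, kappa=kappa0, nu=nu0, psi=psi0)


def niw_posterior(weights: Sequence[np.ndarray], prior: NIWState) -> NIWState:
    """Conjugate NIW update from a pattern's fitted weight vectors.

    mu    = (kappa_0 mu_0 + N xbar) / (kappa_0 + N)
    kappa = kappa_0 + N
    nu    = nu_0 + N
    Psi   = Psi_0 + S + kappa_0 N / (kappa_0 + N) (xbar - mu_0)(xbar - mu_0)^T

    with S the scatter of centred weights around their sample mean xbar.
    """
    W = np.asarray(list(weights), dtype=float)
    if W.size == 0:
        return prior
    if W.ndim != 2 or W.shape[1] != len(prior.mu):
        raise ValueError("weight vectors must match the prior dimension")
    n = len(W)
    xbar = W.mean(axis=0)
    centered = W - xbar
    scatter = centered.T @ centered
    diff = xbar - prior.mu
    mu = (prior.kappa * prior.mu + n * xbar) / (prior.kappa + n)
    psi = prior.psi + scatter + (prior.kappa * n / (prior.kappa + n)) * np.outer(diff, diff)
    return NIWState(mu=mu, kappa=prior.kappa + n, nu=prior.nu + n, psi=psi)


def map_estimate(state: NIWState) -> tuple[np.ndarray, np.ndarray]:
    """MAP (mu_omega, Sigma_omega) = (mu, Psi / nu) of the NIW posterior."""
    sigma = state.psi / state.nu
    try:
        robust_cholesky(sigma)
    except NumericalError as err:
        raise NumericalError("MAP covariance is not positive definite") from err
    return state.mu.copy(), 0.5 * (sigma + sigma.T)


def pmp_complexity(model: PMPModel, T: int) -> float:
    """Differential entropy (nats) of the predictive trajectory distribution.

    Uses the matrix-determinant lemma with Sigma_tau = s I:

        log det(Psi_blk Sigma_w Psi_blk^T + s I)
          = 2T log s + log det(I_2n + L^T Psi_blk^T Psi_blk L / s)

    where L is the Cholesky factor of Sigma_w.
    """
    _, psi_blk = basis_matrix(T, model.basis)
    s = model.sigma_tau
    L = robust_cholesky(model.sigma_w)
    inner = psi_blk @ L
    small = np.eye(2 * model.basis.n) + inner.T @ inner / s
    logdet = 2 * T * np.log(s) + 2.0 * half_logdet(robust_cholesky(small))
    return float(0.5 * logdet + 0.5 * (2 * T) * LOG_2PIE)


def sample_trajectories(
    model: PMPModel, m: int, T: int, seed: int | np.random.Generator | None = None
) -> list[Trajectory]:
    """Draw m trajectories tau = Psi_blk omega + eps from the predictive."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _, psi_blk = basis_matrix(T, model.basis)
    L = robust_cholesky(model.sigma_w)
    d = 2 * model.basis.n
    omegas = model.mu_w[None, :] + rng.standard_normal((m, d)) @ L.T
    taus = omegas @ psi_blk.T
    taus += np.sqrt(model.sigma_tau) * rng.standard_normal(taus.shape)
    times = np.arange(1, T + 1, dtype=float)
    return [Trajectory(times, tau[:T], tau[T:]) for tau in taus]


def fit_pmp_pattern(
    pattern: MotionPattern,
    basis: BasisConfig | None = None,
    prior: NIWState | None = None,
    kappa0: float = DEFAULT_KAPPA0,
    nu0: float = DEFAULT_NU0,
    sigma_tau: float = DEFAULT_SIGMA_TAU,
) -> PMPModel:
    """Fit one pattern: weights per repetition, NIW update, MAP model.

    When no prior is supplied an empirical prior is built from this
    pattern's own weights; for a shared prior across a collection use
    :func:`fit_pmp_patterns`.
    """
    basis = basis or BasisConfig()
    weights = [fit_weights(r, basis) for r in pattern.repetitions]
    if prior is None:
        prior = empirical_prior(weights, kappa0=kappa0, nu0=nu0)
    post = niw_posterior(weights, prior)
    mu_w, sigma_w = map_estimate(post)
    return PMPModel(basis=basis, mu_w=mu_w, sigma_w=sigma_w, sigma_tau=sigma_tau)


def fit_pmp_patterns(
    patterns: Sequence[MotionPattern],
    basis: BasisConfig | None = None,
    kappa0: float = DEFAULT_KAPPA0,
    nu0: float = DEFAULT_NU0,
    sigma_tau: float = DEFAULT_SIGMA_TAU,
) -> list[PMPModel]:
    """Fit a collection with an empirical-Bayes prior pooled over all data."""
    basis = basis or BasisConfig()
    all_weights = [[fit_weights(r, basis) for r in p.repetitions] for p in patterns]
    pooled = [w for ws in all_weights for w in ws]
    prior = empirical_prior(pooled, kappa0=kappa0, nu0=nu0)
    models = []
    for ws in all_weights:
        post = niw_posterior(ws, prior)
        mu_w, sigma_w = map_estimate(post)
        models.append(PMPModel(basis=basis, mu_w=mu_w, sigma_w=sigma_w, sigma_tau=sigma_tau))
    return models
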