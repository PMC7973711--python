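"""Model families for affect dynamics: VAR(1), Ornstein-Uhlenbeck, stationary Gaussian.

A stable multivariate OU process observed on an equally spaced grid is
exactly a stable VAR(1) process; on unequally spaced grids the OU
conditional mean and covariance depend on the actual elapsed time while
the VAR(1) prediction does not.  This module implements the three
families, their conditional (one-step predictive) and stationary
distributions, the OU->VAR(1) mapping, and the Gaussian negative
log-likelihood used throughout the package.

Conventions
-----------
* Time is measured in hours; a drift matrix ``theta`` therefore has
  units of 1/hour.
* Every covariance returned is symmetrized as ``(S + S.T) / 2``:
  floating-point asymmetry would otherwise break Cholesky factorizations
  downstream.
* The diffusion matrix ``sigma`` is kept lower triangular with a
  non-negative diagonal, which fixes the reflection invariance of
  ``sigma @ sigma.T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import (
    expm,
    solve_continuous_lyapunov,
    solve_discrete_lyapunov,
)

__all__ = [
    "VarParams",
    "OuParams",
    "StationaryParams",
    "GaussianPrediction",
    "ou_conditional",
    "ou_stationary",
    "var_conditional",
    "var_stationary",
    "ou_to_var",
    "gaussian_nll",
    "JITTER_SCALE",
]

# Relative ridge added to a conditional covariance before inversion; the
# dt -> 0 conditional covariance is singular and needs this to be scorable.
JITTER_SCALE = 1e-10


def _sym(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


class UnstableModelError(ValueError):
    """Raised when parameters describe a non-stationary (unstable) process."""


@dataclass
class VarParams:
    """Lag-1 vector autoregression ``x_i = c + A x_{i-1} + eps_i``.

    Attributes
    ----------
    intercept : (d,) array
        Intercept vector ``c``.
    transition : (d, d) array
        Transition matrix ``A``; diagonal entries are autoregressive
        effects, off-diagonal entries cross-lagged effects.
    innovation_cov : (d, d) array
        Covariance of the Gaussian innovations ``eps_i``.
    """

    intercept: np.ndarray
    transition: np.ndarray
    innovation_cov: np.ndarray

    def __post_init__(self) -> None:
        self.intercept = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.innovation_cov = _sym(
            np.atleast_2d(np.asarray(self.innovation_cov, dtype=float))
        )

    @property
    def d(self) -> int:
        return self.intercept.shape[0]

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(np.linalg.eigvals(self.transition)) < 1.0))

    def to_dict(self) -> dict:
        return {
            "family": "var",
            "d": self.d,
            "intercept": self.intercept.tolist(),
            "transition": self.transition.tolist(),
            "innovation_cov": self.innovation_cov.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "VarParams":
        return cls(
            np.array(obj["intercept"]),
            np.array(obj["transition"]),
            np.array(obj["innovation_cov"]),
        )


@dataclass
class OuParams:
    """Multivariate Ornstein-Uhlenbeck process ``dy = theta (mu - y) dt + sigma dW``.

    Attributes
    ----------
    mu : (d,) array
        Center of the process; equals the stationary mean when stable.
    theta : (d, d) array
        Drift matrix (1/hour).  The process is stable iff the real parts
        of its eigenvalues are all strictly positive.
    sigma : (d, d) array
        Lower-triangular diffusion matrix with non-negative diagonal;
        the Wiener increments have covariance ``sigma @ sigma.T``.
    """

    mu: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    @property
    def stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.theta).real > 0.0))

    @property
    def diffusion_cov(self) -> np.ndarray:
        return self.sigma @ self.sigma.T

    def to_dict(self) -> dict:
        return {
            "family": "ou",
            "d": self.d,
            "mu": self.mu.tolist(),
            "theta": self.theta.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "OuParams":
        return cls(np.array(obj["mu"]), np.array(obj["theta"]), np.array(obj["sigma"]))


@dataclass
class StationaryParams:
    """Time-invariant Gaussian ``N(mu, cov)`` for series without usable dynamics."""

    mu: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.cov = _sym(np.atleast_2d(np.asarray(self.cov, dtype=float)))

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    def to_dict(self) -> dict:
        return {
            "family": "stationary",
            "d": self.d,
            "mu": self.mu.tolist(),
            "cov": self.cov.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "StationaryParams":
        return cls(np.array(obj["mu"]), np.array(obj["cov"]))


@dataclass
class GaussianPrediction:
    """A Gaussian predictive distribution (mean, cov) for one observation."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = _sym(np.atleast_2d(np.asarray(self.cov, dtype=float)))


def _require_stable_ou(p: OuParams) -> None:
    if not p.stable:
        raise UnstableModelError(
            "unstable OU process: eigenvalues of theta must have positive real parts"
        )


def _require_stable_var(p: VarParams) -> None:
    if not p.stable:
        raise UnstableModelError(
            "unstable VAR(1) process: eigenvalues of A must lie inside the unit circle"
        )


def ou_conditional(p: OuParams, y_prev: np.ndarray, dt: float) -> GaussianPrediction:
    """Conditional distribution of ``y(t + dt)`` given ``y(t) = y_prev``.

    mean = (I - e^{-theta dt}) mu + e^{-theta dt} y_prev
    cov  = Sigma_y - e^{-theta dt} Sigma_y e^{-theta^T dt}

    where ``Sigma_y`` is the stationary covariance.  ``dt`` is in hours.
    """
    _require_stable_ou(p)
    if dt < 0:
        raise ValueError("dt must be non-negative")
    y_prev = np.asarray(y_prev, dtype=float)
    a = expm(-p.theta * dt)
    sig_y = ou_stationary(p).cov
    mean = (np.eye(p.d) - a) @ p.mu + a @ y_prev
    cov = sig_y - a @ sig_y @ a.T
    return GaussianPrediction(mean, cov)


def ou_stationary(p: OuParams) -> StationaryParams:
    """Stationary distribution ``N(mu, Sigma_y)`` of a stable OU process.

    ``Sigma_y`` solves the continuous Lyapunov equation
    ``theta Sigma_y + Sigma_y theta^T = sigma sigma^T``.
    """
    _require_stable_ou(p)
    sig_y = solve_continuous_lyapunov(p.theta, p.diffusion_cov)
    return StationaryParams(p.mu, sig_y)


def var_conditional(
    p: VarParams, x_prev: np.ndarray, steps: int = 1
) -> GaussianPrediction:
    """Distribution of ``x_{i+steps}`` given ``x_i = x_prev``.

    Compounds the one-step recursion ``steps`` times:
    mean = A^s x_prev + (sum_{k<s} A^k) c,  cov = sum_{k<s} A^k Sig_eps A^k^T.
    ``steps > 1`` encodes missing beeps bridged by a longer pseudo-interval.
    """
    _require_stable_var(p)
    steps = int(steps)
    if steps < 1:
        raise ValueError("steps must be a positive integer")
    x_prev = np.asarray(x_prev, dtype=float)
    mean = x_prev.copy()
    cov = np.zeros((p.d, p.d))
    for _ in range(steps):
        mean = p.intercept + p.transition @ mean
        cov = p.transition @ cov @ p.transition.T + p.innovation_cov
    return GaussianPrediction(mean, cov)


def var_stationary(p: VarParams) -> StationaryParams:
    """Stationary distribution of a stable VAR(1): ``mu = (I-A)^-1 c``,
    ``Sigma = A Sigma A^T + Sigma_eps`` (discrete Lyapunov equation)."""
    _require_stable_var(p)
    mu = np.linalg.solve(np.eye(p.d) - p.transition, p.intercept)
    cov = solve_discrete_lyapunov(p.transition, p.innovation_cov)
    return StationaryParams(mu, cov)


def ou_to_var(p: OuParams, dt: float) -> VarParams:
    """Exact VAR(1) equivalent of an OU process observed every ``dt`` hours.

    A = e^{-theta dt},  c = (I - A) mu,  Sigma_eps = Sigma_y - A Sigma_y A^T.
    """
    _require_stable_ou(p)
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = expm(-p.theta * dt)
    sig_y = ou_stationary(p).cov
    c = (np.eye(p.d) - a) @ p.mu
    sig_eps = sig_y - a @ sig_y @ a.T
    return VarParams(c, a, sig_eps)


def gaussian_nll(x: np.ndarray, pred: GaussianPrediction) -> float:
    """Negative log density of ``x`` under ``N(pred.mean, pred.cov)``.

    A relative ridge ``JITTER_SCALE * mean(diag(cov))`` is added before
    factorization so that nearly singular conditional covariances (dt -> 0)
    remain scorable; an exactly singular covariance still raises.
    """
    x = np.asarray(x, dtype=float)
    d = pred.mean.shape[0]
    try:
        chol = np.linalg.cholesky(pred.cov)
    except np.linalg.LinAlgError:
        # nearly singular (e.g. dt -> 0 conditional covariance): retry ridged
        cov = pred.cov + JITTER_SCALE * np.mean(np.diag(pred.cov)) * np.eye(d)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular predictive covariance; cannot evaluate density"
            ) from exc
    resid = x - pred.mean
    z = np.linalg.solve(chol, resid)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(0.5 * (d * np.log(2.0 * np.pi) + log_det + z @ z))


def stationary_nll(x: np.ndarray, p: StationaryParams) -> float:
    """Negative log density of ``x`` under the stationary Gaussian ``p``."""
    return gaussian_nll(x, GaussianPrediction(p.mu, p.cov))
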