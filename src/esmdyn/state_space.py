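"""Measurement-error variants of the OU and VAR(1) models.

Both dynamical families extend to a linear Gaussian state-space model:
the latent affect state follows the OU / VAR(1) dynamics, and each
observation adds independent Gaussian measurement error with a diagonal
covariance (one error variance per rating dimension).  The observation
likelihood is the marginal likelihood delivered by the linear Kalman
filter: the running sum of one-step predictive negative log densities.

Conventions mirror the error-free likelihood:

* the filter restarts from the stationary latent prior at the first
  scorable observation of each day (complete overnight relaxation);
* missing beeps inside a day are bridged by propagating without an
  update (OU: the actual elapsed hours; VAR: compounded unit steps);
* transitions flagged by the large-deviation filter do not contribute
  to the likelihood sum but their observations still update the filter,
  so the flagged end point keeps conditioning what follows.

The covariance update uses the Joseph form, which stays positive
semi-definite under roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .data_model import EsmSeries, TransitionPlan, TransitionItem
from .dynamics import (
    GaussianPrediction,
    OuParams,
    VarParams,
    gaussian_nll,
    ou_stationary,
    var_stationary,
)

__all__ = ["NoiseParams", "FilterState", "kalman_marginal_nll", "kalman_predict_next"]


@dataclass
class NoiseParams:
    """Per-dimension measurement-error variances (squared rating units)."""

    error_var: np.ndarray

    def __post_init__(self) -> None:
        self.error_var = np.atleast_1d(np.asarray(self.error_var, dtype=float))
        if np.any(self.error_var < 0):
            raise ValueError("measurement-error variances must be non-negative")

    @property
    def d(self) -> int:
        return self.error_var.shape[0]

    @property
    def cov(self) -> np.ndarray:
        return np.diag(self.error_var)

    def to_dict(self) -> dict:
        return {"error_var": self.error_var.tolist()}

    @classmethod
    def from_dict(cls, obj: dict) -> "NoiseParams":
        return cls(np.array(obj["error_var"]))


@dataclass
class FilterState:
    """Filtered latent mean and covariance after incorporating an observation."""

    mean: np.ndarray
    cov: np.ndarray


def _stationary(model):
    if isinstance(model, OuParams):
        return ou_stationary(model)
    if isinstance(model, VarParams):
        return var_stationary(model)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _transition_matrices(model, item: TransitionItem, sig_stat: np.ndarray):
    """Propagation matrix A and process covariance Q for one plan item."""
    if isinstance(model, OuParams):
        a = expm(-model.theta * item.dt_hours)
        q = sig_stat - a @ sig_stat @ a.T
        return a, q
    a = np.linalg.matrix_power(model.transition, item.steps)
    q = np.zeros_like(sig_stat)
    for _ in range(item.steps):
        q = model.transition @ q @ model.transition.T + model.innovation_cov
    return a, q


def _joseph_update(m_pred, p_pred, x, r):
    d = m_pred.shape[0]
    s = p_pred + r
    k = np.linalg.solve(s.T, p_pred.T).T  # P S^-1
    m = m_pred + k @ (x - m_pred)
    ik = np.eye(d) - k
    p = ik @ p_pred @ ik.T + k @ r @ k.T
    return m, (p + p.T) / 2.0


def _run_filter(model, noise, series, plan, score: bool):
    """Iterate the plan; return (total scored NLL, final FilterState, mu, Sigma_stat)."""
    stat = _stationary(model)
    mu, sig_stat = stat.mu, stat.cov
    r = noise.cov
    total = 0.0
    state: FilterState | None = None
    for item in plan.items:
        x = series.ratings[item.target]
        if item.kind == "stationary":
            m_pred, p_pred = mu, sig_stat
        else:
            if state is None:
                raise ValueError("transition item before any stationary item")
            a, q = _transition_matrices(model, item, sig_stat)
            m_pred = mu + a @ (state.mean - mu)
            p_pred = a @ state.cov @ a.T + q
            p_pred = (p_pred + p_pred.T) / 2.0
        if score and item.retained:
            total += gaussian_nll(x, GaussianPrediction(m_pred, p_pred + r))
        m, p = _joseph_update(m_pred, p_pred, x, r)
        if np.any(np.diag(p) < -1e-8):
            raise np.linalg.LinAlgError("filter covariance lost positive semi-definiteness")
        state = FilterState(m, p)
    return total, state, mu, sig_stat


def kalman_marginal_nll(
    model, noise: NoiseParams, series: EsmSeries, plan: TransitionPlan
) -> float:
    """Marginal negative log-likelihood of a series under latent dynamics + noise.

    With ``error_var = 0`` this equals the error-free series likelihood:
    the update then pins the latent state to the observation exactly.
    """
    total, _, _, _ = _run_filter(model, noise, series, plan, score=True)
    return total


def kalman_predict_next(
    model,
    noise: NoiseParams,
    series: EsmSeries,
    plan: TransitionPlan,
    *,
    opens_day: bool,
    dt_hours: float | None = None,
    steps: int | None = None,
) -> GaussianPrediction:
    """One-step-ahead predictive distribution for the observation after ``series``.

    The filter is run through the whole prefix (every observation updates
    it, retained or not).  If the next observation opens a new day the
    prediction is the stationary prior plus measurement noise; otherwise
    the latent state is propagated over ``dt_hours`` (OU) or ``steps``
    (VAR) and the noise covariance added.
    """
    _, state, mu, sig_stat = _run_filter(model, noise, series, plan, score=False)
    r = noise.cov
    if opens_day or state is None:
        return GaussianPrediction(mu, sig_stat + r)
    if isinstance(model, OuParams):
        if dt_hours is None:
            raise ValueError("dt_hours required for an OU prediction")
        item = TransitionItem(0, 0, dt_hours=float(dt_hours), steps=1)
    else:
        if steps is None:
            raise ValueError("steps required for a VAR prediction")
        item = TransitionItem(0, 0, dt_hours=0.0, steps=int(steps))
    a, q = _transition_matrices(model, item, sig_stat)
    m_pred = mu + a @ (state.mean - mu)
    p_pred = a @ state.cov @ a.T + q
    return GaussianPrediction(m_pred, p_pred + r)
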