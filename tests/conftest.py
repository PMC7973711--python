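"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import multivariate_normal

from esmdyn import EsmSeries, OuParams, ou_stationary


def random_stable_ou(rng: np.random.Generator, d: int = 2, scale: float = 1.0) -> OuParams:
    """Random OU parameter set with drift eigenvalues shifted into stability."""
    raw = rng.normal(size=(d, d)) * scale
    shift = max(0.0, -np.min(np.linalg.eigvals(raw).real)) + rng.uniform(0.2, 1.0)
    theta = raw + shift * np.eye(d)
    sigma = np.tril(rng.normal(size=(d, d)))
    np.fill_diagonal(sigma, rng.uniform(0.5, 2.0, size=d))
    mu = rng.normal(size=d) * 10.0
    return OuParams(mu, theta, sigma)


def make_series(timestamps, day_index, ratings, missing=None, series_id="t") -> EsmSeries:
    ratings = np.atleast_2d(np.asarray(ratings, dtype=float))
    if ratings.shape[0] != len(timestamps):
        ratings = ratings.T
    if missing is None:
        missing = ~np.isfinite(ratings)
    return EsmSeries(
        series_id,
        np.asarray(timestamps, dtype=float),
        np.asarray(day_index, dtype=int),
        np.where(np.asarray(missing, bool), np.nan, ratings),
        np.asarray(missing, dtype=bool),
        [f"v{j}" for j in range(ratings.shape[1])],
    )


def joint_gaussian_nll(ou: OuParams, series: EsmSeries, error_var=None) -> float:
    """Brute-force joint NLL of a fully observed series.

    Assembles the dense covariance of all observations from the
    stationary covariance and the cross-covariance blocks
    ``Cov(y(s), y(t)) = Sigma_y e^(-theta^T (t - s))`` for s < t, with
    days independent (overnight reset) and diagonal measurement error on
    the block diagonal.  Completely independent of the Kalman recursion.
    """
    d = ou.d
    stat = ou_stationary(ou)
    total = 0.0
    for day in np.unique(series.day_index):
        idx = np.flatnonzero(series.day_index == day)
        n = idx.size
        cov = np.zeros((n * d, n * d))
        mean = np.tile(stat.mu, n)
        x = series.ratings[idx].ravel()
        for i in range(n):
            for j in range(n):
                ti, tj = series.timestamps[idx[i]], series.timestamps[idx[j]]
                if i == j:
                    block = stat.cov.copy()
                    if error_var is not None:
                        block = block + np.diag(error_var)
                elif i < j:
                    block = stat.cov @ expm(-ou.theta.T * (tj - ti))
                else:
                    block = expm(-ou.theta * (ti - tj)) @ stat.cov
                cov[i * d : (i + 1) * d, j * d : (j + 1) * d] = block
        cov = (cov + cov.T) / 2.0
        total += -multivariate_normal(mean=mean, cov=cov).logpdf(x)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
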