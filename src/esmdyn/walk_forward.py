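"""Walk-forward out-of-sample cross-validation.

For every fold n = 1..10 the model is refitted to the first N - n beeps
of a series (beeps count missing occasions too) and the (N - n + 1)th
observation is scored under the fitted one-step predictive density:
the conditional density given the last scorable training observation
(actual elapsed hours for OU, pseudo-steps for VAR), the stationary
density when the test observation opens a new day, and the
Kalman-filter predictive density when measurement error is modelled.
The ten predicted min-log-likelihoods are averaged per series; folds
whose test observation is missing are dropped from the average.

The large-deviation filter, when active, is applied to each fold's
training portion only — speeds, the per-dimension SDs and the
median/MAD threshold are all recomputed from the training data, so no
test information leaks into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import EsmSeries, build_transition_plan
from .deviation_filter import filter_plan
from .dynamics import (
    GaussianPrediction,
    gaussian_nll,
    ou_conditional,
    ou_stationary,
    var_conditional,
    var_stationary,
)
from .estimation import DeConfig, fit_mle
from .state_space import kalman_predict_next

__all__ = ["CvRecord", "walk_forward_cv", "run_study_cv"]

_FAMILY_CODE = {"ou": 1, "var": 2, "stationary": 3}


@dataclass
class CvRecord:
    """Per-series walk-forward result for one family and cutoff."""

    series_id: str
    family: str
    cutoff: float  # math.inf when no filtering
    fold_nlls: np.ndarray  # length n_folds; NaN for invalid folds
    mean_pred_nll: float
    n_folds_valid: int
    frac_removed: float  # mean fraction of training transitions flagged
    noise_on: bool = False


def _fold_seed(base: int, fold: int, family: str) -> int:
    return (base * 1000003 + fold * 8191 + _FAMILY_CODE[family]) % (2**31 - 1)


def walk_forward_cv(
    series: EsmSeries,
    family: str,
    de: DeConfig | None = None,
    cutoff: float = math.inf,
    noise: bool = False,
    n_folds: int = 10,
) -> CvRecord:
    """Average predicted min-log-likelihood of one series under one family.

    Folds are processed from the smallest training set (n = n_folds) to
    the largest (n = 1), and each fold's optimizer is warm-started from
    the previous fold's solution at a reduced iteration budget.  This
    never leaks test information: the warm start comes from a fit on a
    strict subset of the current fold's training data, so no fold's fit
    ever depends on observations outside its own training set.
    """
    de = de or DeConfig.reduced()
    n = series.n
    fold_nlls = np.full(n_folds, np.nan)
    fracs = []
    warm_x = None
    for fold in range(n_folds, 0, -1):
        n_train = n - fold
        test_idx = n_train  # 0-based index of the (N - n + 1)th observation
        if n_train < 2:
            continue
        test_missing = bool(series.obs_missing[test_idx])
        train = series.truncate(n_train)
        plan = build_transition_plan(train)
        if math.isinf(cutoff) or not plan.transitions:
            fit_plan = plan
            frac = 0.0
        else:
            fit_plan, speed_info = filter_plan(train, plan, cutoff)
            frac = 1.0 - float(speed_info.retained_mask.mean())
        warm = warm_x is not None
        fold_de = DeConfig(
            n_pop=de.n_pop,
            cr=de.cr,
            iterations=max(10, de.iterations // 4) if warm else de.iterations,
            f_low=de.f_low,
            f_high=de.f_high,
            seed=_fold_seed(de.seed, fold, family),
            init=de.init,
            init_scale=0.03 if warm else de.init_scale,
            polish=(max(60, de.polish // 4) if de.polish else 0) if warm else de.polish,
        )
        fit = fit_mle(family, train, fit_plan, de=fold_de, noise=noise, x0=warm_x)
        warm_x = fit.raw_x
        if test_missing:
            continue  # nothing to score; fold dropped
        fracs.append(frac)

        # context of the test observation
        scorable = np.flatnonzero(~train.obs_missing)
        last = int(scorable[-1]) if scorable.size else None
        opens_day = last is None or series.day_index[test_idx] != series.day_index[last]
        x_test = series.ratings[test_idx]

        if family == "stationary":
            pred = GaussianPrediction(fit.params.mu, fit.params.cov)
        elif noise:
            dt = None if last is None else float(series.timestamps[test_idx] - series.timestamps[last])
            steps = None if last is None else int(test_idx - last)
            pred = kalman_predict_next(
                fit.params,
                fit.noise,
                train,
                fit_plan,
                opens_day=opens_day,
                dt_hours=dt,
                steps=steps,
            )
        elif opens_day:
            stat = ou_stationary(fit.params) if family == "ou" else var_stationary(fit.params)
            pred = GaussianPrediction(stat.mu, stat.cov)
        elif family == "ou":
            dt = float(series.timestamps[test_idx] - series.timestamps[last])
            pred = ou_conditional(fit.params, series.ratings[last], dt)
        else:
            pred = var_conditional(fit.params, series.ratings[last], int(test_idx - last))
        fold_nlls[fold - 1] = gaussian_nll(x_test, pred)

    valid = np.isfinite(fold_nlls)
    return CvRecord(
        series_id=series.series_id,
        family=family,
        cutoff=cutoff,
        fold_nlls=fold_nlls,
        mean_pred_nll=float(fold_nlls[valid].mean()) if valid.any() else math.nan,
        n_folds_valid=int(valid.sum()),
        frac_removed=float(np.mean(fracs)) if fracs else 0.0,
        noise_on=noise,
    )


def run_study_cv(
    series_list,
    families=("ou", "var", "stationary"),
    cutoffs=(math.inf,),
    de: DeConfig | None = None,
    noise: bool = False,
) -> list[CvRecord]:
    """Walk-forward CV of every series under every family and cutoff."""
    records = []
    for series in series_list:
        for cutoff in cutoffs:
            for family in families:
                records.append(
                    walk_forward_cv(series, family, de=de, cutoff=cutoff, noise=noise)
                )
    return records
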