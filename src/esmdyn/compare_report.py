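"""Aggregation of cross-validation records into model-comparison curves.

The headline summary of the analysis is the *win fraction*: the share
of series for which one model attains a lower averaged predicted
min-log-likelihood than another, traced over a grid of large-deviation
cutoffs C.  A companion AIC comparison uses the training fit instead.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .walk_forward import CvRecord

__all__ = ["win_fraction", "aic", "build_curve", "plot_curves", "DEFAULT_CUTOFF_GRID"]

DEFAULT_CUTOFF_GRID = (math.inf, 10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0)

_TIE_TOL = 1e-12


def win_fraction(records_a: list[CvRecord], records_b: list[CvRecord]) -> float:
    """Fraction of series where model a predicts better than model b.

    Records are paired by series id; exact ties (|difference| < 1e-12)
    are excluded from numerator and denominator.  Returns NaN (with a
    warning) when every pair ties.
    """
    by_id_b = {r.series_id: r for r in records_b}
    if set(r.series_id for r in records_a) != set(by_id_b):
        raise ValueError("records_a and records_b cover different series")
    wins = total = 0
    for ra in records_a:
        diff = ra.mean_pred_nll - by_id_b[ra.series_id].mean_pred_nll
        if math.isnan(diff) or abs(diff) < _TIE_TOL:
            continue
        total += 1
        wins += diff < 0
    if total == 0:
        warnings.warn("all series tie; win fraction undefined", stacklevel=2)
        return math.nan
    return wins / total


def aic(train_nll: float, k: int) -> float:
    """Akaike information criterion ``2k + 2 * min-log-likelihood``."""
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return 2.0 * k + 2.0 * train_nll


def _cell(records, family, cutoff):
    out = [r for r in records if r.family == family and r.cutoff == cutoff]
    return sorted(out, key=lambda r: r.series_id)


def build_curve(records: list[CvRecord], grid=DEFAULT_CUTOFF_GRID) -> pd.DataFrame:
    """Win-fraction curve over a cutoff grid.

    One row per cutoff with the three pairwise win fractions, the
    OU-vs-VAR fraction restricted to series where a dynamical model
    beats its stationary counterpart (subset membership re-evaluated
    per cutoff), the mean fraction of training transitions removed, and
    the number of series.  Raises if any (family, cutoff) cell is
    incomplete.
    """
    gaps = []
    n_series = len({r.series_id for r in records})
    for cutoff in grid:
        for family in ("ou", "var", "stationary"):
            if len(_cell(records, family, cutoff)) != n_series:
                gaps.append((family, cutoff))
    if gaps:
        raise ValueError(f"missing cross-validation cells: {gaps}")

    rows = []
    for cutoff in grid:
        ou = _cell(records, "ou", cutoff)
        var = _cell(records, "var", cutoff)
        stat = _cell(records, "stationary", cutoff)
        stat_by_id = {r.series_id: r for r in stat}
        var_by_id = {r.series_id: r for r in var}
        dyn_ids = {
            r.series_id
            for r in ou
            if r.mean_pred_nll < stat_by_id[r.series_id].mean_pred_nll
            or var_by_id[r.series_id].mean_pred_nll < stat_by_id[r.series_id].mean_pred_nll
        }
        ou_sub = [r for r in ou if r.series_id in dyn_ids]
        var_sub = [r for r in var if r.series_id in dyn_ids]
        rows.append(
            {
                "cutoff": cutoff,
                "ou_vs_var": win_fraction(ou, var),
                "ou_vs_stationary": win_fraction(ou, stat),
                "var_vs_stationary": win_fraction(var, stat),
                "ou_vs_var_dynamic_subset": win_fraction(ou_sub, var_sub)
                if ou_sub
                else math.nan,
                "frac_removed": float(np.mean([r.frac_removed for r in ou + var])),
                "n_series": n_series,
                "n_dynamic_subset": len(dyn_ids),
            }
        )
    return pd.DataFrame(rows)


def plot_curves(curve: pd.DataFrame, path=None):
    """Four-panel style plot of the win-fraction curves (optional output).

    Solid lines: OU vs VAR (with the dynamic-subset variant dashed) and
    each dynamical model vs its stationary counterpart; grey band: mean
    fraction of removed transitions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [("%g" % c) if math.isfinite(c) else "inf" for c in curve["cutoff"]]
    x = np.arange(len(curve))
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax in axes:
        ax.fill_between(x, 0, 100 * curve["frac_removed"], color="0.85", label="% removed")
        ax.set_xticks(x, labels)
        ax.set_xlabel("cutoff C")
        ax.set_ylim(0, 100)
    axes[0].plot(x, 100 * curve["ou_vs_var"], "k-", label="OU vs VAR")
    axes[0].plot(x, 100 * curve["ou_vs_var_dynamic_subset"], "b--", label="dynamic subset")
    axes[0].axhline(50, color="0.6", lw=0.5)
    axes[0].set_ylabel("% series OU wins")
    axes[0].legend(fontsize=8)
    axes[1].plot(x, 100 * curve["ou_vs_stationary"], "b-", label="OU vs stationary")
    axes[1].plot(x, 100 * curve["var_vs_stationary"], "r-", label="VAR vs stationary")
    axes[1].axhline(50, color="0.6", lw=0.5)
    axes[1].set_ylabel("% series dynamical model wins")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
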