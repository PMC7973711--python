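"""Speed-based removal of large deviations.

Large affect changes over short time intervals force a continuous-time
model to adopt implausibly fast relaxation.  To flag them we attach a
speed to every within-day transition,

    v = (1 / dt) * sqrt( sum_j ((x_j,next - x_j,prev) / s_j)^2 ),

the Euclidean displacement of the SD-normalized ratings divided by the
elapsed hours (``s_j`` is the per-dimension sample standard deviation,
which makes the speed invariant to rescaling any dimension).  Speeds
above ``median + C * MAD`` are flagged; flagged transitions are dropped
from training likelihoods, but their end points still serve as starting
points for the next transition.  ``C = inf`` retains everything.

The MAD here is the plain median absolute deviation from the median —
no normal-consistency factor — and the thresholding is a single pass:
speeds are not recomputed after removals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_model import EsmSeries, TransitionPlan

__all__ = ["SpeedSeries", "compute_speeds", "mad_mask", "apply_filter"]


@dataclass
class SpeedSeries:
    """Normalized transition speeds with their robust summary and mask."""

    speeds: np.ndarray  # one per transition item, plan order
    median_speed: float
    mad: float
    cutoff: float  # C; math.inf means keep everything
    retained_mask: np.ndarray  # bool per transition


def compute_speeds(series: EsmSeries, plan: TransitionPlan) -> np.ndarray:
    """Per-transition normalized speeds (displacement per hour).

    ``s_j`` is computed from the scorable (fully observed) observations
    of the series in scope — during cross-validation that is the
    training portion only, so no test information leaks in.
    """
    transitions = plan.transitions
    if not transitions:
        raise ValueError("plan has no transition items")
    observed = series.ratings[~series.obs_missing]
    sd = observed.std(axis=0, ddof=1)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("degenerate constant series: zero sample SD")
    src = np.array([t.source for t in transitions])
    tgt = np.array([t.target for t in transitions])
    dt = np.array([t.dt_hours for t in transitions])
    disp = (series.ratings[tgt] - series.ratings[src]) / sd
    return np.sqrt((disp**2).sum(axis=1)) / dt


def mad_mask(speeds: np.ndarray, cutoff: float) -> np.ndarray:
    """Retained mask under the ``median + C * MAD`` rule (strict > removes)."""
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("no speeds to threshold")
    if not (cutoff > 0):
        raise ValueError("cutoff must be positive (math.inf keeps everything)")
    if math.isinf(cutoff):
        return np.ones(speeds.shape, dtype=bool)
    med = float(np.median(speeds))
    mad = float(np.median(np.abs(speeds - med)))
    return speeds <= med + cutoff * mad


def apply_filter(plan: TransitionPlan, retained_mask: np.ndarray) -> TransitionPlan:
    """New plan with flagged transitions marked not-retained.

    Stationary items are untouched, and the chain structure is
    preserved: a flagged transition's target remains the source of the
    following transition, so only the flagged term leaves the sum.
    """
    retained_mask = np.asarray(retained_mask, dtype=bool)
    n_trans = len(plan.transitions)
    if retained_mask.shape != (n_trans,):
        raise ValueError(
            f"mask length {retained_mask.shape} does not match {n_trans} transitions"
        )
    items = []
    k = 0
    for it in plan.items:
        if it.kind == "transition":
            items.append(replace(it, retained=bool(retained_mask[k]) and it.retained))
            k += 1
        else:
            items.append(replace(it))
    return TransitionPlan(items)


def filter_plan(
    series: EsmSeries, plan: TransitionPlan, cutoff: float
) -> tuple[TransitionPlan, SpeedSeries]:
    """Convenience: compute speeds, threshold at ``cutoff``, apply the mask."""
    if math.isinf(cutoff):
        n = len(plan.transitions)
        mask = np.ones(n, dtype=bool)
        speeds = compute_speeds(series, plan) if n else np.empty(0)
        med = float(np.median(speeds)) if n else math.nan
        mad = float(np.median(np.abs(speeds - med))) if n else math.nan
        return plan, SpeedSeries(speeds, med, mad, cutoff, mask)
    speeds = compute_speeds(series, plan)
    mask = mad_mask(speeds, cutoff)
    med = float(np.median(speeds))
    mad = float(np.median(np.abs(speeds - med)))
    return apply_filter(plan, mask), SpeedSeries(speeds, med, mad, cutoff, mask)
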