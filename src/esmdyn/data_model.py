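"""ESM time-series container, CSV I/O, and day/transition segmentation.

An experience-sampling (ESM) series is one person's sequence of
timestamped multivariate affect ratings, collected over several days in
a daytime window, with missing beeps.  The likelihood conventions used
throughout the package are encoded here once, as a ``TransitionPlan``:

* the first scorable observation of each day is scored under the model's
  stationary distribution (both OU and VAR(1) are assumed to relax
  completely overnight);
* every later scorable observation of the day is scored conditionally on
  the previous scorable observation, carrying both the actual elapsed
  time in hours (for continuous-time models) and a pseudo-step count
  ``1 + number of skipped missing beeps`` (for discrete-time models).

An observation with any missing dimension is treated as fully missing:
the likelihoods are joint over all dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EsmSeries",
    "TransitionItem",
    "StationaryItem",
    "TransitionPlan",
    "read_esm_csv",
    "write_esm_csv",
    "aggregate_pa_na",
    "build_transition_plan",
]


@dataclass
class EsmSeries:
    """One person's timestamped multivariate rating series.

    Attributes
    ----------
    series_id : str
    timestamps : (N,) array
        Hours since 00:00 of the series' first day; strictly increasing.
    day_index : (N,) int array
        Non-decreasing day label per observation.
    ratings : (N, d) array
        Affect ratings (0-100 scale or standardized); entries under a
        true ``missing_mask`` are ignored.
    missing_mask : (N, d) bool array
        True where the rating is missing.
    dim_names : list of d strings
    """

    series_id: str
    timestamps: np.ndarray
    day_index: np.ndarray
    ratings: np.ndarray
    missing_mask: np.ndarray
    dim_names: list[str]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.day_index = np.asarray(self.day_index, dtype=int)
        self.ratings = np.atleast_2d(np.asarray(self.ratings, dtype=float))
        self.missing_mask = np.atleast_2d(np.asarray(self.missing_mask, dtype=bool))
        self.dim_names = list(self.dim_names)
        self.validate()

    @property
    def n(self) -> int:
        return self.timestamps.shape[0]

    @property
    def d(self) -> int:
        return self.ratings.shape[1]

    @property
    def obs_missing(self) -> np.ndarray:
        """(N,) bool: observation treated as fully missing (any dim missing)."""
        return self.missing_mask.any(axis=1)

    def validate(self) -> None:
        n = self.n
        if self.ratings.shape != (n, self.d) or self.missing_mask.shape != (n, self.d):
            raise ValueError(f"series {self.series_id!r}: inconsistent array shapes")
        if len(self.dim_names) != self.d:
            raise ValueError(f"series {self.series_id!r}: dim_names length != d")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(
                f"series {self.series_id!r}: timestamps must be strictly increasing"
            )
        if n >= 2 and np.any(np.diff(self.day_index) < 0):
            raise ValueError(
                f"series {self.series_id!r}: day_index must be non-decreasing"
            )
        observed = ~self.missing_mask
        if not np.all(np.isfinite(self.ratings[observed])):
            raise ValueError(
                f"series {self.series_id!r}: non-finite rating marked as observed"
            )

    def truncate(self, n_obs: int) -> "EsmSeries":
        """First ``n_obs`` observations (beeps, missing ones included)."""
        return EsmSeries(
            self.series_id,
            self.timestamps[:n_obs].copy(),
            self.day_index[:n_obs].copy(),
            self.ratings[:n_obs].copy(),
            self.missing_mask[:n_obs].copy(),
            self.dim_names,
        )


@dataclass
class StationaryItem:
    """Score observation ``target`` under the model's stationary distribution."""

    target: int
    retained: bool = True

    kind = "stationary"


@dataclass
class TransitionItem:
    """Score observation ``target`` conditionally on observation ``source``."""

    source: int
    target: int
    dt_hours: float
    steps: int
    retained: bool = True

    kind = "transition"


@dataclass
class TransitionPlan:
    """Ordered scoring items covering every scorable observation exactly once."""

    items: list

    @property
    def transitions(self) -> list[TransitionItem]:
        return [it for it in self.items if it.kind == "transition"]

    @property
    def stationary_items(self) -> list[StationaryItem]:
        return [it for it in self.items if it.kind == "stationary"]

    def targets(self) -> list[int]:
        return [it.target for it in self.items]


def build_transition_plan(
    series: EsmSeries,
    model_timescale: Literal["continuous", "unit_step"] = "continuous",
) -> TransitionPlan:
    """Segment a series into stationary and transition scoring items.

    The plan is identical for both timescales — each transition carries
    both the elapsed hours and the pseudo-step count — so
    ``model_timescale`` only records the caller's intent.
    """
    items: list = []
    prev_obs: int | None = None  # last scorable observation of the current day
    prev_day: int | None = None
    missing = series.obs_missing
    for i in range(series.n):
        if missing[i]:
            continue
        day = int(series.day_index[i])
        if prev_day is None or day != prev_day or prev_obs is None:
            items.append(StationaryItem(target=i))
        else:
            skipped = int(missing[prev_obs + 1 : i].sum())
            items.append(
                TransitionItem(
                    source=prev_obs,
                    target=i,
                    dt_hours=float(series.timestamps[i] - series.timestamps[prev_obs]),
                    steps=1 + skipped,
                )
            )
        prev_obs = i
        prev_day = day
    return TransitionPlan(items)


def aggregate_pa_na(
    series: EsmSeries,
    positive_items: Sequence[str],
    negative_items: Sequence[str],
) -> EsmSeries:
    """Collapse raw emotion items into per-beep PA and NA means.

    Each aggregate is the mean of the *observed* items in its group; it
    is missing only when every item of the group is missing at a beep.
    """
    if len(positive_items) == 0 or len(negative_items) == 0:
        raise ValueError("positive_items and negative_items must be non-empty")
    idx = {name: j for j, name in enumerate(series.dim_names)}
    for name in list(positive_items) + list(negative_items):
        if name not in idx:
            raise KeyError(f"item {name!r} not among series dimensions")

    out = np.full((series.n, 2), np.nan)
    mask = np.ones((series.n, 2), dtype=bool)
    for k, group in enumerate((positive_items, negative_items)):
        cols = [idx[name] for name in group]
        vals = series.ratings[:, cols]
        miss = series.missing_mask[:, cols]
        cnt = (~miss).sum(axis=1)
        with np.errstate(invalid="ignore"):
            summed = np.where(miss, 0.0, vals).sum(axis=1)
        has = cnt > 0
        out[has, k] = summed[has] / cnt[has]
        mask[:, k] = ~has
    return EsmSeries(
        series.series_id,
        series.timestamps.copy(),
        series.day_index.copy(),
        out,
        mask,
        ["PA", "NA"],
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: header row; columns  series_id, datetime (ISO 8601) OR t_hours,
# day (optional), then one column per rating item; missing = empty cell.
# ---------------------------------------------------------------------------

_RESERVED = {"series_id", "datetime", "t_hours", "day"}


def read_esm_csv(path, schema: dict | None = None) -> list[EsmSeries]:
    """Read ESM series from delimited text.

    Parameters
    ----------
    path : str or file-like
    schema : dict, optional
        Column-name mapping with keys among ``series_id``, ``datetime``,
        ``t_hours``, ``day``, ``items`` (list of rating columns).
        Defaults to the canonical column names, with every non-reserved
        column treated as a rating item.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, float_precision="round_trip")
    id_col = schema.get("series_id", "series_id")
    time_col = schema.get("t_hours", "t_hours" if "t_hours" in df.columns else None)
    dt_col = schema.get("datetime", "datetime" if "datetime" in df.columns else None)
    day_col = schema.get("day", "day" if "day" in df.columns else None)
    if id_col not in df.columns:
        raise ValueError(f"missing series-id column {id_col!r}")
    if time_col is None and dt_col is None:
        raise ValueError("need a 't_hours' or 'datetime' column")

    if "items" in schema:
        items = list(schema["items"])
        unknown = [c for c in items if c not in df.columns]
        if unknown:
            raise ValueError(f"unknown item columns: {unknown}")
    else:
        reserved = {id_col, time_col, dt_col, day_col} | _RESERVED
        items = [c for c in df.columns if c not in reserved]
    if not items:
        raise ValueError("no rating item columns found")

    out: list[EsmSeries] = []
    for sid, grp in df.groupby(id_col, sort=True):
        if time_col is not None and time_col in grp.columns:
            t = grp[time_col].to_numpy(dtype=float)  # t_hours wins over datetime
        else:
            stamps = pd.to_datetime(grp[dt_col])
            origin = stamps.min().normalize()  # 00:00 of the first day
            t = ((stamps - origin) / pd.Timedelta(hours=1)).to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        grp = grp.iloc[order]
        t = t[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"series {sid!r}: duplicated or non-monotone timestamps"
            )
        if day_col is not None and day_col in grp.columns:
            day = grp[day_col].to_numpy(dtype=int)
        else:
            day = np.floor(t / 24.0).astype(int)
        ratings = grp[items].to_numpy(dtype=float)
        mask = ~np.isfinite(ratings)
        ratings = np.where(mask, np.nan, ratings)
        out.append(EsmSeries(str(sid), t, day, ratings, mask, items))
    return out


def write_esm_csv(path, series_list: Iterable[EsmSeries]) -> None:
    """Write series in the package CSV dialect (t_hours timestamps).

    Finite observed values round-trip bit-exactly through
    ``read_esm_csv`` (full-precision ``repr`` formatting).
    """
    frames = []
    for s in series_list:
        data = {
            "series_id": s.series_id,
            "t_hours": [repr(float(t)) for t in s.timestamps],
            "day": s.day_index,
        }
        for j, name in enumerate(s.dim_names):
            data[name] = [
                "" if m else repr(float(v))
                for v, m in zip(s.ratings[:, j], s.missing_mask[:, j])
            ]
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
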