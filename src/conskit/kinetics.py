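"""Terminal-phase half-life estimation by log-linear regression.

The desk-scale counterpart of non-compartmental analysis (NCA) as performed
by PK software: the elimination rate constant ``lambda_z`` is minus the slope
of ordinary least squares of ``ln(value)`` on time over a terminal window of
sampling points, and ``t_half = ln(2) / lambda_z``. The window is chosen by
the standard "best fit" rule: every contiguous terminal window of at least
``min_points`` points starting at or after the observed maximum is fitted,
and the window with maximal adjusted R-squared wins (ties go to the window
with more points). Nonpositive values are excluded (their logarithm is
undefined), never imputed.

Only the half-life is computed; exposure metrics (AUC, clearance) and
compartmental models are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, NoDataError, NoDecayError

# Adjusted-R^2 differences below this are treated as ties (favoring the
# longer window); absorbs float rounding on noiseless data.
_R2_TIE_TOL = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """One time-measurement series (hours vs. arbitrary positive units)."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    series_id: str | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if len(times) != len(values):
            raise InsufficientDataError("times and values must have equal length")
        if len(times) < 3:
            raise InsufficientDataError("a series needs at least 3 points")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InsufficientDataError("times must be strictly increasing")
        if any(v < 0 for v in values):
            raise InsufficientDataError("values must be nonnegative")
        if sum(v > 0 for v in values) < 3:
            raise InsufficientDataError("at least 3 strictly positive values required")


@dataclass(frozen=True)
class DecayFit:
    """Terminal-phase fit result."""

    lambda_z: float            # 1/hour
    t_half: float              # hours, ln(2) / lambda_z
    r2_adj: float
    n_points: int
    points_used: tuple[int, ...]   # indices into the original series
    series_id: str | None = None


def _adjusted_r2(r2: float, n: int) -> float:
    if n <= 2:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_terminal_halflife(series: TimeSeries, min_points: int = 3) -> DecayFit:
    """Fit the terminal elimination phase of one series.

    Considers every contiguous terminal window of at least ``min_points``
    positive-valued points starting at or after the time of the observed
    maximum, fits ``ln(value) ~ time`` by OLS in each, and keeps the window
    with the highest adjusted R-squared (ties favor more points).
    """
    times = np.asarray(series.times, dtype=float)
    values = np.asarray(series.values, dtype=float)
    t_max = times[int(np.argmax(values))]
    usable = np.flatnonzero((values > 0) & (times >= t_max))
    if usable.size < min_points:
        raise InsufficientDataError(
            f"only {usable.size} usable terminal points, need {min_points}"
        )

    best: tuple[float, int, float, tuple[int, ...]] | None = None
    for start in range(usable.size - min_points + 1):
        idx = usable[start:]
        fit = stats.linregress(times[idx], np.log(values[idx]))
        r2a = _adjusted_r2(fit.rvalue**2, idx.size)
        if (
            best is None
            or r2a > best[0] + _R2_TIE_TOL
            or (abs(r2a - best[0]) <= _R2_TIE_TOL and idx.size > best[1])
        ):
            best = (r2a, idx.size, fit.slope, tuple(int(i) for i in idx))
    assert best is not None
    r2a, n, slope, points_used = best
    if slope >= 0:
        raise NoDecayError(
            f"best terminal window has nonnegative slope ({slope:.3g}/h): no decay"
        )
    lam = float(-slope)
    r2a = float(r2a)
    return DecayFit(
        lambda_z=lam,
        t_half=math.log(2) / lam,
        r2_adj=r2a,
        n_points=n,
        points_used=points_used,
        series_id=series.series_id,
    )


@dataclass(frozen=True)
class FitSummary:
    """Per-series fit table plus robust half-life aggregates."""

    table: pd.DataFrame
    t_half_median: float
    t_half_iqr: tuple[float, float]


def summarize_fits(fits: Sequence[DecayFit]) -> FitSummary:
    """Tabulate fits and report median and interquartile range of t_half."""
    if not fits:
        raise NoDataError("no fits to summarize")
    table = pd.DataFrame(
        {
            "series_id": [f.series_id for f in fits],
            "t_half": [f.t_half for f in fits],
            "lambda_z": [f.lambda_z for f in fits],
            "r2_adj": [f.r2_adj for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )
    halves = table["t_half"].to_numpy()
    q1, q3 = np.percentile(halves, [25, 75])
    return FitSummary(
        table=table,
        t_half_median=float(np.median(halves)),
        t_half_iqr=(float(q1), float(q3)),
    )


def read_decay_table(path: str | Path) -> list[TimeSeries]:
    """Read series from a TSV with columns time_h, value, optional series_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_h", "value"}
    if not required <= set(df.columns):
        raise NoDataError(f"decay table needs columns {sorted(required)}, got {list(df.columns)}")
    series: list[TimeSeries] = []
    if "series_id" in df.columns:
        groups: Iterable[tuple[object, pd.DataFrame]] = df.groupby("series_id", sort=False)
    else:
        groups = [(None, df)]
    for sid, sub in groups:
        sub = sub.sort_values("time_h")
        series.append(
            TimeSeries(
                times=tuple(sub["time_h"]),
                values=tuple(sub["value"]),
                series_id=None if sid is None else str(sid),
            )
        )
    return series


def mean_series(replicates: Sequence[TimeSeries], series_id: str | None = None) -> TimeSeries:
    """Arithmetic mean of replicate series sharing identical sampling times."""
    if not replicates:
        raise NoDataError("no replicate series given")
    times = replicates[0].times
    if any(r.times != times for r in replicates[1:]):
        raise InsufficientDataError("replicates must share identical sampling times")
    values = np.mean([r.values for r in replicates], axis=0)
    return TimeSeries(times=times, values=tuple(values), series_id=series_id)
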