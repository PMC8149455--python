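"""Mander's colocalization coefficients for paired intensity channels.

M1 is the fraction of channel-a signal that lies on pixels where channel b is
above its threshold, over the total above-threshold channel-a signal; M2 is
the symmetric quantity for channel b:

    M1 = sum(a_i * [b_i > t_b]) / sum(a_i * [a_i > t_a])
    M2 = sum(b_i * [a_i > t_a]) / sum(b_i * [b_i > t_b])

With zero thresholds these are the classic Mander's overlap fractions
("colocalized signal over total signal"). Threshold selection is left to the
caller; no automated (Costes-style) thresholding is implemented. Z-stacks
are handled by treating each optical section as one pair and aggregating at
the batch level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConskitError, NoDataError, NoSignalError


@dataclass(frozen=True)
class ChannelPair:
    """Two equal-shape nonnegative intensity arrays with per-channel thresholds."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    threshold_a: float = 0.0
    threshold_b: float = 0.0
    pair_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.channel_a, dtype=float)
        b = np.asarray(self.channel_b, dtype=float)
        object.__setattr__(self, "channel_a", a)
        object.__setattr__(self, "channel_b", b)
        if a.shape != b.shape:
            raise ConskitError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if (a < 0).any() or (b < 0).any():
            raise ConskitError("intensities must be nonnegative")
        if self.threshold_a < 0 or self.threshold_b < 0:
            raise ConskitError("thresholds must be nonnegative")

    def swapped(self) -> "ChannelPair":
        return ChannelPair(
            channel_a=self.channel_b,
            channel_b=self.channel_a,
            threshold_a=self.threshold_b,
            threshold_b=self.threshold_a,
            pair_id=self.pair_id,
            group=self.group,
        )


@dataclass(frozen=True)
class ColocResult:
    m1: float
    m2: float
    pair_id: str | None = None
    group: str | None = None


def manders_coefficients(pair: ChannelPair) -> ColocResult:
    """Compute (M1, M2) for one channel pair."""
    a, b = pair.channel_a, pair.channel_b
    total_a = float(a[a > pair.threshold_a].sum())
    total_b = float(b[b > pair.threshold_b].sum())
    if total_a <= 0 or total_b <= 0:
        raise NoSignalError(
            "zero total above-threshold signal "
            f"(a: {total_a}, b: {total_b}); coefficients undefined"
        )
    m1 = float(a[b > pair.threshold_b].sum()) / total_a
    m2 = float(b[a > pair.threshold_a].sum()) / total_b
    return ColocResult(m1=m1, m2=m2, pair_id=pair.pair_id, group=pair.group)


def batch_coloc(
    pairs: Sequence[ChannelPair],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coefficients for many pairs plus mean +/- SD per group label.

    Returns ``(per_pair, per_group)`` DataFrames. Pairs without a group label
    aggregate under the label ``"all"``. SD is the sample standard deviation
    (ddof=1; 0 for singleton groups).
    """
    if not pairs:
        raise NoDataError("no channel pairs given")
    results = [manders_coefficients(p) for p in pairs]
    per_pair = pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "group": [r.group if r.group is not None else "all" for r in results],
            "m1": [r.m1 for r in results],
            "m2": [r.m2 for r in results],
        }
    )
    per_group = (
        per_pair.groupby("group", sort=False)[["m1", "m2"]]
        .agg(["mean", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, "count"])
        .reset_index()
    )
    per_group.columns = [
        "group", "m1_mean", "m1_sd", "m1_n", "m2_mean", "m2_sd", "m2_n",
    ]
    return per_pair, per_group


def load_channel(path: str | Path) -> np.ndarray:
    """Load an intensity matrix from TSV/CSV text or a grayscale image file."""
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        return np.loadtxt(path, dtype=float)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, dtype=float, delimiter=",")
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale by mean over channels
        arr = arr[..., :3].mean(axis=-1)
    return arr
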