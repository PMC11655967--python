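"""Dive detection, phase segmentation, and per-dive statistics.

A dive is a maximal submerged excursion reaching at least ``min_depth``
(default 25 m) and lasting at least ``min_duration`` (default 32 s);
shallower or shorter excursions are surface behavior, not dives, for a
deep-diving phocid.  Each dive is split into descent, bottom, and ascent
phases; the bottom phase is constrained to depths greater than half the
dive's maximum depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import TDRSeries, from_seconds

log = logging.getLogger(__name__)

#: Columns of the dive-statistics table, in output order.
DIVESTAT_COLUMNS = [
    "dive_number", "start", "end", "duration", "max_depth",
    "descent_duration", "bottom_duration", "ascent_duration",
    "descent_rate", "ascent_rate", "bottom_range", "wiggles",
    "post_dive_interval", "lat", "lon", "lat_se", "lon_se",
    "solar_elevation",
]


@dataclass
class DiveCriteria:
    min_depth: float = 25.0  # meters
    min_duration: float = 32.0  # seconds
    bottom_depth_fraction: float = 0.5  # of max depth
    speed_fraction: float = 0.75  # of initial descent / final ascent rate
    #: readings within this of zero count as surface; None → one sensor
    #: count (residual correction error is at most the quantization step)
    surface_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_duration <= 0:
            raise ValueError("criteria must be positive")
        if not 0 < self.bottom_depth_fraction < 1:
            raise ValueError("bottom_depth_fraction must be in (0, 1)")

    def surface_for(self, series: TDRSeries) -> float:
        return (
            self.surface_threshold
            if self.surface_threshold is not None
            else series.depth_resolution
        )


def detect_dives(
    series: TDRSeries, criteria: DiveCriteria | None = None
) -> list[tuple[int, int]]:
    """Find dives in a zero-offset-corrected series.

    Returns (start, end) sample-index pairs where start/end are the last
    and first surface samples bounding each submerged excursion.  Negative
    corrected depths are treated as surface.  Both thresholds are
    inclusive: an excursion to exactly 25 m for exactly 32 s is a dive.
    """
    criteria = criteria or DiveCriteria()
    d = np.maximum(series.depth, 0.0)
    t = series.seconds
    wet = d > criteria.surface_for(series)
    dives = []
    n = len(d)
    i = 0
    while i < n:
        if wet[i]:
            j = i
            while j + 1 < n and wet[j + 1]:
                j += 1
            start = max(i - 1, 0)  # last surface sample before the excursion
            end = min(j + 1, n - 1)  # first surface sample after
            max_depth = d[i : j + 1].max()
            duration = t[end] - t[start]
            if max_depth >= criteria.min_depth and duration >= criteria.min_duration:
                dives.append((start, end))
            i = j + 1
        else:
            i += 1
    return dives


def segment_phases(
    series: TDRSeries,
    dive: tuple[int, int],
    criteria: DiveCriteria | None = None,
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Split a dive into (descent, bottom, ascent) index spans.

    Vertical speed is smoothed with a 3-sample moving mean; the descent
    ends where smoothed speed falls below ``speed_fraction`` of the initial
    descent rate, and the ascent begins (mirror rule) at the last sample
    where smoothed speed exceeds that fraction of the final ascent rate —
    the speed inflections that mark a behavioral change.  The bottom phase
    is then constrained to the contiguous block of samples deeper than
    ``bottom_depth_fraction`` of the maximum depth that contains the
    deepest sample; V-shaped dives get a single-sample bottom at max depth.
    """
    criteria = criteria or DiveCriteria()
    s0, s1 = dive
    d = np.maximum(series.depth[s0 : s1 + 1], 0.0)
    t = series.seconds[s0 : s1 + 1]
    n = len(d)
    imax = int(np.argmax(d))
    max_depth = d[imax]
    if n < 4:
        b = s0 + imax
        return (s0, b), (b, b), (b, s1)

    v = np.diff(d) / np.diff(t)  # v[i] between samples i and i+1
    if len(v) >= 3:
        vs = np.convolve(v, np.ones(3) / 3, mode="same")
    else:
        vs = v

    init_rate = max(vs[0], 1e-9)
    k = 0
    while k < imax and vs[k] >= criteria.speed_fraction * init_rate:
        k += 1
    descent_end = k  # first sample where smoothed speed dropped

    final_rate = max(-vs[-1], 1e-9)
    k = len(vs) - 1
    while k > imax - 1 and -vs[k] >= criteria.speed_fraction * final_rate:
        k -= 1
    ascent_start = k + 1

    # hard contract: bottom samples deeper than the depth-fraction threshold,
    # contiguous around the deepest sample
    thresh = criteria.bottom_depth_fraction * max_depth
    lo = imax
    while lo > 0 and d[lo - 1] > thresh:
        lo -= 1
    hi = imax
    while hi < n - 1 and d[hi + 1] > thresh:
        hi += 1
    b0 = max(descent_end, lo)
    b1 = min(ascent_start, hi)
    degenerate_v = (imax - descent_end) <= 1 and (ascent_start - imax) <= 1
    if b0 > b1 or not (b0 <= imax <= b1) or degenerate_v:
        b0 = b1 = imax  # V-dive: bottom collapses to the apex
    return (s0, s0 + b0), (s0 + b0, s0 + b1), (s0 + b1, s1)


def count_wiggles(depths: np.ndarray, min_amplitude: float) -> int:
    """Count complete up-and-down oscillations of amplitude ≥ ``min_amplitude``.

    One wiggle = an upward deflection (depth decrease from a running
    maximum) followed by a return to descent, each leg at least the
    minimum amplitude — the zig-zag count commonly used as a foraging
    proxy.  Monotone segments and sub-amplitude jitter contribute nothing.
    """
    if len(depths) < 3:
        return 0
    count = 0
    direction = 1  # +1 descending (depth increasing), -1 ascending
    extreme = depths[0]
    for x in depths[1:]:
        if direction == 1:
            if x > extreme:
                extreme = x
            elif extreme - x >= min_amplitude:
                direction = -1
                extreme = x
        else:
            if x < extreme:
                extreme = x
            elif x - extreme >= min_amplitude:
                direction = 1
                extreme = x
                count += 1  # completed an up-down oscillation
    return count


def compute_dive_stats(
    series: TDRSeries,
    dives: list[tuple[int, int]],
    criteria: DiveCriteria | None = None,
) -> pd.DataFrame:
    """One row of statistics per detected dive (the Level 3 dive table)."""
    criteria = criteria or DiveCriteria()
    t = series.seconds
    rows = []
    for k, (s0, s1) in enumerate(dives):
        (ds0, ds1), (b0, b1), (a0, a1) = segment_phases(series, (s0, s1), criteria)
        d = np.maximum(series.depth, 0.0)
        max_depth = float(d[s0 : s1 + 1].max())
        duration = float(t[s1] - t[s0])
        desc_dur = float(t[ds1] - t[ds0])
        bot_dur = float(t[b1] - t[b0])
        asc_dur = float(t[a1] - t[a0])
        desc_rate = float((d[ds1] - d[ds0]) / desc_dur) if desc_dur > 0 else np.nan
        asc_rate = float((d[a0] - d[a1]) / asc_dur) if asc_dur > 0 else np.nan
        bottom = d[b0 : b1 + 1]
        bottom_range = float(bottom.max() - bottom.min()) if bottom.size else 0.0
        wig = count_wiggles(bottom, 2 * series.depth_resolution)
        rows.append(
            dict(
                dive_number=k + 1,
                start=from_seconds(np.array([t[s0]]))[0],
                end=from_seconds(np.array([t[s1]]))[0],
                duration=duration,
                max_depth=max_depth,
                descent_duration=desc_dur,
                bottom_duration=bot_dur,
                ascent_duration=asc_dur,
                descent_rate=desc_rate,
                ascent_rate=asc_rate,
                bottom_range=bottom_range,
                wiggles=wig,
                post_dive_interval=np.nan,
                lat=np.nan, lon=np.nan, lat_se=np.nan, lon_se=np.nan,
                solar_elevation=np.nan,
                _start_idx=s0, _end_idx=s1,
            )
        )
    df = pd.DataFrame(rows, columns=DIVESTAT_COLUMNS + ["_start_idx", "_end_idx"])
    if len(df) > 1:
        starts = df["start"].to_numpy("datetime64[s]").astype("int64")
        ends = df["end"].to_numpy("datetime64[s]").astype("int64")
        pdi = (starts[1:] - ends[:-1]).astype(float)
        df.loc[df.index[:-1], "post_dive_interval"] = pdi
    return df


def merge_zero_pdi(stats: pd.DataFrame, series: TDRSeries,
                   criteria: DiveCriteria | None = None) -> pd.DataFrame:
    """Merge dives whose post-dive interval is 0 s with their successor.

    A 0-s surface interval means the detector split one dive in two
    (a mid-dive surface artifact); the two spans are merged and statistics
    recomputed from the corrected series.  Applied iteratively until no
    zero PDIs remain; a trailing dive with zero PDI and no successor is
    left as-is.
    """
    criteria = criteria or DiveCriteria()
    if stats.empty:
        return stats
    spans = list(zip(stats["_start_idx"].astype(int), stats["_end_idx"].astype(int)))
    pdis = stats["post_dive_interval"].to_numpy()
    changed = True
    while changed:
        changed = False
        for i in range(len(spans) - 1):
            if pdis[i] == 0:
                spans[i] = (spans[i][0], spans[i + 1][1])
                del spans[i + 1]
                pdis = np.delete(pdis, i)
                pdis[i] = _pdi_after(spans, i, series)
                changed = True
                break
    out = compute_dive_stats(series, spans, criteria)
    return out


def _pdi_after(spans, i, series) -> float:
    if i + 1 >= len(spans):
        return np.nan
    t = series.seconds
    return float(t[spans[i + 1][0]] - t[spans[i][1]])


def filter_dive_stats(
    stats: pd.DataFrame,
    max_rate: float = 3.0,
    max_duration: float = 150 * 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coarse plausibility filter on the Level 3 dive table.

    Rows with descent or ascent rate above 3 m/s or duration above
    150 min — beyond what the animal can achieve — are moved to the
    ``removed`` table (they remain in earlier data levels).  Values exactly
    at a threshold are kept: the bounds are strict.
    """
    if stats.empty:
        return stats, stats.copy()
    bad = (
        (stats["descent_rate"] > max_rate)
        | (stats["ascent_rate"] > max_rate)
        | (stats["duration"] > max_duration)
    )
    return stats[~bad].reset_index(drop=True), stats[bad].reset_index(drop=True)


def write_divestat_csv(stats: pd.DataFrame, path) -> None:
    """Write the dive table as DiveStat.csv (ISO-8601 datetimes)."""
    out = stats[DIVESTAT_COLUMNS].copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
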