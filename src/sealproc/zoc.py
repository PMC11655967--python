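"""Zero-offset correction (ZOC) of depth series.

Pressure sensors drift over a multi-month deployment, so the raw "surface"
wanders away from 0 m.  The correction here mirrors the classic windowed
approach: despike, trim to a realistic depth range, estimate an approximate
surface per two-hour window as the most repeated shallow value, then refine
the surface at the start and end of each dive, constrained to lie within
``refine_multiplier`` times the sensor resolution of the window estimate.
Corrected depth = original depth − applicable surface offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import Level, TDRSeries

log = logging.getLogger(__name__)


@dataclass
class ZocConfig:
    """Tunables for the zero-offset correction.

    Defaults are the values used for northern elephant seals: a two-hour
    surface-estimation window, a 5 m/s vertical-speed spike filter, a
    realistic depth range of −10 m (10 m above the surface) to 2,200 m, a
    15 m ceiling for surface-candidate samples, and a refinement tolerance
    of 15 sensor counts.
    """

    window: float = 7200.0  # seconds
    spike_speed: float = 5.0  # m/s
    min_depth: float = -10.0  # meters (above-surface readings allowed)
    max_depth: float = 2200.0  # meters
    surface_search_ceiling: float = 15.0  # meters
    refine_multiplier: float = 15.0  # × depth_resolution
    frequent_fraction: float = 0.001  # for suggest_min_depth

    def __post_init__(self) -> None:
        if self.window <= 0 or self.spike_speed <= 0:
            raise ValueError("window and spike_speed must be positive")
        if not (self.min_depth < 0 < self.max_depth):
            raise ValueError("need min_depth < 0 < max_depth")
        if self.surface_search_ceiling <= 0:
            raise ValueError("surface_search_ceiling must be positive")


@dataclass
class ZocResult:
    corrected: TDRSeries
    window_offsets: list[tuple[np.datetime64, float]]
    per_dive_surfaces: list[tuple[int, float, float]]
    removed_samples: int
    offset_per_sample: np.ndarray = field(default=None)  # type: ignore[assignment]


def despike(series: TDRSeries, spike_speed: float = 5.0) -> TDRSeries:
    """Replace isolated depth spikes by neighbor interpolation.

    A spike is a run of at most two samples entered and exited at a
    vertical speed above ``spike_speed`` with opposite signs — sensor
    glitches rather than swimming.  Sustained fast segments are left
    untouched.  Replacing (instead of deleting) preserves the sampling
    grid.
    """
    if len(series) < 3:
        return series
    t = series.seconds
    d = series.depth.copy()
    n_replaced = 0
    # two passes so a two-sample spike collapses after its first sample does
    for _ in range(2):
        dt = np.diff(t)
        v = np.diff(d) / dt  # v[i] = speed from sample i to i+1
        changed = False
        i = 1
        while i < len(d) - 1:
            run_end = None
            if abs(v[i - 1]) > spike_speed:
                # candidate spike starting at i; try run lengths 1 then 2
                for L in (1, 2):
                    j = i + L - 1  # last sample of run
                    if j + 1 >= len(d):
                        break
                    v_out = (d[j + 1] - d[j]) / (t[j + 1] - t[j])
                    if abs(v_out) > spike_speed and np.sign(v_out) != np.sign(v[i - 1]):
                        run_end = j
                        break
            if run_end is not None:
                lo, hi = i - 1, run_end + 1
                frac = (t[i : run_end + 1] - t[lo]) / (t[hi] - t[lo])
                d[i : run_end + 1] = d[lo] + frac * (d[hi] - d[lo])
                n_replaced += run_end - i + 1
                changed = True
                i = hi
            else:
                i += 1
        if not changed:
            break
    if n_replaced:
        log.info("despike: replaced %d samples", n_replaced)
    return series.with_(depth=d)


def trim_range(series: TDRSeries, min_depth: float, max_depth: float) -> TDRSeries:
    """Drop samples outside the realistic depth range [min_depth, max_depth]."""
    if min_depth >= max_depth:
        raise ValueError("min_depth must be below max_depth")
    keep = (series.depth >= min_depth) & (series.depth <= max_depth)
    n_removed = int((~keep).sum())
    if n_removed == len(series):
        raise ValueError("range trim removed every sample")
    if n_removed:
        log.info("trim_range: removed %d samples outside [%g, %g] m",
                 n_removed, min_depth, max_depth)
    return series.with_(time=series.time[keep], depth=series.depth[keep])


def suggest_min_depth(
    series: TDRSeries, default_min: float = -10.0, frequent_fraction: float = 0.001
) -> float:
    """Advise a lower trim bound when above-surface readings are frequent.

    Some sensors persistently read well above the surface (e.g. near
    −40 m).  If at least ``frequent_fraction`` of samples lie below
    ``default_min``, the 1st percentile of those values (floored to the
    sensor resolution) is suggested instead; otherwise the default is
    returned.  Purely advisory — nothing is trimmed here.
    """
    below = series.depth[series.depth < default_min]
    if len(series) == 0 or below.size < frequent_fraction * len(series) or below.size == 0:
        return default_min
    p1 = np.percentile(below, 1.0)
    res = series.depth_resolution
    return float(np.floor(p1 / res) * res)


def _mode_binned(depths: np.ndarray, resolution: float) -> float:
    """Mode of depths binned at the sensor resolution; ties go shallow."""
    bins = np.round(depths / resolution).astype(np.int64)
    values, counts = np.unique(bins, return_counts=True)
    best = counts.max()
    # values is sorted ascending, so the first max-count bin is the shallowest
    return float(values[np.argmax(counts == best)] * resolution)


def window_surface_offsets(
    series: TDRSeries, config: ZocConfig | None = None
) -> list[tuple[np.datetime64, float]]:
    """Approximate surface offset per fixed two-hour window.

    Windows are contiguous, non-overlapping, and anchored at the record
    start.  Within each window the offset is the most repeated depth
    (binned at the sensor resolution) among samples between ``min_depth``
    and ``surface_search_ceiling``.  Windows with no surface candidates
    (e.g. a continuous deep dive) inherit the previous window's offset;
    leading empty windows inherit the first available one.
    """
    config = config or ZocConfig()
    t = series.seconds
    d = series.depth
    if len(series) == 0:
        raise ValueError("empty series")
    edges = np.arange(t[0], t[-1] + config.window, config.window)
    offsets: list[float | None] = []
    starts: list[float] = []
    for w0 in edges[:-1]:
        in_win = (t >= w0) & (t < w0 + config.window)
        cand = d[in_win & (d >= config.min_depth) & (d <= config.surface_search_ceiling)]
        starts.append(w0)
        offsets.append(_mode_binned(cand, series.depth_resolution) if cand.size else None)
    if all(o is None for o in offsets):
        raise ValueError("no surface intervals found")
    # forward fill, then back fill the leading Nones
    last = None
    for i, o in enumerate(offsets):
        if o is None and last is not None:
            offsets[i] = last
        elif o is not None:
            last = o
    first = next(o for o in offsets if o is not None)
    for i, o in enumerate(offsets):
        if o is None:
            offsets[i] = first
        else:
            break
    from .types import from_seconds

    return [(from_seconds(np.array([s]))[0], float(o)) for s, o in zip(starts, offsets)]


def _offsets_at(t: np.ndarray, window_offsets, window: float) -> np.ndarray:
    """Per-sample window offset (step function over the fixed windows)."""
    starts = np.array([w[0].astype("datetime64[s]").astype("int64") for w in window_offsets], dtype=float)
    vals = np.array([w[1] for w in window_offsets])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(vals) - 1)
    return vals[idx]


def refine_dive_surfaces(
    series: TDRSeries,
    window_offsets: list[tuple[np.datetime64, float]],
    config: ZocConfig | None = None,
) -> ZocResult:
    """Per-dive surface refinement and final correction.

    Excursions below the surface-search ceiling (relative to the window
    offset) are treated as provisional dives.  The shallowest reading in
    the bounding surface intervals gives candidate start/end surfaces; a
    candidate is accepted only if it lies within
    ``refine_multiplier × depth_resolution`` of the window offset
    (7.5 m for a 0.5 m-resolution sensor), otherwise the window offset is
    used.  Inside a dive the applicable surface is interpolated linearly
    between the accepted start and end surfaces; outside dives the window
    offset applies.  Negative corrected depths are preserved (the dive
    detector clips them to 0).
    """
    config = config or ZocConfig()
    t = series.seconds
    d = series.depth
    base = _offsets_at(t, window_offsets, config.window)
    tol = config.refine_multiplier * series.depth_resolution

    # provisional dives: runs where depth-base exceeds the ceiling; the
    # complement segments are surface intervals
    deep = (d - base) > config.surface_search_ceiling
    runs: list[tuple[int, int]] = []
    in_run = False
    s0 = 0
    for i, flag in enumerate(deep):
        if flag and not in_run:
            s0, in_run = i, True
        elif not flag and in_run:
            runs.append((s0, i - 1))
            in_run = False
    if in_run:
        runs.append((s0, len(deep) - 1))

    # accepted surface value per surface interval: local minimum depth,
    # tolerance-checked against the window offset
    offset = base.copy()
    surf_vals: list[float] = []
    intervals: list[tuple[int, int]] = []  # [lo, hi) index ranges of surface intervals
    lo = 0
    for s0, s1 in runs + [(len(d), len(d))]:
        hi = s0
        if hi > lo:
            seg = d[lo:hi]
            b = float(np.median(base[lo:hi]))
            cand = float(seg.min())
            surf_vals.append(cand if abs(cand - b) <= tol else b)
            intervals.append((lo, hi))
        lo = s1 + 1
    for (ilo, ihi), sv in zip(intervals, surf_vals):
        offset[ilo:ihi] = sv

    per_dive: list[tuple[int, float, float]] = []
    for k, (s0, s1) in enumerate(runs):
        pre = [sv for (ilo, ihi), sv in zip(intervals, surf_vals) if ihi == s0]
        post = [sv for (ilo, ihi), sv in zip(intervals, surf_vals) if ilo == s1 + 1]
        start_surf = pre[0] if pre else float(base[s0])
        end_surf = post[0] if post else float(base[s1])
        per_dive.append((k, start_surf, end_surf))
        idx = np.arange(s0, s1 + 1)
        if len(idx) > 1:
            frac = (t[idx] - t[s0]) / (t[s1] - t[s0])
        else:
            frac = np.zeros(1)
        offset[idx] = start_surf + frac * (end_surf - start_surf)

    corrected = series.with_(depth=d - offset, level=Level.ZOC)
    return ZocResult(
        corrected=corrected,
        window_offsets=window_offsets,
        per_dive_surfaces=per_dive,
        removed_samples=0,
        offset_per_sample=offset,
    )


def zero_offset_correct(series: TDRSeries, config: ZocConfig | None = None) -> ZocResult:
    """Full ZOC pipeline: despike → range trim → window offsets → refine."""
    config = config or ZocConfig()
    n0 = len(series)
    s = despike(series, config.spike_speed)
    s = trim_range(s, config.min_depth, config.max_depth)
    removed = n0 - len(s)
    offsets = window_surface_offsets(s, config)
    result = refine_dive_surfaces(s, offsets, config)
    result.removed_samples = removed
    return result


def refine_tolerance(depth_resolution: float, refine_multiplier: float = 15.0) -> float:
    """Per-dive surface acceptance tolerance in meters.

    The refined start/end surface of a dive must lie within this distance
    of the windowed surface estimate: ``refine_multiplier`` sensor counts
    (7.5 m for a 0.5 m-resolution instrument).
    """
    return refine_multiplier * depth_resolution
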