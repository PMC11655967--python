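"""Quality-control flags for tracks and dive records.

Flags run 1 (complete) to 5 (no data).  For tracks the rules combine the
average location rate over the data-collection period — departure to last
fix, so days after a dead tag don't count — with the largest gap between
fixes.  For dive records the rules combine sampling gaps with indications
of instrument malfunction found by scanning the dive statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import LocationFix, QCFlag, TDRSeries, as_seconds

log = logging.getLogger(__name__)

DAY = 86400.0


@dataclass
class QCThresholds:
    min_rate_per_day: float = 2.0  # locations/day for a usable track
    short_gap_days: float = 1.0  # flag-1 ceiling for track gaps
    long_gap_days: float = 2.0  # flag-2 ceiling ("up to 2 days", inclusive)
    short_dive_s: float = 60.0
    short_dive_fraction: float = 0.10  # minor-malfunction trigger
    repeat_depth_count: int = 20  # identical deep max-depths
    repeat_depth_min_m: float = 200.0
    spike_burst_factor: float = 10.0  # density jump over baseline
    substantial_severity: int = 2


def qc_track(
    fixes: list[LocationFix],
    trip_span: tuple[np.datetime64, np.datetime64 | None],
    thresholds: QCThresholds | None = None,
) -> QCFlag:
    """Track QC flag from location rate and largest gap.

    5 = no fixes; 4 = sparse (<2 locations/day on average); otherwise
    1 if no gap exceeds 24 h, 2 if the largest gap is ≤ 2 days,
    3 if any gap exceeds 2 consecutive days.
    """
    th = thresholds or QCThresholds()
    if len(fixes) == 0:
        return QCFlag(5, "no GPS or Argos locations")
    t = np.sort(as_seconds(np.array([f.timestamp for f in fixes], dtype="datetime64[s]")))
    departure = as_seconds(np.array([np.datetime64(trip_span[0], "s")]))[0]
    period_days = max((t[-1] - departure) / DAY, 1e-9)
    rate = len(fixes) / period_days
    if rate < th.min_rate_per_day:
        return QCFlag(4, f"sparse data: {rate:.2f} locations/day")
    max_gap_days = float(np.diff(t).max() / DAY) if len(t) > 1 else 0.0
    if max_gap_days <= th.short_gap_days:
        return QCFlag(1, "complete: no gaps > 24 h")
    if max_gap_days <= th.long_gap_days:
        return QCFlag(2, f"gap of {max_gap_days:.1f} days")
    return QCFlag(3, f"gap of {max_gap_days:.1f} days (> 2 days)")


@dataclass
class AnomalyReport:
    short_dive_fraction: float = 0.0
    repeated_depths: list[tuple[float, int]] = field(default_factory=list)
    spike_density_per_h: float = 0.0
    suggested_truncation: np.datetime64 | None = None
    severity: int = 0  # 0 none, 1 minor, 2 substantial
    notes: list[str] = field(default_factory=list)


def scan_dive_anomalies(
    stats: pd.DataFrame,
    series: TDRSeries,
    thresholds: QCThresholds | None = None,
    spike_speed: float = 5.0,
) -> AnomalyReport:
    """Scan dive statistics and the depth series for malfunction signatures.

    Looks for the patterns a reviewer would catch by eye: many extremely
    short dives, many deep dives to an identical depth (a saturated or
    stuck sensor), and bursts of depth spikes.  When spike density in a
    sliding 24-h window jumps more than ``spike_burst_factor`` times the
    baseline, the window start is suggested as a truncation time so the
    clean head of the record can be reprocessed.
    """
    th = thresholds or QCThresholds()
    rep = AnomalyReport()
    if len(stats):
        rep.short_dive_fraction = float((stats["duration"] < th.short_dive_s).mean())
        if rep.short_dive_fraction > th.short_dive_fraction:
            rep.severity = max(rep.severity, 1)
            rep.notes.append(
                f"{rep.short_dive_fraction:.0%} of dives shorter than {th.short_dive_s:g} s"
            )
        deep = stats.loc[stats["max_depth"] > th.repeat_depth_min_m, "max_depth"]
        counts = deep.round(6).value_counts()
        repeated = counts[counts > th.repeat_depth_count]
        rep.repeated_depths = [(float(v), int(c)) for v, c in repeated.items()]
        if rep.repeated_depths:
            rep.severity = max(rep.severity, 2)
            rep.notes.append(f"{len(rep.repeated_depths)} max-depth value(s) repeated")

    # spike density in sliding 24-h windows
    t = series.seconds
    if len(series) > 2:
        dt = np.diff(t)
        v = np.diff(series.depth) / np.maximum(dt, 1e-9)
        spike = (np.abs(v[:-1]) > spike_speed) & (np.abs(v[1:]) > spike_speed) & (
            np.sign(v[:-1]) != np.sign(v[1:])
        )
        spike_t = t[1:-1][spike]
        span_h = (t[-1] - t[0]) / 3600.0
        rep.spike_density_per_h = len(spike_t) / max(span_h, 1e-9)
        if len(spike_t) >= 5 and span_h > 48:
            edges = np.arange(t[0], t[-1], DAY)
            dens = np.array([np.sum((spike_t >= e) & (spike_t < e + DAY)) for e in edges]) / 24.0
            baseline = max(np.median(dens), 1.0 / 24.0)
            burst = np.where(dens > th.spike_burst_factor * baseline)[0]
            if burst.size:
                rep.suggested_truncation = np.datetime64(int(edges[burst[0]]), "s")
                rep.severity = max(rep.severity, 2)
                rep.notes.append("spike burst: truncation suggested")
    return rep


def qc_dive_record(
    series: TDRSeries | None,
    anomaly_report: AnomalyReport | None = None,
    thresholds: QCThresholds | None = None,
) -> QCFlag:
    """Dive-record QC flag from sampling gaps and the anomaly report.

    5 = no record; 4 = substantial malfunction; 3 = any gap over 2 days;
    2 = gaps up to 2 days or minor malfunction; 1 = complete and clean.
    A gap is an inter-sample interval exceeding twice the sampling
    interval.
    """
    th = thresholds or QCThresholds()
    if series is None or len(series) == 0:
        return QCFlag(5, "no dive records")
    severity = anomaly_report.severity if anomaly_report is not None else 0
    if severity >= th.substantial_severity:
        return QCFlag(4, "substantial indications of instrument failure")
    t = series.seconds
    gaps = np.diff(t)
    gap_mask = gaps > 2 * series.sampling_interval
    max_gap_days = float(gaps[gap_mask].max() / DAY) if gap_mask.any() else 0.0
    if max_gap_days > th.long_gap_days:
        return QCFlag(3, f"gap of {max_gap_days:.1f} days (> 2 days)")
    if gap_mask.any() or severity >= 1:
        why = "gaps up to 2 days" if gap_mask.any() else "minor malfunction indications"
        return QCFlag(2, why)
    return QCFlag(1, "complete, no gaps, no malfunction")
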