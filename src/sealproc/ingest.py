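"""Reading and harmonizing manufacturer TDR CSVs and location files.

Level 1 = the decoded record exactly as read; Level 2 = the curated record
(haulouts filled, clocks corrected, trimmed to the at-sea period).  All
timestamps are stored in UTC; the only local-time handling in the package
is the Little Leonardo clock correction, whose offset includes the shift
to UTC.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DeploymentMetadata,
    Level,
    LocationFix,
    Manufacturer,
    Source,
    TDRSeries,
    from_seconds,
    parse_toppid,  # noqa: F401  (re-exported: part of the ingest surface)
)

log = logging.getLogger(__name__)

# Column names accepted per manufacturer dialect (case-insensitive).
_DIALECT_COLUMNS = {
    Manufacturer.WC: (("Time", "Depth"), ("time", "depth")),
    Manufacturer.SMRU: (("Date", "Depth"), ("time", "depth")),
    Manufacturer.LL: (("Time", "Depth"), ("time", "depth")),
}


class TDRParseError(ValueError):
    """Raised when a TDR CSV cannot be parsed; carries the line number."""


def read_tdr_csv(
    path: str | Path,
    manufacturer: Manufacturer | str,
    sampling_interval: float,
    depth_resolution: float,
    instrument_id: str = "",
) -> TDRSeries:
    """Read a decoded TDR CSV into a Level 1 series.

    The file must have a header row and timestamp + depth columns.  SMRU
    exports may contain interleaved text lines flagging at-sea ``haulout``
    periods (the tag was dry at the surface); these lines are dropped and
    the resulting gaps are filled later by :func:`fill_smru_haulouts`.

    Rows are preserved verbatim (Level 1 is decoded, uncurated); a
    non-monotonic timestamp raises rather than being silently reordered.
    """
    manufacturer = Manufacturer(manufacturer)
    path = Path(path)
    times: list[np.datetime64] = []
    depths: list[float] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        cols = [c.strip().lower() for c in header.rstrip("\n").split(",")]
        try:
            t_idx = next(i for i, c in enumerate(cols) if c in ("time", "date", "datetime"))
            d_idx = next(i for i, c in enumerate(cols) if c == "depth")
        except StopIteration:
            raise TDRParseError(
                f"{path.name}: header must name a time and a depth column, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if manufacturer == Manufacturer.SMRU and "haulout" in line.lower():
                continue  # textual haulout marker, not a sample
            parts = line.split(",")
            try:
                t = np.datetime64(parts[t_idx].strip(), "s")
                d = float(parts[d_idx])
            except (ValueError, IndexError) as exc:
                raise TDRParseError(f"{path.name}:{lineno}: unparseable row: {line!r}") from exc
            if not np.isfinite(d):
                raise TDRParseError(f"{path.name}:{lineno}: non-finite depth")
            times.append(t)
            depths.append(d)
    series = TDRSeries(
        time=np.array(times, dtype="datetime64[s]"),
        depth=np.array(depths, dtype=float),
        sampling_interval=sampling_interval,
        depth_resolution=depth_resolution,
        manufacturer=manufacturer,
        instrument_id=instrument_id,
        level=Level.L1,
    )
    series.validate_monotonic()
    return series


def fill_smru_haulouts(series: TDRSeries) -> TDRSeries:
    """Fill at-sea haulout gaps in an SMRU record with zero depths.

    SMRU tags suspend depth logging while dry, leaving gaps in the series.
    Each gap is replaced by zero-depth samples on the tag's sampling grid,
    anchored at the gap start, so downstream steps see a consistent time
    series.  The record's total span is unchanged.
    """
    if series.manufacturer != Manufacturer.SMRU:
        raise ValueError("haulout filling applies to SMRU records only")
    if len(series) < 2:
        return series
    dt = series.sampling_interval
    t = series.seconds
    gaps = np.where(np.diff(t) > dt * 1.5)[0]
    if gaps.size == 0:
        return series
    t_parts = [t]
    d_parts = [series.depth]
    n_filled = 0
    for i in gaps:
        # interior grid points strictly between the bounding samples
        fill = np.arange(t[i] + dt, t[i + 1] - dt / 2, dt)
        residual = (t[i + 1] - t[i]) % dt
        if residual > 1e-9 and abs(residual - dt) > 1e-9:
            log.info(
                "haulout gap at %s not grid-aligned (residual %.1f s); "
                "filled on grid anchored at gap start",
                from_seconds(t[i]),
                residual,
            )
        t_parts.append(fill)
        d_parts.append(np.zeros_like(fill))
        n_filled += fill.size
    order = np.argsort(np.concatenate(t_parts), kind="stable")
    t_new = np.concatenate(t_parts)[order]
    d_new = np.concatenate(d_parts)[order]
    log.info("filled %d haulout samples across %d gaps", n_filled, gaps.size)
    return series.with_(time=from_seconds(t_new), depth=d_new)


def correct_ll_time(
    series: TDRSeries, offset_hours: float, compression_minutes: float
) -> TDRSeries:
    """Apply the Little Leonardo clock correction.

    LL tags start on a local-time clock and drift relative to the other
    instruments on the animal.  The correction is a shift of
    ``offset_hours`` (which includes local→UTC) followed by a linear
    rescaling of elapsed time so the record's end moves by
    ``compression_minutes`` while its start stays fixed (an affine map of
    elapsed time anchored at the first sample).
    """
    if series.manufacturer != Manufacturer.LL:
        raise ValueError("clock correction applies to Little Leonardo records only")
    t = series.seconds + offset_hours * 3600.0
    if len(t) > 1 and compression_minutes != 0.0:
        span = t[-1] - t[0]
        scale = (span + compression_minutes * 60.0) / span
        t = t[0] + (t - t[0]) * scale
    return series.with_(time=from_seconds(t))


def truncate_to_trip(series: TDRSeries, meta: DeploymentMetadata) -> TDRSeries:
    """Trim a record to the at-sea period (departure → arrival).

    Samples before the departure from the beach are removed; samples after
    the arrival (when known) are removed.  Short mid-trip shore visits are
    left as gaps — they are known only from metadata and are not inferred.
    """
    keep = series.time >= meta.departure
    if meta.arrival is not None:
        keep &= series.time <= meta.arrival
    if not keep.any():
        raise ValueError("no at-sea data: record does not overlap the trip span")
    out = series.with_(time=series.time[keep], depth=series.depth[keep], level=Level.L2)
    log.info("truncated %d -> %d samples", len(series), len(out))
    return out


def subsample_to_8s(series: TDRSeries) -> TDRSeries:
    """Subsample a high-frequency record to the common 8-s grid.

    Dive metrics are sensitive to sampling rate, so 1/2/4-s records are
    decimated (every ``8/interval``-th sample, starting at the first) to
    make derived metrics comparable across the data set.  5-s records
    (Little Leonardo) do not divide 8 s and are returned unchanged, as are
    records already at 8 s or coarser.
    """
    dt = series.sampling_interval
    if dt not in (1, 2, 4):
        log.info("sampling interval %s s not subsampled", dt)
        return series
    stride = int(round(8 / dt))
    return series.with_(
        time=series.time[::stride],
        depth=series.depth[::stride],
        sampling_interval=8.0,
    )


def merge_location_sources(
    argos: Sequence[LocationFix], gps: Sequence[LocationFix]
) -> list[LocationFix]:
    """Merge Argos and GPS fixes for a deployment into one time-sorted list.

    Class-Z fixes (failed Doppler convergence) are dropped, and exact
    duplicates — same source, timestamp and coordinates — are collapsed.
    """
    seen = set()
    merged: list[LocationFix] = []
    for f in list(argos) + list(gps):
        if f.quality_class == "Z":
            continue
        key = (f.source, f.timestamp.astype("int64"), round(f.lat, 6), round(f.lon, 6))
        if key in seen:
            continue
        seen.add(key)
        merged.append(f)
    merged.sort(key=lambda f: (f.timestamp.astype("int64"), f.source.value))
    return merged


def read_locations_csv(path: str | Path, source: Source | str = Source.ARGOS) -> list[LocationFix]:
    """Read a location CSV (timestamp, lat, lon, class, optional ellipse)."""
    source = Source(source)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    fixes = []
    for row in df.itertuples(index=False):
        fixes.append(
            LocationFix(
                timestamp=np.datetime64(str(getattr(row, "timestamp")), "s"),
                lat=float(row.lat),
                lon=float(row.lon),
                quality_class=str(getattr(row, "quality_class", getattr(row, "lc", "B"))),
                source=source,
                error_semi_major=_opt(row, "error_semi_major"),
                error_semi_minor=_opt(row, "error_semi_minor"),
                error_ellipse_orientation=_opt(row, "error_ellipse_orientation"),
            )
        )
    return fixes


def _opt(row, name: str) -> Optional[float]:
    v = getattr(row, name, None)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def read_metadata_csv(path: str | Path) -> list[DeploymentMetadata]:
    """Read deployment metadata, one CSV row per deployment."""
    df = pd.read_csv(path, dtype={"TOPPID": str})
    metas = []
    for row in df.itertuples(index=False):
        arrival = getattr(row, "Arrival", None)
        if arrival is not None and (pd.isna(arrival) or str(arrival) == ""):
            arrival = None
        metas.append(
            DeploymentMetadata(
                toppid=str(row.TOPPID),
                animal_id=str(row.AnimalID),
                colony=str(row.Colony),
                departure=np.datetime64(str(row.Departure), "s"),
                arrival=None if arrival is None else np.datetime64(str(arrival), "s"),
                trip=str(getattr(row, "Trip", "post-breeding")),
            )
        )
    return metas


def write_tdr_csv(series: TDRSeries, path: str | Path) -> None:
    """Write a series as a canonical two-column CSV (ISO-8601 time, depth)."""
    df = pd.DataFrame({"time": series.time.astype("datetime64[s]"), "depth": series.depth})
    df.to_csv(path, index=False)
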