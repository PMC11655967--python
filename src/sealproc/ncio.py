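"""netCDF-4 packaging: the two-file-per-deployment layout.

Each deployment yields ``<TOPPID>_TrackTDR_RawCurated.nc`` (Levels 1 & 2:
decoded and curated depth series and location fixes) and
``<TOPPID>_TrackTDR_Processed.nc`` (Level 3: the interpolated track and
per-TDR dive-statistics tables, with 8-s subsampled twins).  Data live in
netCDF-4 groups (RAW_TDR1, CLEAN_TDR1, RAW_LOCATIONS, …, TRACK, TDR1,
TDR1_8S); deployment metadata and QC flags are global attributes; units
are variable attributes.  Datetimes are stored as seconds since
1970-01-01 UTC.  See docs/netcdf_schema.md for the full inventory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import netCDF4
import numpy as np
import pandas as pd

from .dives import DIVESTAT_COLUMNS
from .types import (
    DeploymentBundle,
    DeploymentMetadata,
    Level,
    LocationFix,
    Manufacturer,
    QCFlag,
    Source,
    TDRSeries,
    as_seconds,
    from_seconds,
)

log = logging.getLogger(__name__)

FILL_INT = -9999
_TIME_UNITS = "seconds since 1970-01-01 00:00:00 UTC"


class SchemaError(ValueError):
    """A file does not conform to the two-file deployment schema."""


def order_tdrs(qc_flags: list[QCFlag], manufacturers: list[Manufacturer]) -> list[int]:
    """Priority order of TDR records: best quality first, ties favor WC.

    The best available record is always published as TDR1; among records
    of equal quality, Wildlife Computers tags take priority.
    """
    idx = list(range(len(qc_flags)))
    return sorted(
        idx,
        key=lambda i: (
            qc_flags[i].value,
            0 if Manufacturer(manufacturers[i]) == Manufacturer.WC else 1,
            i,
        ),
    )


def _write_series(grp, series: TDRSeries) -> None:
    grp.createDimension("obs", len(series))
    v = grp.createVariable("DATE", "f8", ("obs",))
    v.units = _TIME_UNITS
    v[:] = as_seconds(series.time)
    v = grp.createVariable("DEPTH", "f8", ("obs",))
    v.units = "meters"
    v.positive = "down"
    v[:] = series.depth
    grp.sampling_interval = float(series.sampling_interval)
    grp.depth_resolution = float(series.depth_resolution)
    grp.manufacturer = series.manufacturer.value
    grp.instrument_id = series.instrument_id


def _read_series(grp, level: Level) -> TDRSeries:
    return TDRSeries(
        time=from_seconds(grp["DATE"][:].filled(np.nan)),
        depth=np.asarray(grp["DEPTH"][:].filled(np.nan)),
        sampling_interval=float(grp.sampling_interval),
        depth_resolution=float(grp.depth_resolution),
        manufacturer=Manufacturer(grp.manufacturer),
        instrument_id=str(grp.instrument_id),
        level=level,
    )


def _write_fixes(grp, fixes: list[LocationFix]) -> None:
    n = len(fixes)
    grp.createDimension("obs", n)
    v = grp.createVariable("DATE", "f8", ("obs",))
    v.units = _TIME_UNITS
    v[:] = as_seconds(np.array([f.timestamp for f in fixes], dtype="datetime64[s]"))
    for name, units, vals in (
        ("LAT", "degrees_north", [f.lat for f in fixes]),
        ("LON", "degrees_east", [f.lon for f in fixes]),
    ):
        v = grp.createVariable(name, "f8", ("obs",))
        v.units = units
        v[:] = np.asarray(vals)
    v = grp.createVariable("LC", str, ("obs",))
    v.long_name = "location quality class"
    for i, f in enumerate(fixes):
        v[i] = f.quality_class
    v = grp.createVariable("SOURCE", str, ("obs",))
    for i, f in enumerate(fixes):
        v[i] = f.source.value
    v = grp.createVariable("ERROR_SEMI_MAJOR", "f8", ("obs",))
    v.units = "meters"
    v[:] = np.array(
        [np.nan if f.error_semi_major is None else f.error_semi_major for f in fixes]
    )


def _read_fixes(grp) -> list[LocationFix]:
    t = from_seconds(grp["DATE"][:].filled(np.nan))
    lat = grp["LAT"][:].filled(np.nan)
    lon = grp["LON"][:].filled(np.nan)
    lc = grp["LC"][:]
    src = grp["SOURCE"][:]
    sm = grp["ERROR_SEMI_MAJOR"][:].filled(np.nan)
    return [
        LocationFix(
            timestamp=t[i], lat=float(lat[i]), lon=float(lon[i]),
            quality_class=str(lc[i]), source=Source(str(src[i])),
            error_semi_major=None if np.isnan(sm[i]) else float(sm[i]),
        )
        for i in range(len(t))
    ]


def _meta_attrs(ds, bundle: DeploymentBundle) -> None:
    m = bundle.meta
    ds.TOPPID = m.toppid
    ds.Animal_ID = m.animal_id
    ds.All_TOPPIDs = ",".join(m.all_toppids_for_animal)
    ds.Colony = m.colony
    ds.Colony_Lat = float(m.colony_lat)
    ds.Colony_Lon = float(m.colony_lon)
    ds.Departure = str(np.datetime64(m.departure, "s"))
    ds.Arrival = "" if m.arrival is None else str(np.datetime64(m.arrival, "s"))
    ds.Trip = m.trip
    if bundle.qc_track is not None:
        ds.QC_Track = int(bundle.qc_track.value)
        ds.QC_Track_Comment = bundle.qc_track.rationale
    for i, flag in enumerate(bundle.qc_tdr, start=1):
        setattr(ds, f"QC_TDR{i}", int(flag.value))
        setattr(ds, f"QC_TDR{i}_Comment", flag.rationale)


def _meta_from_attrs(ds) -> DeploymentMetadata:
    arrival = str(getattr(ds, "Arrival", ""))
    return DeploymentMetadata(
        toppid=str(ds.TOPPID),
        animal_id=str(ds.Animal_ID),
        colony=str(ds.Colony),
        colony_lat=float(ds.Colony_Lat),
        colony_lon=float(ds.Colony_Lon),
        departure=np.datetime64(str(ds.Departure), "s"),
        arrival=None if arrival == "" else np.datetime64(arrival, "s"),
        trip=str(ds.Trip),
        all_toppids_for_animal=str(ds.All_TOPPIDs).split(","),
    )


def write_rawcurated(bundle: DeploymentBundle, out_dir) -> Path:
    """Write the Levels 1 & 2 file (`<TOPPID>_TrackTDR_RawCurated.nc`).

    For a record flagged quality 4 the raw (Level 1) data are included but
    no curated group is written.
    """
    if not bundle.meta.toppid:
        raise ValueError("bundle has no TOPPID")
    path = Path(out_dir) / f"{bundle.meta.toppid}_TrackTDR_RawCurated.nc"
    with netCDF4.Dataset(path, "w", format="NETCDF4") as ds:
        _meta_attrs(ds, bundle)
        for i, series in enumerate(bundle.raw_tdr, start=1):
            _write_series(ds.createGroup(f"RAW_TDR{i}"), series)
        for i, series in enumerate(bundle.clean_tdr, start=1):
            if series is None:
                continue
            flag = bundle.qc_tdr[i - 1] if i - 1 < len(bundle.qc_tdr) else None
            if flag is not None and flag.value >= 4:
                continue  # questionable data: raw only, no processing
            _write_series(ds.createGroup(f"CLEAN_TDR{i}"), series)
        if bundle.raw_locs:
            _write_fixes(ds.createGroup("RAW_LOCATIONS"), bundle.raw_locs)
        if bundle.curated_locs:
            _write_fixes(ds.createGroup("CURATED_LOCATIONS"), bundle.curated_locs)
    return path


def _write_divestats(grp, stats: pd.DataFrame) -> None:
    grp.createDimension("dive", len(stats))
    for col in DIVESTAT_COLUMNS:
        name = col.upper().replace("POST_DIVE_INTERVAL", "PDI")
        if col in ("start", "end"):
            v = grp.createVariable(name, "f8", ("dive",))
            v.units = _TIME_UNITS
            v[:] = as_seconds(stats[col].to_numpy("datetime64[s]"))
        elif col in ("dive_number", "wiggles"):
            v = grp.createVariable(name, "i8", ("dive",), fill_value=FILL_INT)
            v[:] = stats[col].to_numpy(np.int64)
        else:
            v = grp.createVariable(name, "f8", ("dive",))
            v[:] = stats[col].to_numpy(float)
    # convenience alias used for mapping dive locations
    v = grp.createVariable("MAXDEPTH", "f8", ("dive",))
    v.units = "meters"
    v[:] = stats["max_depth"].to_numpy(float)
    v = grp.createVariable("DATE", "f8", ("dive",))
    v.units = _TIME_UNITS
    v[:] = as_seconds(stats["start"].to_numpy("datetime64[s]"))


def _read_divestats(grp) -> pd.DataFrame:
    out = {}
    for col in DIVESTAT_COLUMNS:
        name = col.upper().replace("POST_DIVE_INTERVAL", "PDI")
        arr = grp[name][:]
        arr = arr.filled(np.nan) if np.ma.isMaskedArray(arr) else arr
        if col in ("start", "end"):
            out[col] = from_seconds(arr)
        elif col in ("dive_number", "wiggles"):
            out[col] = np.asarray(arr, np.int64)
        else:
            out[col] = np.asarray(arr, float)
    return pd.DataFrame(out)


def write_processed(bundle: DeploymentBundle, out_dir) -> Path:
    """Write the Level 3 file (`<TOPPID>_TrackTDR_Processed.nc`).

    The interpolated track goes in group TRACK (DATE, LAT, LON, LAT_SE,
    LON_SE); each dive-statistics table goes in TDRn with an 8-s
    subsampled twin in TDRn_8S when available.
    """
    if bundle.track is None and not bundle.dive_stats:
        raise ValueError("no Level 3 products: need a track or dive statistics")
    path = Path(out_dir) / f"{bundle.meta.toppid}_TrackTDR_Processed.nc"
    with netCDF4.Dataset(path, "w", format="NETCDF4") as ds:
        _meta_attrs(ds, bundle)
        if bundle.track is not None:
            grp = ds.createGroup("TRACK")
            grp.createDimension("obs", len(bundle.track))
            v = grp.createVariable("DATE", "f8", ("obs",))
            v.units = _TIME_UNITS
            v[:] = as_seconds(bundle.track["timestamp"].to_numpy("datetime64[s]"))
            for name, col, units in (
                ("LAT", "lat", "degrees_north"),
                ("LON", "lon", "degrees_east"),
                ("LAT_SE", "se_lat", "meters"),
                ("LON_SE", "se_lon", "meters"),
            ):
                v = grp.createVariable(name, "f8", ("obs",))
                v.units = units
                v[:] = bundle.track[col].to_numpy(float)
        for i, stats in enumerate(bundle.dive_stats, start=1):
            if stats is None:
                continue
            _write_divestats(ds.createGroup(f"TDR{i}"), stats)
            if i - 1 < len(bundle.dive_stats_8s) and bundle.dive_stats_8s[i - 1] is not None:
                _write_divestats(ds.createGroup(f"TDR{i}_8S"), bundle.dive_stats_8s[i - 1])
    return path


def read_bundle(path) -> DeploymentBundle:
    """Read either deployment file back into a (partial) bundle.

    The inverse of the writers for all numeric arrays and attributes; a
    missing mandatory group or DATE variable raises :class:`SchemaError`
    naming the offender.
    """
    path = Path(path)
    with netCDF4.Dataset(path, "r") as ds:
        meta = _meta_from_attrs(ds)
        bundle = DeploymentBundle(meta=meta)
        if hasattr(ds, "QC_Track"):
            bundle.qc_track = QCFlag(int(ds.QC_Track), str(getattr(ds, "QC_Track_Comment", "")))
        i = 1
        while hasattr(ds, f"QC_TDR{i}"):
            bundle.qc_tdr.append(
                QCFlag(int(getattr(ds, f"QC_TDR{i}")), str(getattr(ds, f"QC_TDR{i}_Comment", "")))
            )
            i += 1
        groups = ds.groups
        for g in groups.values():
            if "DATE" not in g.variables and not g.name.startswith("CLEAN"):
                raise SchemaError(f"group {g.name} lacks DATE")
        is_processed = path.name.endswith("_Processed.nc")
        if is_processed:
            if "TRACK" not in groups and not any(n.startswith("TDR") for n in groups):
                raise SchemaError("TRACK")
            if "TRACK" in groups:
                g = groups["TRACK"]
                bundle.track = pd.DataFrame(
                    {
                        "timestamp": from_seconds(g["DATE"][:].filled(np.nan)),
                        "lat": g["LAT"][:].filled(np.nan),
                        "lon": g["LON"][:].filled(np.nan),
                        "se_lat": g["LAT_SE"][:].filled(np.nan),
                        "se_lon": g["LON_SE"][:].filled(np.nan),
                    }
                )
            i = 1
            while f"TDR{i}" in groups:
                bundle.dive_stats.append(_read_divestats(groups[f"TDR{i}"]))
                bundle.dive_stats_8s.append(
                    _read_divestats(groups[f"TDR{i}_8S"]) if f"TDR{i}_8S" in groups else None
                )
                i += 1
        else:
            i = 1
            while f"RAW_TDR{i}" in groups:
                bundle.raw_tdr.append(_read_series(groups[f"RAW_TDR{i}"], Level.L1))
                i += 1
            i = 1
            while f"CLEAN_TDR{i}" in groups:
                bundle.clean_tdr.append(_read_series(groups[f"CLEAN_TDR{i}"], Level.L2))
                i += 1
            if "RAW_LOCATIONS" in groups:
                bundle.raw_locs = _read_fixes(groups["RAW_LOCATIONS"])
            if "CURATED_LOCATIONS" in groups:
                bundle.curated_locs = _read_fixes(groups["CURATED_LOCATIONS"])
    return bundle
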