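"""Assigning a location and solar elevation to the start of each dive.

Dives are geolocated by linear interpolation along the 3-hourly modeled
track: for each dive start the bracketing pair of predicted locations is
found and latitude, longitude and their standard errors are interpolated
in time with a common weight.  Dives outside the track's time span are
clamped to the nearest endpoint and flagged as extrapolated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .solar import solar_elevation
from .types import as_seconds

log = logging.getLogger(__name__)


def geolocate_dives(stats: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Fill lat/lon/SE/solar-elevation columns of a dive table from a track.

    ``track`` must have columns timestamp, lat, lon, se_lat, se_lon and be
    time-sorted.  Interpolation is performed directly in degrees (adequate
    at 3-h spacing); longitudes are unwrapped across the ±180° meridian
    before interpolating.  An ``extrapolated`` column marks dives clamped
    to the first or last track point.
    """
    out = stats.copy()
    if track is None or len(track) == 0:
        log.warning("empty track: dive locations left unfilled")
        out["extrapolated"] = False
        return out

    tt = as_seconds(track["timestamp"].to_numpy("datetime64[s]"))
    lat = track["lat"].to_numpy(float)
    lon = np.rad2deg(np.unwrap(np.deg2rad(track["lon"].to_numpy(float))))
    se_lat = track["se_lat"].to_numpy(float)
    se_lon = track["se_lon"].to_numpy(float)

    td = as_seconds(out["start"].to_numpy("datetime64[s]"))
    clamped = (td < tt[0]) | (td > tt[-1])
    tq = np.clip(td, tt[0], tt[-1])

    out["lat"] = np.interp(tq, tt, lat)
    ilon = np.interp(tq, tt, lon)
    out["lon"] = np.mod(ilon + 180.0, 360.0) - 180.0
    out["lat_se"] = np.interp(tq, tt, se_lat)
    out["lon_se"] = np.interp(tq, tt, se_lon)
    out["extrapolated"] = clamped
    if clamped.any():
        log.info("%d dives outside track span clamped to endpoints", clamped.sum())

    out["solar_elevation"] = [
        solar_elevation(ts, la, lo).elevation
        for ts, la, lo in zip(out["start"], out["lat"], out["lon"])
    ]
    return out
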