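"""Topocentric solar position from a low-precision analytic ephemeris.

Implements the standard Keplerian solar-position computation (mean
longitude and anomaly of the Sun, eccentric-anomaly correction, ecliptic
obliquity, right ascension/declination, local hour angle → horizontal
coordinates).  Accuracy is a few hundredths of a degree over recent
decades, ample for tagging dives as day/twilight/night.  No atmospheric
refraction correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import as_seconds

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class SolarPosition:
    elevation: float  # degrees above horizon, [-90, 90]
    azimuth: float  # degrees clockwise from north, [0, 360)


def julian_date(timestamp) -> float:
    """Julian date (UTC) of a datetime64."""
    sec = float(as_seconds(np.array([np.datetime64(timestamp, "s")]))[0])
    return sec / 86400.0 + 2440587.5


def solar_elevation(timestamp, lat: float, lon: float) -> SolarPosition:
    """Solar elevation and azimuth at a UTC instant and position.

    Parameters
    ----------
    timestamp : datetime64-like, UTC
    lat, lon : degrees (north / east positive)
    """
    jd = julian_date(timestamp)
    d = jd - 2451543.5  # days since 1999-12-31 00:00 (epoch of the series)

    w = 282.9404 + 4.70935e-5 * d  # longitude of perihelion, deg
    e = 0.016709 - 1.151e-9 * d  # eccentricity
    M = np.mod(356.0470 + 0.9856002585 * d, 360.0)  # mean anomaly, deg
    L = w + M  # Sun's mean longitude
    oblecl = 23.4393 - 3.563e-7 * d  # obliquity of the ecliptic

    # eccentric anomaly (first-order Kepler correction), then true position
    E = M + (180.0 / np.pi) * e * np.sin(M * _DEG) * (1 + e * np.cos(M * _DEG))
    x = np.cos(E * _DEG) - e
    y = np.sin(E * _DEG) * np.sqrt(1 - e * e)
    v = np.arctan2(y, x) / _DEG  # true anomaly
    sun_lon = v + w  # ecliptic longitude of the Sun

    # ecliptic → equatorial
    xe = np.cos(sun_lon * _DEG)
    ye = np.sin(sun_lon * _DEG) * np.cos(oblecl * _DEG)
    ze = np.sin(sun_lon * _DEG) * np.sin(oblecl * _DEG)
    ra = np.arctan2(ye, xe) / _DEG  # right ascension, deg
    dec = np.arcsin(ze)  # declination, rad

    # local sidereal time (hours): mean-longitude approximation + UT + lon
    ut_hours = np.mod(jd + 0.5, 1.0) * 24.0
    gmst0 = np.mod(L + 180.0, 360.0) / 15.0
    lst = gmst0 + ut_hours + lon / 15.0
    ha = np.mod(lst * 15.0 - ra, 360.0)  # hour angle, deg
    ha_r = ha * _DEG
    lat_r = lat * _DEG

    sin_el = np.sin(lat_r) * np.sin(dec) + np.cos(lat_r) * np.cos(dec) * np.cos(ha_r)
    el = np.arcsin(np.clip(sin_el, -1, 1))
    az = np.arctan2(
        -np.sin(ha_r) * np.cos(dec),
        np.sin(dec) * np.cos(lat_r) - np.cos(dec) * np.sin(lat_r) * np.cos(ha_r),
    )
    return SolarPosition(
        elevation=float(el / _DEG),
        azimuth=float(np.mod(az / _DEG, 360.0)),
    )
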