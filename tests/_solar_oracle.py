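"""Independent solar-position oracle (NOAA solar-calculator formulation).

Deliberately a different derivation from the package's ephemeris: Julian
centuries, the NOAA geometric-mean-longitude/equation-of-center series,
nutation-corrected obliquity, and the equation of time.  Used only to
cross-check the package's solar elevations.
"""

from __future__ import annotations

import math

import numpy as np

from sealproc.types import as_seconds

R = math.pi / 180.0


def noaa_solar_elevation(timestamp, lat: float, lon: float) -> float:
    """Solar elevation (degrees, no refraction) per the NOAA calculator."""
    sec = float(as_seconds(np.array([np.datetime64(timestamp, "s")]))[0])
    jd = sec / 86400.0 + 2440587.5
    T = (jd - 2451545.0) / 36525.0

    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        math.sin(M * R) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * M * R) * (0.019993 - 0.000101 * T)
        + math.sin(3 * M * R) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega * R)

    seconds = 21.448 - T * (46.8150 + T * (0.00059 - T * 0.001813))
    e0 = 23.0 + (26.0 + seconds / 60.0) / 60.0
    eps = e0 + 0.00256 * math.cos(omega * R)  # corrected obliquity

    decl = math.asin(math.sin(eps * R) * math.sin(app_long * R))

    y = math.tan(eps * R / 2.0) ** 2
    eq_time = 4.0 / R * (
        y * math.sin(2 * L0 * R)
        - 2 * e * math.sin(M * R)
        + 4 * e * y * math.sin(M * R) * math.cos(2 * L0 * R)
        - 0.5 * y * y * math.sin(4 * L0 * R)
        - 1.25 * e * e * math.sin(2 * M * R)
    )  # minutes

    minutes_utc = (sec % 86400.0) / 60.0
    true_solar_min = (minutes_utc + eq_time + 4.0 * lon) % 1440.0
    ha = true_solar_min / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0

    cos_zen = math.sin(lat * R) * math.sin(decl) + math.cos(lat * R) * math.cos(
        decl
    ) * math.cos(ha * R)
    cos_zen = max(-1.0, min(1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))
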