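"""Track curation and continuous-time correlated-random-walk interpolation.

Raw Argos/GPS fixes are curated (colony anchors, land removal, speed
filter) and then fed to a continuous-time correlated random walk (CTCRW):
per axis the velocity is an Ornstein–Uhlenbeck process with decay ``beta``
and noise scale ``sigma``, and position is its integral.  The state-space
form admits an exact discretization, so maximum-likelihood estimation of
(beta, sigma) runs through a Kalman filter and interpolated positions with
standard errors come from the Rauch–Tung–Striebel smoother evaluated on a
regular (default 3-hourly) grid.

Positions are filtered in a local azimuthal-equidistant plane centered on
the track centroid, which keeps distortion bounded at ocean-basin scale,
and results are inverse-projected to latitude/longitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .types import DeploymentMetadata, LocationFix, Source, as_seconds, from_seconds

log = logging.getLogger(__name__)

EARTH_RADIUS = 6371008.8  # meters


@dataclass
class TrackConfig:
    """Curation and interpolation settings.

    ``class_error_sd`` maps each Argos quality class to a one-axis
    measurement SD in meters, taken from the nominal class error radii
    (3: <250 m, 2: 250–500 m, 1: 500–1500 m, 0/A/B: unbounded) with
    class G (GPS-grade, ~50 m accuracy) much tighter.
    """

    predict_interval: float = 10800.0  # seconds (3 h)
    max_speed: float = 3.0  # m/s
    end_anchor_window: float = 5.0  # days
    colony_buffer_km: float = 5.0
    class_error_sd: dict = field(
        default_factory=lambda: {
            "3": 250.0, "2": 500.0, "1": 1500.0,
            "0": 5000.0, "A": 5000.0, "B": 10000.0, "G": 50.0,
        }
    )

    def __post_init__(self) -> None:
        if self.predict_interval <= 0 or self.max_speed <= 0:
            raise ValueError("predict_interval and max_speed must be positive")
        if any(sd <= 0 for sd in self.class_error_sd.values()):
            raise ValueError("measurement SDs must be positive")


@dataclass
class CtcrwParams:
    beta: float  # 1/s, velocity autocorrelation decay
    sigma: float  # m/s^(3/2), velocity process noise scale
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.sigma <= 0:
            raise ValueError("beta and sigma must be positive")


class FitError(RuntimeError):
    """CTCRW fit failure; carries the last parameter iterate."""

    def __init__(self, message: str, last: tuple[float, float] | None = None):
        super().__init__(message)
        self.last = last


# ---------------------------------------------------------------------------
# curation


def add_colony_anchors(
    fixes: list[LocationFix],
    meta: DeploymentMetadata,
    config: TrackConfig | None = None,
) -> list[LocationFix]:
    """Prepend a departure anchor at the colony; append an arrival anchor.

    The start anchor (colony coordinates, departure time, class G) is
    always added.  The end anchor is added only when the arrival time is
    known and the last fix lies within ``end_anchor_window`` days of it —
    otherwise the track ends at sea, avoiding interpolation across a long
    unobserved span after tag failure.
    """
    config = config or TrackConfig()
    start = LocationFix(
        timestamp=meta.departure,
        lat=meta.colony_lat,
        lon=meta.colony_lon,
        quality_class="G",
        source=Source.ANCHOR,
    )
    out = [start] + [f for f in fixes]
    if meta.arrival is not None:
        last_t = max((f.timestamp for f in fixes), default=None)
        gap_days = (
            0.0
            if last_t is None  # no fixes at all: track is just the endpoints
            else (meta.arrival - last_t) / np.timedelta64(1, "s") / 86400.0
        )
        if gap_days <= config.end_anchor_window:
            out.append(
                LocationFix(
                    timestamp=meta.arrival,
                    lat=meta.colony_lat,
                    lon=meta.colony_lon,
                    quality_class="G",
                    source=Source.ANCHOR,
                )
            )
    out.sort(key=lambda f: f.timestamp.astype("int64"))
    return out


def remove_land_fixes(
    fixes: list[LocationFix],
    bathymetry,
    colony: tuple[float, float] | None = None,
    colony_buffer_km: float = 5.0,
) -> list[LocationFix]:
    """Drop fixes that fall on land according to a bathymetry grid.

    ``bathymetry`` is any object with 1-D ``lat``/``lon`` arrays and a 2-D
    ``elevation`` array (positive up, meters, shape lat × lon).  Fixes in
    cells with elevation ≥ 0 are removed — except colony anchors and fixes
    within ``colony_buffer_km`` of the colony, which sit on land by
    construction.  Fixes outside the grid are kept and logged.
    """
    lat_g = np.asarray(bathymetry.lat, float)
    lon_g = np.asarray(bathymetry.lon, float)
    elev = np.asarray(bathymetry.elevation, float)
    out = []
    n_removed = 0
    for f in fixes:
        if f.source == Source.ANCHOR:
            out.append(f)
            continue
        if colony is not None:
            if great_circle_m(f.lat, f.lon, colony[0], colony[1]) <= colony_buffer_km * 1000:
                out.append(f)
                continue
        if not (lat_g.min() <= f.lat <= lat_g.max() and lon_g.min() <= f.lon <= lon_g.max()):
            log.info("fix at (%g, %g) outside bathymetry grid; kept", f.lat, f.lon)
            out.append(f)
            continue
        i = int(np.argmin(np.abs(lat_g - f.lat)))
        j = int(np.argmin(np.abs(lon_g - f.lon)))
        if elev[i, j] >= 0:
            n_removed += 1
        else:
            out.append(f)
    if n_removed:
        log.info("removed %d on-land fixes", n_removed)
    return out


def great_circle_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in meters (haversine)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS * np.arcsin(np.sqrt(a)))


def _speeds(t: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Segment speeds (m/s), vectorized haversine; zero-dt segments → inf."""
    p = np.deg2rad(lat)
    dphi = np.diff(p)
    dlmb = np.deg2rad(np.diff(lon))
    a = np.sin(dphi / 2) ** 2 + np.cos(p[:-1]) * np.cos(p[1:]) * np.sin(dlmb / 2) ** 2
    dist = 2 * EARTH_RADIUS * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt > 0, dist / np.where(dt > 0, dt, 1.0), np.inf)
    return v


def speed_filter(fixes: list[LocationFix], max_speed: float = 3.0) -> list[LocationFix]:
    """Remove fixes implying over-speed travel (default 3 m/s).

    Iterative worst-offender removal: while any segment speed exceeds the
    bound, remove the non-anchor fix whose removal most reduces the number
    of violating segments (evaluated locally: dropping fix *i* replaces
    its two adjacent segments with one bridging segment).  Ties go to the
    fix adjacent to the fastest segment.  Segments at exactly the bound
    are kept; anchors are immune.
    """
    fixes = list(fixes)
    while True:
        n = len(fixes)
        t = np.array([f.timestamp.astype("int64") for f in fixes], float)
        lat = np.array([f.lat for f in fixes])
        lon = np.array([f.lon for f in fixes])
        anchor = np.array([f.source == Source.ANCHOR for f in fixes])
        if n < 2:
            return fixes
        v = _speeds(t, lat, lon)
        viol = v > max_speed
        # violations not repairable (both endpoints anchors) don't count
        repairable = viol & ~(anchor[:-1] & anchor[1:])
        if not repairable.any():
            return fixes
        candidates = np.flatnonzero(~anchor)
        if candidates.size == 0:
            return fixes
        worst_seg = int(np.argmax(np.where(repairable, v, -np.inf)))
        best_i, best_key = None, None
        for i in candidates:
            removed = (viol[i - 1] if i > 0 else 0) + (viol[i] if i < n - 1 else 0)
            if removed == 0:
                continue
            added = 0
            if 0 < i < n - 1:
                bridge = _speeds(t[[i - 1, i + 1]], lat[[i - 1, i + 1]], lon[[i - 1, i + 1]])[0]
                added = int(bridge > max_speed)
            delta = removed - added
            adjacency = max(v[i - 1] if i > 0 else 0.0, v[i] if i < n - 1 else 0.0)
            key = (delta, 1 if i in (worst_seg, worst_seg + 1) else 0, adjacency, -i)
            if best_key is None or key > best_key:
                best_i, best_key = int(i), key
        if best_i is None:
            # every violation is adjacent only to anchors; nothing to do
            return fixes
        del fixes[best_i]
        if not any(f.source != Source.ANCHOR for f in fixes):
            raise ValueError("speed filter removed every non-anchor fix")


# ---------------------------------------------------------------------------
# local planar projection (azimuthal equidistant, spherical)


@dataclass
class LocalProjection:
    lat0: float
    lon0: float

    def forward(self, lat, lon):
        """Degrees → meters (x east, y north)."""
        phi0, lam0 = np.deg2rad(self.lat0), np.deg2rad(self.lon0)
        phi, lam = np.deg2rad(np.asarray(lat, float)), np.deg2rad(np.asarray(lon, float))
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        cos_c = np.clip(cos_c, -1, 1)
        c = np.arccos(cos_c)
        k = np.where(c > 1e-12, c / np.maximum(np.sin(c), 1e-300), 1.0)
        x = EARTH_RADIUS * k * np.cos(phi) * np.sin(lam - lam0)
        y = EARTH_RADIUS * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
        )
        return x, y

    def inverse(self, x, y):
        """Meters → degrees."""
        phi0, lam0 = np.deg2rad(self.lat0), np.deg2rad(self.lon0)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS
        small = rho < 1e-9
        rho_safe = np.where(small, 1.0, rho)
        phi = np.arcsin(
            np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / rho_safe
        )
        lam = lam0 + np.arctan2(
            x * np.sin(c),
            rho_safe * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
        )
        phi = np.where(small, phi0, phi)
        lam = np.where(small, lam0, lam)
        return np.rad2deg(phi), np.rad2deg(np.mod(lam + np.pi, 2 * np.pi) - np.pi)


# ---------------------------------------------------------------------------
# CTCRW state space


def ctcrw_matrices(beta: float, sigma: float, dt: np.ndarray):
    """Exact transition (F) and process-noise (Q) matrices per step.

    State per axis is (position, velocity); velocity is OU with decay
    ``beta`` and infinitesimal SD ``sigma``, position its integral.
    """
    dt = np.asarray(dt, float)
    e = np.exp(-beta * dt)
    F = np.zeros(dt.shape + (2, 2))
    F[..., 0, 0] = 1.0
    F[..., 0, 1] = (1 - e) / beta
    F[..., 1, 1] = e
    s2 = sigma**2
    q11 = (s2 / beta**2) * (dt - 2 * (1 - e) / beta + (1 - e**2) / (2 * beta))
    q12 = (s2 / (2 * beta**2)) * (1 - 2 * e + e**2)
    q22 = s2 * (1 - e**2) / (2 * beta)
    Q = np.zeros(dt.shape + (2, 2))
    Q[..., 0, 0] = q11
    Q[..., 0, 1] = Q[..., 1, 0] = q12
    Q[..., 1, 1] = q22
    return F, Q


def _kalman(beta, sigma, t, z, r2, predict_t=None, smooth=False):
    """Kalman filter (and optional RTS smoother) for one axis.

    t : observation times (s); z : observed positions (m); r2 : measurement
    variances.  If ``predict_t`` is given, times are merged and entries
    without observations are treated as missing.  Returns loglik and,
    when smoothing, the smoothed mean/variance at ``predict_t``.
    """
    if predict_t is not None:
        all_t = np.concatenate([t, predict_t])
        obs_idx = np.concatenate([np.ones(len(t), bool), np.zeros(len(predict_t), bool)])
        order = np.argsort(all_t, kind="stable")
        all_t = all_t[order]
        obs_idx = obs_idx[order]
        z_all = np.full(len(all_t), np.nan)
        r_all = np.full(len(all_t), np.nan)
        z_all[obs_idx] = z[np.argsort(t, kind="stable")]
        r_all[obs_idx] = r2[np.argsort(t, kind="stable")]
    else:
        all_t, z_all, r_all = t, z, r2
        obs_idx = np.ones(len(t), bool)

    n = len(all_t)
    dt = np.diff(all_t)
    F, Q = ctcrw_matrices(beta, sigma, dt)
    H = np.array([1.0, 0.0])

    # diffuse-ish prior: first observation anchors position, vague velocity
    first_obs = np.argmax(obs_idx)
    m = np.array([z_all[first_obs], 0.0])
    P = np.diag([max(r_all[first_obs], 1.0), (2.0) ** 2])  # 2 m/s velocity prior SD

    loglik = 0.0
    ms = np.zeros((n, 2))
    Ps = np.zeros((n, 2, 2))
    mp = np.zeros((n, 2))
    Pp = np.zeros((n, 2, 2))
    for k in range(n):
        if k > 0:
            m = F[k - 1] @ m
            P = F[k - 1] @ P @ F[k - 1].T + Q[k - 1]
        mp[k] = m
        Pp[k] = P
        if obs_idx[k] and k != first_obs:
            S = P[0, 0] + r_all[k]
            resid = z_all[k] - m[0]
            loglik += -0.5 * (np.log(2 * np.pi * S) + resid**2 / S)
            K = P @ H / S
            m = m + K * resid
            P = P - np.outer(K, H @ P)
            P = 0.5 * (P + P.T)
        ms[k] = m
        Ps[k] = P

    if not smooth:
        return loglik, None, None

    # RTS smoother
    sm = ms.copy()
    sP = Ps.copy()
    for k in range(n - 2, -1, -1):
        Ppk = Pp[k + 1]
        G = Ps[k] @ F[k].T @ np.linalg.inv(Ppk)
        sm[k] = ms[k] + G @ (sm[k + 1] - mp[k + 1])
        sP[k] = Ps[k] + G @ (sP[k + 1] - Ppk) @ G.T
    if predict_t is not None:
        sel = ~obs_idx
        return loglik, sm[sel], sP[sel]
    return loglik, sm, sP


def _fixes_xyr(fixes: list[LocationFix], config: TrackConfig, proj: LocalProjection):
    t = as_seconds(np.array([f.timestamp for f in fixes], dtype="datetime64[s]"))
    lat = np.array([f.lat for f in fixes])
    lon = np.array([f.lon for f in fixes])
    x, y = proj.forward(lat, lon)
    sd = np.array(
        [
            f.error_semi_major
            if f.error_semi_major is not None
            else config.class_error_sd[f.quality_class]
            for f in fixes
        ]
    )
    return t, x, y, sd**2


def fit_ctcrw(fixes: list[LocationFix], config: TrackConfig | None = None) -> CtcrwParams:
    """Maximum-likelihood (beta, sigma) for the CTCRW over a fix sequence.

    Both axes share the parameters; the likelihood is the sum of the two
    axis Kalman-filter likelihoods.  Optimization runs Nelder–Mead in
    log-parameter space from a fixed start, so refits on identical input
    are deterministic.
    """
    config = config or TrackConfig()
    if len(fixes) < 10:
        raise FitError(f"need at least 10 fixes, got {len(fixes)}")
    t0 = fixes[0].timestamp
    span_days = (fixes[-1].timestamp - t0) / np.timedelta64(1, "s") / 86400.0
    if span_days < 1.0:
        raise FitError("fixes must span at least one day")

    proj = LocalProjection(
        lat0=float(np.mean([f.lat for f in fixes])),
        lon0=float(np.mean([f.lon for f in fixes])),
    )
    t, x, y, r2 = _fixes_xyr(fixes, config, proj)

    def nll(theta):
        beta, sigma = np.exp(theta)
        if not (1e-8 < beta < 1.0 and 1e-6 < sigma < 10.0):
            return 1e12
        lx, _, _ = _kalman(beta, sigma, t, x, r2)
        ly, _, _ = _kalman(beta, sigma, t, y, r2)
        return -(lx + ly)

    x0 = np.log([1e-4, 0.02])  # ~3-h velocity correlation, ~1 m/s RMS speed
    res = minimize(nll, x0, method="Nelder-Mead",
                   options=dict(xatol=1e-4, fatol=1e-4, maxiter=400))
    beta, sigma = np.exp(res.x)
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise FitError("CTCRW fit failed to converge", last=(beta, sigma))
    return CtcrwParams(beta=float(beta), sigma=float(sigma), loglik=float(-res.fun))


def predict_track(
    fixes: list[LocationFix],
    params: CtcrwParams,
    config: TrackConfig | None = None,
) -> pd.DataFrame:
    """Smoothed positions with standard errors on the regular grid.

    The grid is anchored at the first fix and spans to the last fix at
    ``predict_interval`` spacing (default 3 h).  Standard errors are the
    square roots of the smoothed position variances, in meters.
    """
    config = config or TrackConfig()
    proj = LocalProjection(
        lat0=float(np.mean([f.lat for f in fixes])),
        lon0=float(np.mean([f.lon for f in fixes])),
    )
    t, x, y, r2 = _fixes_xyr(fixes, config, proj)
    grid = np.arange(t[0], t[-1] + 1e-9, config.predict_interval)
    _, mx, Px = _kalman(params.beta, params.sigma, t, x, r2, predict_t=grid, smooth=True)
    _, my, Py = _kalman(params.beta, params.sigma, t, y, r2, predict_t=grid, smooth=True)
    lat, lon = proj.inverse(mx[:, 0], my[:, 0])
    return pd.DataFrame(
        {
            "timestamp": from_seconds(grid),
            "lat": lat,
            "lon": lon,
            "se_lat": np.sqrt(np.maximum(Py[:, 0, 0], 0.0)),  # north axis, meters
            "se_lon": np.sqrt(np.maximum(Px[:, 0, 0], 0.0)),  # east axis, meters
        }
    )


def process_track(
    fixes: list[LocationFix],
    meta: DeploymentMetadata,
    config: TrackConfig | None = None,
    bathymetry=None,
) -> tuple[pd.DataFrame, CtcrwParams]:
    """Full Level 2 → Level 3 track pipeline (anchors, curation, fit, predict)."""
    config = config or TrackConfig()
    fixes = add_colony_anchors(fixes, meta, config)
    if bathymetry is not None:
        fixes = remove_land_fixes(
            fixes, bathymetry, colony=(meta.colony_lat, meta.colony_lon),
            colony_buffer_km=config.colony_buffer_km,
        )
    fixes = speed_filter(fixes, config.max_speed)
    params = fit_ctcrw(fixes, config)
    return predict_track(fixes, params, config), params
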