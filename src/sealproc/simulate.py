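"""Synthetic deployments with ground truth.

Every pipeline stage is testable without archived tag data: this module
generates multi-month-style dive records (known dive table, injected
sensor drift, spikes, haulout gaps) and satellite tracks simulated from
the exact CTCRW transition density with Argos-class observation noise.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .track import LocalProjection, TrackConfig, ctcrw_matrices
from .types import (
    DeploymentMetadata,
    Level,
    LocationFix,
    Manufacturer,
    Source,
    TDRSeries,
    from_seconds,
)


@dataclass
class DiveSimConfig:
    """Shape of a simulated dive record.

    Defaults emulate an adult female elephant seal: dives mostly 300–700 m
    (occasionally past 1200 m), 20–40 min long, with 2–3 min surface
    intervals, sampled at 8 s with 0.5 m sensor resolution.
    """

    n_dives: int = 100
    depth_mode: float = 500.0  # meters, mode of the depth mixture
    depth_sd: float = 150.0
    depth_min: float = 100.0
    depth_max: float = 1500.0
    descent_speed: tuple[float, float] = (0.8, 1.5)  # m/s range
    ascent_speed: tuple[float, float] = (0.8, 1.5)
    bottom_duration: tuple[float, float] = (300.0, 900.0)  # seconds
    surface_interval: tuple[float, float] = (120.0, 200.0)  # seconds
    shape_mix: dict = field(default_factory=lambda: {"U": 0.6, "square": 0.25, "V": 0.15})
    wiggle_amplitude: float = 5.0  # meters, U-dive bottom oscillation
    sampling_interval: float = 8.0
    depth_resolution: float = 0.5
    start_time: str = "2015-02-01T00:00:00"
    drift: Optional[tuple] = None  # ("linear", total_m) | ("piecewise", step_m, seg_s)
    spike_rate_per_h: float = 0.0
    spike_magnitude: float = 80.0  # meters
    haulout_spans: list = field(default_factory=list)  # [(start_s, end_s)] rel. to start

    def __post_init__(self) -> None:
        if self.n_dives < 0 or self.sampling_interval <= 0 or self.depth_resolution <= 0:
            raise ValueError("counts, sampling interval and resolution must be positive")
        if not 0 < self.depth_min <= self.depth_max:
            raise ValueError("need 0 < depth_min <= depth_max")
        if self.surface_interval[0] <= 0 or self.bottom_duration[0] <= 0:
            raise ValueError("durations must be positive")


@dataclass
class TrackSimConfig:
    """CTCRW simulation settings for a synthetic satellite track.

    Defaults give a transiting seal: RMS speed ~1 m/s with a ~3-hour
    velocity correlation timescale, observed ~8 times a day (the typical
    Argos yield for a surfacing seal) with class-dependent noise.
    """

    beta: float = 1e-4  # 1/s (≈2.8 h velocity decorrelation)
    sigma: float = 0.01414  # m/s^1.5 → RMS speed ≈ 1 m/s
    duration_days: float = 62.5
    fixes_per_day: float = 8.0
    class_mix: dict = field(
        default_factory=lambda: {"3": 0.10, "2": 0.10, "1": 0.15,
                                 "0": 0.15, "A": 0.25, "B": 0.25}
    )
    start_lat: float = 37.108
    start_lon: float = -122.336
    start_time: str = "2015-02-01T00:00:00"
    step_s: float = 60.0
    gaps: list = field(default_factory=list)  # [(start_day, length_days)]
    noise: bool = True


@dataclass
class SyntheticTruth:
    seed: int
    dive_table: Optional[pd.DataFrame] = None
    drift_fn: Optional[object] = None  # callable seconds -> meters
    spike_times: list = field(default_factory=list)
    haulout_spans: list = field(default_factory=list)
    ctcrw_params: Optional[tuple[float, float]] = None
    true_positions: Optional[pd.DataFrame] = None


def _draw_depth(rng: np.random.Generator, cfg: DiveSimConfig) -> float:
    # lognormal-ish mixture: bulk around the mode, thin deep tail
    if rng.random() < 0.97:
        d = rng.normal(cfg.depth_mode, cfg.depth_sd)
    else:
        d = cfg.depth_mode + rng.exponential(300.0)
    return float(np.clip(d, cfg.depth_min, cfg.depth_max))


def generate_dive_record(
    config: DiveSimConfig | None = None, seed: int = 0
) -> tuple[TDRSeries, SyntheticTruth]:
    """Build a dive record on the sampling grid with an exact truth table.

    Depth profiles are constructed sample-by-sample (descent ramp, bottom,
    ascent ramp, surface interval), quantized to the sensor resolution,
    then drift, spikes, and haulout gaps are applied.  The truth table is
    consistent with the series by construction: truth start/end are the
    bounding surface samples, matching the dive detector's convention.
    """
    cfg = config or DiveSimConfig()
    rng = np.random.default_rng(seed)
    dt = cfg.sampling_interval
    res = cfg.depth_resolution
    shapes = list(cfg.shape_mix)
    probs = np.array([cfg.shape_mix[s] for s in shapes], float)
    probs /= probs.sum()

    depths = [0.0] * 5  # lead-in surface samples
    truth_rows = []
    for k in range(cfg.n_dives):
        D = round(_draw_depth(rng, cfg) / res) * res
        shape = shapes[rng.choice(len(shapes), p=probs)]
        vd = rng.uniform(*cfg.descent_speed)
        va = rng.uniform(*cfg.ascent_speed)
        n_desc = max(int(np.ceil(D / (vd * dt))), 2)
        n_asc = max(int(np.ceil(D / (va * dt))), 2)
        if shape == "V":
            n_bot = 1
        else:
            n_bot = max(int(round(rng.uniform(*cfg.bottom_duration) / dt)), 3)
        profile = list(np.linspace(0, D, n_desc + 1)[1:])
        if shape == "U" and n_bot >= 3:
            osc = cfg.wiggle_amplitude * np.abs(np.sin(np.linspace(0, 3 * np.pi, n_bot)))
            profile += list(D - osc)
        else:
            profile += [D] * n_bot
        profile += list(np.linspace(D, 0, n_asc + 1)[1:-1])
        start_idx = len(depths) - 1  # last surface sample before the excursion
        depths += profile
        end_idx = len(depths)  # first surface sample after
        n_surf = max(int(round(rng.uniform(*cfg.surface_interval) / dt)), 2)
        depths += [0.0] * n_surf
        truth_rows.append(
            dict(dive_number=k + 1, start_idx=start_idx, end_idx=end_idx,
                 max_depth=D, duration=(end_idx - start_idx) * dt, shape=shape)
        )
    depths = np.asarray(depths)
    n = len(depths)
    t0 = np.datetime64(cfg.start_time, "s")
    t = t0 + (np.arange(n) * dt).astype("timedelta64[s]")
    t_rel = np.arange(n) * dt

    truth = pd.DataFrame(truth_rows)
    truth["start"] = t[truth["start_idx"].to_numpy()]
    truth["end"] = t[truth["end_idx"].to_numpy()]

    drift_fn = _make_drift(cfg, t_rel[-1])
    observed = depths + drift_fn(t_rel)
    observed = np.round(observed / res) * res

    spike_times = []
    if cfg.spike_rate_per_h > 0:
        n_spikes = rng.poisson(cfg.spike_rate_per_h * t_rel[-1] / 3600.0)
        idx = rng.choice(np.arange(2, n - 2), size=min(n_spikes, n - 4), replace=False)
        idx = np.sort(idx)
        idx = idx[np.diff(np.concatenate([[-10], idx])) > 3]  # keep spikes isolated
        for i in idx:
            observed[i] += cfg.spike_magnitude
            spike_times.append(t[i])

    keep = np.ones(n, bool)
    for s0, s1 in cfg.haulout_spans:
        keep &= ~((t_rel > s0) & (t_rel < s1))

    series = TDRSeries(
        time=t[keep], depth=observed[keep],
        sampling_interval=dt, depth_resolution=res,
        manufacturer=Manufacturer.WC, instrument_id=f"SIM{seed:04d}", level=Level.L2,
    )
    return series, SyntheticTruth(
        seed=seed, dive_table=truth, drift_fn=drift_fn,
        spike_times=spike_times, haulout_spans=list(cfg.haulout_spans),
    )


def _make_drift(cfg: DiveSimConfig, span_s: float):
    if cfg.drift is None:
        return lambda s: np.zeros_like(np.asarray(s, float))
    kind = cfg.drift[0]
    if kind == "linear":
        total = cfg.drift[1]
        return lambda s: np.asarray(s, float) / max(span_s, 1.0) * total
    if kind == "piecewise":
        step_m, seg_s = cfg.drift[1], cfg.drift[2]
        n_seg = int(span_s // seg_s) + 2
        rng = np.random.default_rng(12345)  # drift shape fixed per config
        levels = np.cumsum(rng.uniform(-step_m, step_m, n_seg))
        levels = np.clip(levels, -5.0, 5.0)

        def fn(s):
            return levels[(np.asarray(s, float) // seg_s).astype(int)]

        fn.levels, fn.segment_s = levels, seg_s
        return fn
    raise ValueError(f"unknown drift spec {cfg.drift!r}")


def generate_track(
    config: TrackSimConfig | None = None, seed: int = 0
) -> tuple[list[LocationFix], SyntheticTruth]:
    """Simulate a CTCRW path and Argos-like observations of it.

    The true path is drawn from the exact transition density at
    ``step_s`` resolution; fixes occur at Poisson times (default 8/day),
    carry a quality class drawn from ``class_mix``, and are perturbed with
    the corresponding class-level Gaussian noise per planar axis.
    """
    cfg = config or TrackSimConfig()
    rng = np.random.default_rng(seed)
    n_steps = int(cfg.duration_days * 86400 / cfg.step_s)
    dt = np.full(n_steps, cfg.step_s)
    F, Q = ctcrw_matrices(cfg.beta, cfg.sigma, dt)
    L = np.linalg.cholesky(Q[0] + 1e-12 * np.eye(2))
    v_sd = cfg.sigma / np.sqrt(2 * cfg.beta)  # stationary velocity SD

    state = np.zeros((2, 2))  # axis (x, y) × (pos, vel)
    state[:, 1] = rng.normal(0, v_sd, 2)
    path = np.zeros((n_steps + 1, 2))
    for k in range(n_steps):
        noise = (L @ rng.standard_normal((2, 2)).T).T
        state = state @ F[0].T + noise
        path[k + 1] = state[:, 0]

    t0 = np.datetime64(cfg.start_time, "s")
    step_times = np.arange(n_steps + 1) * cfg.step_s
    proj = LocalProjection(lat0=cfg.start_lat, lon0=cfg.start_lon)

    # Poisson sampling times
    n_fix = rng.poisson(cfg.fixes_per_day * cfg.duration_days)
    fix_t = np.sort(rng.uniform(0, cfg.duration_days * 86400, n_fix))
    for g0, glen in cfg.gaps:
        fix_t = fix_t[~((fix_t >= g0 * 86400) & (fix_t < (g0 + glen) * 86400))]
    fix_t = np.unique(np.round(fix_t))

    classes = list(cfg.class_mix)
    cprobs = np.array([cfg.class_mix[c] for c in classes], float)
    cprobs /= cprobs.sum()
    sd_map = TrackConfig().class_error_sd

    fixes = []
    for ft in fix_t:
        i = int(round(ft / cfg.step_s))
        i = min(i, n_steps)
        x, y = path[i]
        qc = classes[rng.choice(len(classes), p=cprobs)]
        if cfg.noise:
            sd = sd_map[qc]
            x += rng.normal(0, sd)
            y += rng.normal(0, sd)
        lat, lon = proj.inverse(x, y)
        fixes.append(
            LocationFix(
                timestamp=t0 + np.timedelta64(int(ft), "s"),
                lat=float(lat), lon=float(lon), quality_class=qc,
                source=Source.GPS if qc == "G" else Source.ARGOS,
            )
        )

    lat_p, lon_p = proj.inverse(path[:, 0], path[:, 1])
    truth = SyntheticTruth(
        seed=seed,
        ctcrw_params=(cfg.beta, cfg.sigma),
        true_positions=pd.DataFrame(
            {"timestamp": t0 + step_times.astype("timedelta64[s]"),
             "lat": lat_p, "lon": lon_p, "x": path[:, 0], "y": path[:, 1]}
        ),
    )
    return fixes, truth


def make_demo_inputs(seed: int = 0):
    """Small end-to-end deployment inputs (~7 days, ~300 dives)."""
    t0 = "2015-02-01T00:00:00"
    dive_cfg = DiveSimConfig(
        n_dives=300, start_time=t0,
        drift=("linear", 4.0), spike_rate_per_h=0.2,
    )
    tdr, dive_truth = generate_dive_record(dive_cfg, seed=seed)
    span_days = (tdr.time[-1] - tdr.time[0]) / np.timedelta64(1, "s") / 86400.0
    track_cfg = TrackSimConfig(duration_days=float(span_days), start_time=t0)
    fixes, track_truth = generate_track(track_cfg, seed=seed + 1)
    departure = np.datetime64(t0, "s")
    arrival = tdr.time[-1] + np.timedelta64(3600, "s")
    meta = DeploymentMetadata(
        toppid=f"20{15:02d}{(seed % 999) + 1:03d}",
        animal_id=f"X{seed:03d}",
        colony="ANM",
        departure=departure,
        arrival=arrival,
        trip="post-breeding",
    )
    return meta, tdr, fixes, SyntheticTruth(
        seed=seed, dive_table=dive_truth.dive_table,
        drift_fn=dive_truth.drift_fn, spike_times=dive_truth.spike_times,
        ctcrw_params=track_truth.ctcrw_params,
        true_positions=track_truth.true_positions,
    )


def make_demo_deployment(seed: int = 0):
    """Run the full pipeline on a small synthetic deployment."""
    from .pipeline import process_deployment

    meta, tdr, fixes, truth = make_demo_inputs(seed)
    bundle = process_deployment(meta, [tdr], fixes)
    return bundle, truth
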