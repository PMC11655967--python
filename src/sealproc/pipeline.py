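"""End-to-end orchestration of the deployment-processing workflow.

Order of stages: ingest → zero-offset correction → dive analysis →
track curation/interpolation → dive geolocation → quality control →
netCDF packaging.  Each stage logs counts in/out and its parameters so
the provenance recorded in the netCDF global attributes can be
reconstructed from the logs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import dives as dv
from . import qc as qcmod
from . import track as trk
from . import zoc as zocmod
from .geolocate import geolocate_dives
from .ingest import subsample_to_8s
from .ncio import write_processed, write_rawcurated
from .types import DeploymentBundle, DeploymentMetadata, LocationFix, TDRSeries

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage configurations plus I/O paths and the random seed.

    Every threshold default equals the processing protocol's value:
    25 m / 32 s dive criteria, 50% bottom-depth constraint, 5 m/s spike
    filter, 3 m/s track speed filter, 150 min duration cap, 2-h ZOC
    window, 15 m surface ceiling, 15× resolution refinement tolerance,
    −10 m / 2200 m depth range, 3-h prediction grid, 5-day end-anchor
    window, 8-s subsampling target.
    """

    zoc: zocmod.ZocConfig = field(default_factory=zocmod.ZocConfig)
    dive_criteria: dv.DiveCriteria = field(default_factory=dv.DiveCriteria)
    track: trk.TrackConfig = field(default_factory=trk.TrackConfig)
    qc: qcmod.QCThresholds = field(default_factory=qcmod.QCThresholds)
    seed: int = 0
    out_dir: str = "."


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def analyze_tdr(series: TDRSeries, config: PipelineConfig):
    """ZOC + dive analysis for one curated series; returns (zoc, stats)."""
    zres = zocmod.zero_offset_correct(series, config.zoc)
    spans = dv.detect_dives(zres.corrected, config.dive_criteria)
    stats = dv.compute_dive_stats(zres.corrected, spans, config.dive_criteria)
    stats = dv.merge_zero_pdi(stats, zres.corrected, config.dive_criteria)
    stats, removed = dv.filter_dive_stats(stats)
    log.info(
        "dive analysis: %d dives detected, %d kept after filters",
        len(spans), len(stats),
    )
    return zres, stats


def process_deployment(
    meta: DeploymentMetadata,
    tdr_list: list[TDRSeries],
    fixes: list[LocationFix],
    config: PipelineConfig | None = None,
    bathymetry=None,
) -> DeploymentBundle:
    """Run every processing stage for one deployment and return the bundle."""
    config = config or PipelineConfig()
    bundle = DeploymentBundle(meta=meta, raw_tdr=list(tdr_list), raw_locs=list(fixes))

    try:
        track_df, params = trk.process_track(fixes, meta, config.track, bathymetry)
        curated = trk.add_colony_anchors(fixes, meta, config.track)
        curated = trk.speed_filter(curated, config.track.max_speed)
        bundle.curated_locs = curated
        bundle.track = track_df
    except trk.FitError as exc:
        raise StageError("track", exc)

    stats_list = []
    for series in tdr_list:
        try:
            zres, stats = analyze_tdr(series, config)
        except Exception as exc:
            raise StageError("dive_analysis", exc)
        bundle.clean_tdr.append(series)
        bundle.zoc_tdr.append(zres.corrected)
        stats = geolocate_dives(stats, bundle.track)
        stats_list.append((zres, stats))
        sub = subsample_to_8s(series)
        if sub is not series and len(sub) > 1:
            zres8, stats8 = analyze_tdr(sub, config)
            stats8 = geolocate_dives(stats8, bundle.track)
        else:
            stats8 = None
        bundle.dive_stats.append(stats)
        bundle.dive_stats_8s.append(stats8)

    try:
        bundle.qc_track = qcmod.qc_track(
            bundle.curated_locs, (meta.departure, meta.arrival), config.qc
        )
        for series, (zres, stats) in zip(tdr_list, stats_list):
            report = qcmod.scan_dive_anomalies(stats, zres.corrected, config.qc)
            bundle.qc_tdr.append(qcmod.qc_dive_record(series, report, config.qc))
    except Exception as exc:
        raise StageError("qc", exc)
    return bundle


def run_pipeline(
    meta: DeploymentMetadata,
    tdr_list: list[TDRSeries],
    fixes: list[LocationFix],
    config: PipelineConfig | None = None,
    bathymetry=None,
) -> dict:
    """Process a deployment, write both netCDF files plus CSV outputs.

    Returns a manifest: every artifact path with its SHA-256 checksum.
    """
    config = config or PipelineConfig()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = process_deployment(meta, tdr_list, fixes, config, bathymetry)

    paths = []
    try:
        paths.append(write_rawcurated(bundle, out_dir))
        paths.append(write_processed(bundle, out_dir))
    except Exception as exc:
        raise StageError("package", exc)

    track_csv = out_dir / f"{meta.toppid}_TRACK.csv"
    bundle.track.to_csv(track_csv, index=False)
    paths.append(track_csv)
    for i, stats in enumerate(bundle.dive_stats, start=1):
        p = out_dir / f"{meta.toppid}_TDR{i}_DiveStat.csv"
        dv.write_divestat_csv(stats, p)
        paths.append(p)

    manifest = {}
    for p in paths:
        manifest[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    log.info("pipeline complete: %d artifacts", len(manifest))
    return manifest
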