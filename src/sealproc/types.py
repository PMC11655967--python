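"""Core domain types shared across the processing pipeline.

The pipeline follows the three-tier biologging data convention:
Level 1 = decoded (raw), Level 2 = curated, Level 3 = interpolated/derived.
Depth series and location fixes are the two data streams; everything else
(dive statistics, predicted tracks, QC flags) is derived from them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EPOCH = np.datetime64("1970-01-01T00:00:00", "s")


class Manufacturer(str, enum.Enum):
    """TDR manufacturer, which determines the CSV dialect and fix-ups."""

    WC = "WC"  # Wildlife Computers
    SMRU = "SMRU"  # Sea Mammal Research Unit
    LL = "LL"  # Little Leonardo


class Level(str, enum.Enum):
    L1 = "L1"  # decoded, uncurated
    L2 = "L2"  # curated (trimmed, haulouts filled, clock-corrected)
    ZOC = "ZOC"  # zero-offset corrected


class Source(str, enum.Enum):
    ARGOS = "ARGOS"
    GPS = "GPS"
    ANCHOR = "ANCHOR"  # colony start/end points added during curation


#: Argos location quality classes plus "G" for GPS-grade points.
QUALITY_CLASSES = ("3", "2", "1", "0", "A", "B", "Z", "G")

#: Colony codes with (lat, lon) of the rookery.
COLONIES = {
    "ANM": (37.108, -122.336),  # Año Nuevo mainland
    "SNI": (33.234, -119.524),  # San Nicolas Island
    "IG": (29.040, -118.280),  # Isla Guadalupe
    "ISB": (28.300, -115.570),  # Isla San Benito
}


def as_seconds(t: np.ndarray) -> np.ndarray:
    """Convert a datetime64 array to float seconds since the Unix epoch."""
    return (np.asarray(t, dtype="datetime64[s]") - EPOCH) / np.timedelta64(1, "s")


def from_seconds(s: np.ndarray) -> np.ndarray:
    """Inverse of :func:`as_seconds` (rounded to whole seconds)."""
    return EPOCH + np.asarray(np.round(s), dtype="timedelta64[s]")


@dataclass
class TDRSeries:
    """A timestamped depth series from one instrument.

    Parameters
    ----------
    time : datetime64[s] array, strictly increasing
    depth : float array, meters, positive downward
    sampling_interval : nominal seconds between samples
    depth_resolution : meters per sensor count (e.g. 0.5)
    """

    time: np.ndarray
    depth: np.ndarray
    sampling_interval: float
    depth_resolution: float
    manufacturer: Manufacturer = Manufacturer.WC
    instrument_id: str = ""
    level: Level = Level.L1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[s]")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.time.shape != self.depth.shape:
            raise ValueError("time and depth must have the same length")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.depth_resolution <= 0:
            raise ValueError("depth_resolution must be positive")
        self.manufacturer = Manufacturer(self.manufacturer)
        self.level = Level(self.level)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def seconds(self) -> np.ndarray:
        return as_seconds(self.time)

    def validate_monotonic(self) -> None:
        """Raise if timestamps are not strictly increasing."""
        if len(self.time) > 1:
            bad = np.where(np.diff(self.time.astype("int64")) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"non-increasing timestamp at row {bad[0] + 1}: "
                    f"{self.time[bad[0] + 1]}"
                )

    def with_(self, **kwargs) -> "TDRSeries":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "depth": self.depth})


@dataclass(frozen=True)
class LocationFix:
    """One raw location estimate (Argos Doppler, FastLoc GPS, or anchor)."""

    timestamp: np.datetime64
    lat: float
    lon: float
    quality_class: str
    source: Source = Source.ARGOS
    error_semi_major: Optional[float] = None  # meters
    error_semi_minor: Optional[float] = None  # meters
    error_ellipse_orientation: Optional[float] = None  # degrees

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "timestamp", np.datetime64(self.timestamp, "s")
        )
        object.__setattr__(self, "source", Source(self.source))
        qc = str(self.quality_class).upper()
        if qc not in QUALITY_CLASSES:
            raise ValueError(f"unknown quality class {qc!r}")
        if qc == "G" and self.source == Source.ARGOS:
            raise ValueError("class G is reserved for GPS/anchor fixes")
        object.__setattr__(self, "quality_class", qc)
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180 <= self.lon <= 180:
            raise ValueError(f"longitude {self.lon} out of range")


def fixes_to_frame(fixes: Sequence[LocationFix]) -> pd.DataFrame:
    """Tabulate a fix sequence (one row per fix, time-ordered as given)."""
    return pd.DataFrame(
        {
            "timestamp": [f.timestamp for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
            "quality_class": [f.quality_class for f in fixes],
            "source": [f.source.value for f in fixes],
            "error_semi_major": [f.error_semi_major for f in fixes],
            "error_semi_minor": [f.error_semi_minor for f in fixes],
            "error_ellipse_orientation": [
                f.error_ellipse_orientation for f in fixes
            ],
        }
    )


def frame_to_fixes(df: pd.DataFrame) -> list[LocationFix]:
    out = []
    for row in df.itertuples(index=False):
        sm = getattr(row, "error_semi_major", None)
        out.append(
            LocationFix(
                timestamp=np.datetime64(row.timestamp, "s"),
                lat=float(row.lat),
                lon=float(row.lon),
                quality_class=str(row.quality_class),
                source=Source(row.source),
                error_semi_major=None if sm is None or pd.isna(sm) else float(sm),
            )
        )
    return out


@dataclass
class DeploymentMetadata:
    """Identity and trip timing for one instrument deployment."""

    toppid: str
    animal_id: str
    colony: str
    departure: np.datetime64
    arrival: Optional[np.datetime64] = None
    trip: str = "post-breeding"  # or "post-molting"
    all_toppids_for_animal: list[str] = field(default_factory=list)
    colony_lat: Optional[float] = None
    colony_lon: Optional[float] = None
    instruments: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        parse_toppid(self.toppid)  # validates format
        self.departure = np.datetime64(self.departure, "s")
        if self.arrival is not None:
            self.arrival = np.datetime64(self.arrival, "s")
            if not self.departure < self.arrival:
                raise ValueError("departure must precede arrival")
        if self.colony_lat is None:
            if self.colony not in COLONIES:
                raise ValueError(
                    f"unknown colony {self.colony!r} and no coordinates given"
                )
            self.colony_lat, self.colony_lon = COLONIES[self.colony]
        if not self.all_toppids_for_animal:
            self.all_toppids_for_animal = [self.toppid]


def parse_toppid(toppid: str) -> tuple[int, int, int]:
    """Split a 7-digit deployment identifier.

    Digits 1-2 encode the species (20 = northern elephant seal), 3-4 the
    two-digit year (expanded to 2000+yy), 5-7 the deployment serial.

    >>> parse_toppid("2004001")
    (20, 2004, 1)
    """
    s = str(toppid)
    if len(s) != 7 or not s.isdigit():
        raise ValueError(f"TOPPID must be 7 decimal digits, got {toppid!r}")
    return int(s[:2]), 2000 + int(s[2:4]), int(s[4:7])


@dataclass(frozen=True)
class QCFlag:
    """Integer 1-5 quality flag with a human-readable rationale.

    1 = complete, 2 = mostly complete, 3 = incomplete (gaps > 2 days),
    4 = questionable, 5 = no data.
    """

    value: int
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4, 5):
            raise ValueError("QC flag must be an integer in 1..5")


@dataclass
class DeploymentBundle:
    """Everything produced for one deployment, ready for netCDF packaging."""

    meta: DeploymentMetadata
    raw_tdr: list[TDRSeries] = field(default_factory=list)
    clean_tdr: list[TDRSeries] = field(default_factory=list)
    zoc_tdr: list[TDRSeries] = field(default_factory=list)
    raw_locs: list[LocationFix] = field(default_factory=list)
    curated_locs: list[LocationFix] = field(default_factory=list)
    track: Optional[pd.DataFrame] = None  # PredictedLocation table
    dive_stats: list[pd.DataFrame] = field(default_factory=list)
    dive_stats_8s: list[Optional[pd.DataFrame]] = field(default_factory=list)
    qc_track: Optional[QCFlag] = None
    qc_tdr: list[QCFlag] = field(default_factory=list)
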