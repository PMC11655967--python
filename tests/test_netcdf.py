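import numpy as np
import pandas as pd
import pytest

from sealproc import ncio
from sealproc.types import (
    DeploymentBundle,
    DeploymentMetadata,
    Level,
    LocationFix,
    Manufacturer,
    QCFlag,
    Source,
    TDRSeries,
)

T0 = np.datetime64("2015-02-01T00:00:00", "s")


def random_bundle(rng: np.random.Generator, toppid="2015001") -> DeploymentBundle:
    n = int(rng.integers(20, 60))
    t = T0 + (np.arange(n) * 8).astype("timedelta64[s]")
    series = TDRSeries(
        time=t,
        depth=np.round(rng.uniform(0, 500, n) * 2) / 2,
        sampling_interval=8,
        depth_resolution=0.5,
        manufacturer=[Manufacturer.WC, Manufacturer.SMRU][int(rng.integers(2))],
        instrument_id=f"I{rng.integers(1000)}",
        level=Level.L1,
    )
    fixes = [
        LocationFix(
            timestamp=T0 + np.timedelta64(int(s), "s"),
            lat=float(rng.uniform(30, 50)),
            lon=float(rng.uniform(-140, -120)),
            quality_class=str(rng.choice(["3", "2", "1", "0", "A", "B"])),
            source=Source.ARGOS,
            error_semi_major=float(rng.uniform(100, 5000)) if rng.random() < 0.5 else None,
        )
        for s in np.sort(rng.integers(0, 86400, int(rng.integers(5, 15))))
    ]
    m = int(rng.integers(5, 20))
    track = pd.DataFrame(
        {
            "timestamp": T0 + (np.arange(m) * 10800).astype("timedelta64[s]"),
            "lat": rng.uniform(30, 50, m),
            "lon": rng.uniform(-140, -120, m),
            "se_lat": rng.uniform(0, 5000, m),
            "se_lon": rng.uniform(0, 5000, m),
        }
    )
    k = int(rng.integers(3, 10))
    stats = pd.DataFrame(
        {
            "dive_number": np.arange(1, k + 1),
            "start": T0 + (np.arange(k) * 2000).astype("timedelta64[s]"),
            "end": T0 + (np.arange(k) * 2000 + 1500).astype("timedelta64[s]"),
            "duration": rng.uniform(100, 2000, k),
            "max_depth": rng.uniform(25, 800, k),
            "descent_duration": rng.uniform(50, 500, k),
            "bottom_duration": rng.uniform(50, 500, k),
            "ascent_duration": rng.uniform(50, 500, k),
            "descent_rate": rng.uniform(0.5, 2.5, k),
            "ascent_rate": rng.uniform(0.5, 2.5, k),
            "bottom_range": rng.uniform(0, 50, k),
            "wiggles": rng.integers(0, 10, k),
            "post_dive_interval": rng.uniform(60, 300, k),
            "lat": rng.uniform(30, 50, k),
            "lon": rng.uniform(-140, -120, k),
            "lat_se": rng.uniform(0, 5000, k),
            "lon_se": rng.uniform(0, 5000, k),
            "solar_elevation": rng.uniform(-90, 90, k),
        }
    )
    meta = DeploymentMetadata(
        toppid=toppid,
        animal_id=f"X{rng.integers(100)}",
        colony="ANM",
        departure=T0,
        arrival=T0 + np.timedelta64(int(rng.integers(5, 200)), "D"),
        all_toppids_for_animal=[toppid, "2014009"],
    )
    return DeploymentBundle(
        meta=meta,
        raw_tdr=[series],
        clean_tdr=[series.with_(level=Level.L2)],
        raw_locs=fixes,
        curated_locs=fixes,
        track=track,
        dive_stats=[stats],
        dive_stats_8s=[stats.copy() if rng.random() < 0.5 else None],
        qc_track=QCFlag(int(rng.integers(1, 4)), "synthetic"),
        qc_tdr=[QCFlag(int(rng.integers(1, 4)), "synthetic")],
    )


def assert_bundle_roundtrip(b, tmp_path):
    p1 = ncio.write_rawcurated(b, tmp_path)
    p2 = ncio.write_processed(b, tmp_path)
    r1 = ncio.read_bundle(p1)
    r2 = ncio.read_bundle(p2)
    np.testing.assert_array_equal(r1.raw_tdr[0].time, b.raw_tdr[0].time)
    np.testing.assert_array_equal(r1.raw_tdr[0].depth, b.raw_tdr[0].depth)
    np.testing.assert_array_equal(r1.clean_tdr[0].depth, b.clean_tdr[0].depth)
    assert r1.raw_tdr[0].manufacturer == b.raw_tdr[0].manufacturer
    assert r1.raw_locs == b.raw_locs
    assert r1.meta.toppid == b.meta.toppid
    assert r1.meta.animal_id == b.meta.animal_id
    assert r1.meta.all_toppids_for_animal == b.meta.all_toppids_for_animal
    assert r1.meta.departure == b.meta.departure
    assert r1.meta.arrival == b.meta.arrival
    assert r1.qc_track.value == b.qc_track.value
    assert [f.value for f in r1.qc_tdr] == [f.value for f in b.qc_tdr]
    pd.testing.assert_frame_equal(r2.track, b.track)
    for col in b.dive_stats[0].columns:
        got = r2.dive_stats[0][col].to_numpy()
        want = b.dive_stats[0][col].to_numpy()
        if col in ("start", "end"):
            np.testing.assert_array_equal(got.astype("datetime64[s]"), want.astype("datetime64[s]"))
        else:
            np.testing.assert_array_equal(got, want)
    if b.dive_stats_8s[0] is not None:
        assert r2.dive_stats_8s[0] is not None


class TestRoundTrip:
    def test_filenames_follow_toppid_pattern(self, tmp_path):
        b = random_bundle(np.random.default_rng(0), toppid="2004001")
        p1 = ncio.write_rawcurated(b, tmp_path)
        p2 = ncio.write_processed(b, tmp_path)
        assert p1.name == "2004001_TrackTDR_RawCurated.nc"
        assert p2.name == "2004001_TrackTDR_Processed.nc"

    def test_random_bundles_roundtrip(self, tmp_path):
        for seed in range(20):
            b = random_bundle(np.random.default_rng(seed), toppid=f"20150{seed:02d}")
            assert_bundle_roundtrip(b, tmp_path)

    def test_write_read_write_identical(self, tmp_path):
        b = random_bundle(np.random.default_rng(5))
        p2 = ncio.write_processed(b, tmp_path)
        r = ncio.read_bundle(p2)
        r.meta = b.meta
        d2 = tmp_path / "again"
        d2.mkdir()
        r.qc_track, r.qc_tdr = b.qc_track, b.qc_tdr
        p2b = ncio.write_processed(r, d2)
        import netCDF4

        with netCDF4.Dataset(p2) as a, netCDF4.Dataset(p2b) as c:
            np.testing.assert_array_equal(a["TRACK/LAT"][:], c["TRACK/LAT"][:])
            np.testing.assert_array_equal(a["TDR1/MAXDEPTH"][:], c["TDR1/MAXDEPTH"][:])


class TestSchema:
    def test_quality4_record_gets_no_clean_group(self, tmp_path):
        b = random_bundle(np.random.default_rng(1))
        b.qc_tdr = [QCFlag(4, "questionable")]
        p = ncio.write_rawcurated(b, tmp_path)
        import netCDF4

        with netCDF4.Dataset(p) as ds:
            assert "RAW_TDR1" in ds.groups
            assert "CLEAN_TDR1" not in ds.groups

    def test_missing_level3_products_errors(self, tmp_path):
        b = random_bundle(np.random.default_rng(2))
        b.track = None
        b.dive_stats = []
        with pytest.raises(ValueError):
            ncio.write_processed(b, tmp_path)

    def test_file_missing_track_group_schema_error(self, tmp_path):
        import netCDF4

        p = tmp_path / "2015001_TrackTDR_Processed.nc"
        b = random_bundle(np.random.default_rng(3))
        with netCDF4.Dataset(p, "w") as ds:
            ncio._meta_attrs(ds, b)
        with pytest.raises(ncio.SchemaError, match="TRACK"):
            ncio.read_bundle(p)

    def test_group_without_date_rejected(self, tmp_path):
        import netCDF4

        p = tmp_path / "2015001_TrackTDR_RawCurated.nc"
        b = random_bundle(np.random.default_rng(4))
        with netCDF4.Dataset(p, "w") as ds:
            ncio._meta_attrs(ds, b)
            g = ds.createGroup("RAW_TDR1")
            g.createDimension("obs", 3)
            v = g.createVariable("DEPTH", "f8", ("obs",))
            v[:] = [1.0, 2.0, 3.0]
        with pytest.raises(ncio.SchemaError, match="RAW_TDR1"):
            ncio.read_bundle(p)

    def test_8s_twin_group_present(self, tmp_path):
        b = random_bundle(np.random.default_rng(6))
        b.dive_stats_8s = [b.dive_stats[0].copy()]
        p = ncio.write_processed(b, tmp_path)
        import netCDF4

        with netCDF4.Dataset(p) as ds:
            assert "TDR1" in ds.groups and "TDR1_8S" in ds.groups


class TestTdrOrdering:
    def test_quality_then_wc_priority(self):
        flags = [QCFlag(2), QCFlag(1), QCFlag(1)]
        mans = [Manufacturer.WC, Manufacturer.SMRU, Manufacturer.WC]
        order = ncio.order_tdrs(flags, mans)
        assert order == [2, 1, 0]  # flag-1 WC, then flag-1 SMRU, then flag-2

    def test_equal_quality_wc_first(self):
        flags = [QCFlag(1), QCFlag(1)]
        mans = [Manufacturer.SMRU, Manufacturer.WC]
        assert ncio.order_tdrs(flags, mans) == [1, 0]

    def test_pure_function_of_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            k = int(rng.integers(1, 4))
            flags = [QCFlag(int(rng.integers(1, 6))) for _ in range(k)]
            mans = [list(Manufacturer)[int(rng.integers(3))] for _ in range(k)]
            o1 = ncio.order_tdrs(flags, mans)
            o2 = ncio.order_tdrs(list(flags), list(mans))
            assert o1 == o2
            assert sorted(o1) == list(range(k))
            # best flag always first
            assert flags[o1[0]].value == min(f.value for f in flags)
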