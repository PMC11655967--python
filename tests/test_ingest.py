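import numpy as np
import pytest

from sealproc import ingest
from sealproc.types import (
    DeploymentMetadata,
    Level,
    LocationFix,
    Manufacturer,
    Source,
    parse_toppid,
)

from conftest import T0, make_series


def _write_csv(tmp_path, rows, header="time,depth"):
    p = tmp_path / "tdr.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadTdrCsv:
    def test_identity_read(self, tmp_path):
        base = np.datetime64("2015-02-01T00:00:00")
        rows = [
            f"{base + np.timedelta64(8 * i, 's')},{10.0 * i}" for i in range(10)
        ]
        p = _write_csv(tmp_path, rows)
        s = ingest.read_tdr_csv(p, "WC", sampling_interval=8, depth_resolution=0.5)
        assert len(s) == 10
        assert s.level == Level.L1
        assert s.sampling_interval == 8
        np.testing.assert_allclose(s.depth, 10.0 * np.arange(10))

    def test_smru_haulout_lines_dropped(self, tmp_path):
        rows = [
            "2015-02-01T00:00:00,5.0",
            "HAULOUT start",
            "2015-02-01T00:00:08,6.0",
        ]
        p = _write_csv(tmp_path, rows)
        s = ingest.read_tdr_csv(p, "SMRU", 8, 0.5)
        assert len(s) == 2

    def test_duplicate_timestamp_errors_with_location(self, tmp_path):
        rows = [
            "2015-02-01T00:00:00,5.0",
            "2015-02-01T00:00:08,6.0",
            "2015-02-01T00:00:08,7.0",
        ]
        p = _write_csv(tmp_path, rows)
        with pytest.raises(ValueError, match="00:00:08"):
            ingest.read_tdr_csv(p, "WC", 8, 0.5)

    def test_unparseable_row_reports_line_number(self, tmp_path):
        rows = ["2015-02-01T00:00:00,5.0", "garbage,here"]
        p = _write_csv(tmp_path, rows)
        with pytest.raises(ingest.TDRParseError, match=":3:"):
            ingest.read_tdr_csv(p, "WC", 8, 0.5)


class TestFillSmruHaulouts:
    def test_60s_gap_in_4s_series(self):
        t = np.concatenate([np.arange(0, 20, 4), np.arange(80, 100, 4)])
        s = make_series(np.ones(10), interval=4, manufacturer=Manufacturer.SMRU)
        s = s.with_(time=T0 + t.astype("timedelta64[s]"))
        filled = ingest.fill_smru_haulouts(s)
        # 60-s gap between t=16 and t=80 → interior points 20,24,...,76 = 15
        # but the classic count for a 60-s span at 4 s is (gap/interval)-1
        gap = 80 - 16
        assert len(filled) == 10 + gap // 4 - 1
        inserted = filled.depth[(filled.seconds - filled.seconds[0] > 16)
                                & (filled.seconds - filled.seconds[0] < 80)]
        assert (inserted == 0).all()

    def test_no_gap_unchanged(self):
        s = make_series(np.ones(10), interval=4, manufacturer=Manufacturer.SMRU)
        filled = ingest.fill_smru_haulouts(s)
        assert len(filled) == 10

    def test_single_interval_gap_no_insertion(self):
        t = np.array([0, 4, 8, 16, 20])  # one missing sample at 12
        s = make_series(np.ones(5), interval=4, manufacturer=Manufacturer.SMRU)
        s = s.with_(time=T0 + t.astype("timedelta64[s]"))
        filled = ingest.fill_smru_haulouts(s)
        assert len(filled) == 6  # exactly the one interior point at t=12


class TestCorrectLlTime:
    def test_pure_shift(self):
        s = make_series(np.ones(10), interval=5, manufacturer=Manufacturer.LL)
        out = ingest.correct_ll_time(s, offset_hours=8.0, compression_minutes=0.0)
        assert (out.seconds - s.seconds == 8 * 3600).all()

    def test_identity(self):
        s = make_series(np.ones(10), interval=5, manufacturer=Manufacturer.LL)
        out = ingest.correct_ll_time(s, 0.0, 0.0)
        np.testing.assert_array_equal(out.time, s.time)

    def test_compression_affine_map(self):
        # 10-h record: end moves +6 min, midpoint +3 min, start fixed
        n = 7201
        t = T0 + (np.arange(n) * 5).astype("timedelta64[s]")
        s = make_series(np.ones(n), interval=5, manufacturer=Manufacturer.LL)
        s = s.with_(time=t)
        out = ingest.correct_ll_time(s, 0.0, compression_minutes=6.0)
        assert out.seconds[0] == s.seconds[0]
        assert out.seconds[-1] - s.seconds[-1] == pytest.approx(360, abs=1)
        mid = n // 2
        assert out.seconds[mid] - s.seconds[mid] == pytest.approx(180, abs=1)


class TestTruncateToTrip:
    def test_leading_truncation(self, meta):
        s = make_series(np.ones(100), t0=meta.departure - np.timedelta64(400, "s"))
        out = ingest.truncate_to_trip(s, meta)
        assert out.level == Level.L2
        assert out.time[0] >= meta.departure
        np.testing.assert_array_equal(
            out.depth, s.depth[s.time >= meta.departure]
        )

    def test_arrival_unknown_keeps_tail(self):
        meta = DeploymentMetadata(
            toppid="2015002", animal_id="X", colony="ANM",
            departure=np.datetime64("2015-02-01T00:00:00"),
        )
        s = make_series(np.ones(50), t0=meta.departure + np.timedelta64(10, "D"))
        out = ingest.truncate_to_trip(s, meta)
        assert len(out) == 50

    def test_departure_after_last_sample_errors(self, meta):
        s = make_series(np.ones(10), t0=meta.departure - np.timedelta64(1, "D"))
        meta2 = DeploymentMetadata(
            toppid="2015003", animal_id="X", colony="ANM",
            departure=np.datetime64("2015-03-01T00:00:00"),
        )
        with pytest.raises(ValueError, match="no at-sea data"):
            ingest.truncate_to_trip(s, meta2)


class TestSubsample:
    @pytest.mark.parametrize("interval,expect_n", [(1, 10), (2, 20), (4, 40), (8, 80)])
    def test_stride(self, interval, expect_n):
        s = make_series(np.arange(80.0), interval=interval)
        out = ingest.subsample_to_8s(s)
        assert len(out) == expect_n
        if interval < 8:
            assert out.sampling_interval == 8.0
            # output is a subset of input, phase-anchored at the first sample
            assert out.depth[0] == s.depth[0]
            assert set(out.depth).issubset(set(s.depth))

    def test_5s_ll_not_subsampled(self):
        s = make_series(np.arange(80.0), interval=5, manufacturer=Manufacturer.LL)
        out = ingest.subsample_to_8s(s)
        assert len(out) == 80
        assert out.sampling_interval == 5


class TestMergeLocations:
    def _fix(self, sec, qc="1", source=Source.ARGOS, lat=40.0):
        return LocationFix(
            timestamp=T0 + np.timedelta64(sec, "s"),
            lat=lat, lon=-130.0, quality_class=qc, source=source,
        )

    def test_interleave(self):
        argos = [self._fix(i * 100) for i in range(5)]
        gps = [self._fix(i * 100 + 50, qc="G", source=Source.GPS) for i in range(3)]
        merged = ingest.merge_location_sources(argos, gps)
        assert len(merged) == 8
        t = [f.timestamp for f in merged]
        assert t == sorted(t)

    def test_class_z_removed(self):
        merged = ingest.merge_location_sources([self._fix(0, qc="Z"), self._fix(10)], [])
        assert len(merged) == 1
        assert merged[0].quality_class != "Z"

    def test_duplicates_collapse_and_idempotent(self):
        a = [self._fix(0), self._fix(0), self._fix(5)]
        merged = ingest.merge_location_sources(a, [])
        assert len(merged) == 2
        again = ingest.merge_location_sources(merged, [])
        assert again == merged

    def test_order_insensitive(self):
        a = [self._fix(0), self._fix(100)]
        g = [self._fix(50, qc="G", source=Source.GPS)]
        assert ingest.merge_location_sources(a, g) == ingest.merge_location_sources(
            list(reversed(a)), g
        )


class TestParseToppid:
    @pytest.mark.parametrize(
        "tid,expect",
        [("2004001", (20, 2004, 1)), ("2020125", (20, 2020, 125))],
    )
    def test_valid(self, tid, expect):
        assert parse_toppid(tid) == expect

    @pytest.mark.parametrize("tid", ["20040", "20040011", "20o4001"])
    def test_invalid(self, tid):
        with pytest.raises(ValueError):
            parse_toppid(tid)


def test_l1_to_l2_preserves_depths(meta):
    """Curation ops change membership/timestamps, never depth values."""
    s = make_series(np.arange(200.0), t0=meta.departure - np.timedelta64(80, "s"))
    out = ingest.truncate_to_trip(s, meta)
    surviving = np.isin(s.time, out.time)
    np.testing.assert_array_equal(s.depth[surviving], out.depth)
    sub = ingest.subsample_to_8s(make_series(np.arange(64.0), interval=2))
    pairs_in = set(zip(make_series(np.arange(64.0), interval=2).seconds, np.arange(64.0)))
    assert set(zip(sub.seconds, sub.depth)).issubset(pairs_in)
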