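"""Package a processed deployment as the two-file netCDF-4 layout.

Writes `<TOPPID>_TrackTDR_RawCurated.nc` (Levels 1 & 2) and
`<TOPPID>_TrackTDR_Processed.nc` (Level 3), then reads them back and
verifies the arrays survive the round trip.
"""

import tempfile
from pathlib import Path

import numpy as np

from sealproc.ncio import read_bundle, write_processed, write_rawcurated
from sealproc.simulate import make_demo_deployment

bundle, _ = make_demo_deployment(seed=0)
with tempfile.TemporaryDirectory() as d:
    p_raw = write_rawcurated(bundle, d)
    p_proc = write_processed(bundle, d)
    print(f"wrote {p_raw.name}  ({p_raw.stat().st_size / 1024:.0f} kB)")
    print(f"wrote {p_proc.name}   ({p_proc.stat().st_size / 1024:.0f} kB)")

    back = read_bundle(p_proc)
    same_track = np.array_equal(back.track["lat"], bundle.track["lat"])
    same_depth = np.array_equal(
        read_bundle(p_raw).raw_tdr[0].depth, bundle.raw_tdr[0].depth
    )
    print(f"TRACK/LAT round-trips exactly: {same_track}")
    print(f"RAW_TDR1/DEPTH round-trips exactly: {same_depth}")
    print(f"groups in processed file: TRACK, TDR1"
          f"{', TDR1_8S' if bundle.dive_stats_8s[0] is not None else ''}")
print()
print("Deployment metadata and QC flags travel as global attributes; data")
print("live in netCDF-4 groups so a user can read TRACK/LAT, TRACK/LON and")
print("TRACK/DATE to map a trip without touching the full dive record.")
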