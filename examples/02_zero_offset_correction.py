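"""Zero-offset correction of a drifting depth record.

Simulates a week-long dive record whose pressure sensor drifts by +4 m,
with occasional single-sample spikes, then runs the windowed ZOC and
reports how well the per-window surface offsets track the injected drift.
"""

import numpy as np

from sealproc.simulate import DiveSimConfig, generate_dive_record
from sealproc.types import as_seconds
from sealproc.zoc import refine_tolerance, zero_offset_correct

cfg = DiveSimConfig(n_dives=300, drift=("linear", 4.0), spike_rate_per_h=0.5)
series, truth = generate_dive_record(cfg, seed=0)
result = zero_offset_correct(series)

t0 = series.seconds[0]
errs = []
for w0, off in result.window_offsets:
    mid = float(as_seconds(np.array([w0]))[0]) - t0 + 3600.0
    errs.append(abs(off - float(truth.drift_fn(np.array([mid]))[0])))
errs = np.array(errs)

surface = np.abs(result.corrected.depth[series.depth < 10])
print(f"record span:                  {(series.seconds[-1] - t0) / 86400:.1f} days")
print(f"2-h windows:                  {len(result.window_offsets)}")
print(f"offset error vs true drift:   max {errs.max():.2f} m "
      f"({100 * (errs <= series.depth_resolution).mean():.0f}% within the "
      f"{series.depth_resolution:g} m sensor step)")
print(f"refinement tolerance:         {refine_tolerance(series.depth_resolution):g} m "
      f"(15 × {series.depth_resolution:g} m resolution)")
print(f"corrected surface |depth|:    median {np.median(surface):.2f} m")
print()
print("After correction the sea surface reads 0 m everywhere, so the dive")
print("detector can use a fixed threshold despite the sensor drift.")
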