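# sealproc

Processing pipeline for pinniped biologging data: time-depth-recorder
(TDR) harmonization and zero-offset correction, dive detection and
statistics, satellite-track curation and state-space interpolation, dive
geolocation, quality-control flagging, and netCDF-4 packaging.

The package targets the kind of multi-year tagging program run on
northern elephant seals (*Mirounga angustirostris*): each deployment
yields a multi-month depth series from one to three TDRs (Wildlife
Computers, SMRU, or Little Leonardo tags, sampling every 1–8 s) plus
Argos and FastLoc-GPS location estimates. Raw records are noisy — the
pressure sensor drifts, Argos positions carry kilometer-scale
class-dependent errors, tags die at sea — and the scientific products
(dive tables, regular tracks) require a reproducible, quality-controlled
chain from decoded files to archived netCDF. `sealproc` implements that
chain as a tested library with a thin CLI, and ships a synthetic-data
generator so every stage can be verified against ground truth without any
archived tag data.

## Methods at a glance

**Zero-offset correction (ZOC).** Depth spikes implying vertical speeds
above 5 m/s on both flanks are replaced by neighbor interpolation, and
samples outside a realistic range (−10 m to 2,200 m by default) are
dropped. Within each two-hour window the approximate surface is the mode
of readings between the range minimum and 15 m, binned at the sensor
resolution. Surfaces at each dive's start and end are then refined, but
must lie within 15 sensor counts of the window estimate (7.5 m for a
0.5 m-resolution instrument). Corrected depth is `d(t) − offset(t)`.

**Dive analysis.** A dive is a submerged excursion with maximum depth
≥ 25 m and duration ≥ 32 s. Descent ends and ascent begins at smoothed
vertical-speed inflections; the bottom phase is additionally constrained
deeper than 50% of the dive's maximum depth. Per-dive statistics include
phase durations, mean descent/ascent rates, bottom range, wiggle count,
and post-dive interval; dives with a 0-s post-dive interval are merged
with their successor, and rows with rates > 3 m/s or durations > 150 min
are moved out of the Level 3 table.

**Track model.** Curated fixes (colony anchors at class "G", on-land
fixes removed against a bathymetry grid, a 3 m/s great-circle speed
filter) feed a continuous-time correlated random walk. Per planar axis
the velocity is Ornstein–Uhlenbeck,

    dv = −β v dt + σ dW,      dx = v dt,

with exact discretization over irregular fix intervals; measurement SDs
come from the Argos quality class (250 m for class 3 up to 10 km for
class B; 50 m for GPS-grade fixes). (β, σ) are estimated by maximizing
the Kalman-filter likelihood; the Rauch–Tung–Striebel smoother emits
positions and standard errors on an exact 3-hour grid.

**Dive geolocation and QC.** Each dive start is linearly interpolated
(coordinates and standard errors, common weight) between the two nearest
track points, and the solar elevation at that time and place is computed
from a standard analytic ephemeris. Tracks and dive records receive
integer 1–5 quality flags from the location rate, largest gap, and
instrument-malfunction indicators.

**Packaging.** Each deployment becomes two netCDF-4 files —
`<TOPPID>_TrackTDR_RawCurated.nc` (Levels 1–2) and
`<TOPPID>_TrackTDR_Processed.nc` (Level 3) — with data in groups
(`RAW_TDR1`, `CURATED_LOCATIONS`, `TRACK`, `TDR1`, `TDR1_8S`, …) and
metadata plus QC flags in global attributes. See `docs/netcdf_schema.md`.

## Worked example

Fit the track model to a simulated deployment with known parameters:

```sh
python examples/04_track_interpolation.py
```

```
fixes simulated: 238   after 3 m/s speed filter: 182
beta  (1/s): true 0.0001   fitted 9.28e-05 (7.2% off)
sigma       : true 0.0141   fitted 0.0129 (8.8% off)
predicted locations: 238 at exactly 10800 s spacing
position SE: median 4.0 km, max inside the 1-day gap 18.0 km
```

The fitted β (velocity decorrelation rate) and σ (process-noise scale)
recover the simulation truth to within ~10% from 30 days of Argos-class
noisy fixes; the interpolated track lands on an exact 3-hour grid, and
the standard errors swell inside the one-day observation gap, flagging
the low-confidence stretch. The other scripts in `examples/` walk
through ingestion, ZOC, dive analysis, geolocation/QC, and netCDF
packaging the same way, each printing the numbers it computes.

A full deployment can also be processed from the shell:

```sh
sealproc run --seed 0 --out-dir out/   # simulate + process + package
sealproc zoc --in L2.csv --out ZOC.csv
sealproc dives --in ZOC.csv --out DiveStat.csv
```

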