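# netCDF-4 deployment file schema

Two files per deployment, linked by the 7-digit TOPPID (digits 1–2:
species code, 3–4: year − 2000, 5–7: deployment serial):

| file | contents |
|---|---|
| `<TOPPID>_TrackTDR_RawCurated.nc` | Levels 1–2: decoded and curated depth series and location fixes |
| `<TOPPID>_TrackTDR_Processed.nc` | Level 3: interpolated track and per-TDR dive-statistics tables |

All datetimes are `float64` seconds since 1970-01-01 UTC (`units`
attribute on every DATE variable). Missing values: `NaN` (floats),
`-9999` (integers, declared via `_FillValue`). Every data group carries
a `DATE` variable; readers must reject files where one is absent.

## Global attributes (both files)

`TOPPID`, `Animal_ID`, `All_TOPPIDs` (comma-separated, every deployment
of this individual), `Colony`, `Colony_Lat`, `Colony_Lon`, `Departure`,
`Arrival` (ISO-8601; empty when unknown), `Trip`, `QC_Track`,
`QC_Track_Comment`, and per record `QC_TDRn` / `QC_TDRn_Comment`.

## RawCurated groups

* `RAW_TDRn` (n = 1..3, best record first; quality ties favor Wildlife
  Computers): `DATE`, `DEPTH` (m, positive down); group attributes
  `sampling_interval` (s), `depth_resolution` (m), `manufacturer`
  (WC/SMRU/LL), `instrument_id`.
* `CLEAN_TDRn`: same layout, Level 2 (curated). Absent for records
  flagged quality 4 — those keep raw data only.
* `RAW_LOCATIONS`, `CURATED_LOCATIONS`: `DATE`, `LAT`, `LON`, `LC`
  (quality class string: 3/2/1/0/A/B/Z/G), `SOURCE` (ARGOS/GPS/ANCHOR),
  `ERROR_SEMI_MAJOR` (m, NaN when unavailable).

## Processed groups

* `TRACK`: `DATE` (exact 3-h grid), `LAT`, `LON` (degrees), `LAT_SE`,
  `LON_SE` (m, smoothed-state standard errors).
* `TDRn` and, when the native rate divides 8 s, the subsampled twin
  `TDRn_8S`: one element per dive —
  `DIVE_NUMBER`, `DATE` (= dive start), `START`, `END`, `DURATION` (s),
  `MAX_DEPTH` + alias `MAXDEPTH` (m), `DESCENT_DURATION`,
  `BOTTOM_DURATION`, `ASCENT_DURATION` (s), `DESCENT_RATE`,
  `ASCENT_RATE` (m/s), `BOTTOM_RANGE` (m), `WIGGLES` (count), `PDI`
  (post-dive interval, s), `LAT`, `LON` (degrees, interpolated dive
  start), `LAT_SE`, `LON_SE` (m), `SOLAR_ELEVATION` (degrees).

The `MAXDEPTH`/`DATE` aliases in dive groups exist so a track-style
reader (`DATE`, `LAT`, `LON`, `MAXDEPTH`) can map dive positions without
knowing the full table layout.
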