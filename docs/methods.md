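# Methods

This note records the models, algorithmic choices, and defaults behind
each pipeline stage, the assumptions the synthetic-data generator makes,
and the known limitations.

## Data model and levels

Depth series (`TDRSeries`) carry UTC timestamps, depths in meters
positive down, the nominal sampling interval, and the sensor resolution
(meters per count). Location fixes carry an Argos quality class
(3/2/1/0/A/B/Z) or "G" for GPS-grade points, including the colony
anchors added during curation. Data move through three levels: decoded
(L1), curated (L2: haulouts filled, clocks corrected, trimmed to the
at-sea window), and derived (L3: dive statistics and the interpolated
track). L1→L2 operations never alter depth values, only membership and
timestamps — a property the test suite asserts directly.

## Ingestion and harmonization

* **SMRU haulout filling.** SMRU tags suspend logging while dry; gaps
  are filled with zero-depth samples on the tag's own grid, anchored at
  the gap start. Gaps that are not grid-alignable are filled on the
  anchored grid and the residual is logged rather than silently
  redistributed.
* **Little Leonardo clock correction.** LL tags need a per-record time
  offset (including local→UTC) and a small linear "compression" of
  elapsed time. The compression is applied as an affine map anchored at
  the record start (the anchor is a package choice — the convention is
  not standardized — and is documented here so records corrected
  elsewhere can be compared). Estimating the offset/compression is left
  to the caller: it requires a reference record from the same animal.
* **Subsampling.** 1/2/4-s records are decimated to 8 s by index stride,
  phase-anchored at the first sample; 5-s records do not divide 8 s and
  pass through unchanged. Subsampled output is an exact subset of the
  input samples.
* **Duplicate fixes** are collapsed on the key (source, timestamp, lat,
  lon); class-Z (non-converged) fixes never reach Level 2.

## Zero-offset correction

The despike rule targets isolated one- or two-sample excursions entered
and exited faster than 5 m/s with opposite flank signs; sustained fast
segments are real swimming and are left alone. Spikes are *replaced* by
neighbor interpolation rather than deleted so the sampling grid stays
regular.

Surface estimation uses fixed, non-overlapping two-hour windows anchored
at the record start. Within a window, candidate samples lie between the
configured minimum depth and the 15 m ceiling; the offset is the mode of
candidates binned at exactly the sensor resolution, with ties broken
toward the shallower bin (a conservative surface). Windows without
candidates (continuous deep diving) inherit the previous window's
offset; leading empty windows inherit the first available one.

Refinement then assigns each *surface interval* (the stretches between
provisional dives, detected as excursions beyond the ceiling relative to
the window offset) its own surface: the interval's minimum depth,
accepted only within 15 × resolution of the window offset, otherwise the
window offset stands. Inside a dive the offset interpolates linearly
between the bounding intervals' surfaces. This per-interval scheme
guarantees that every surface interval contains a sample corrected to
exactly 0 m, which keeps consecutive dives separated even when drift
quantization leaves other surface samples half a count high. Negative
corrected depths are preserved in the output (information preservation);
the dive detector clips them to zero.

The advisory `suggest_min_depth` flags records whose sensor persistently
reads above the surface: if at least 0.1% of samples (configurable — the
notion of "frequently occurring" is inherently a judgment call) lie
below the default minimum, the 1st percentile of those readings, floored
to the resolution, is suggested as the new minimum.

## Dive analysis

Detection treats readings within one sensor count of zero as surface:
after correction the residual surface error is at most the quantization
step, and a threshold of one count makes boundary placement robust
without affecting the 25 m depth criterion. Both dive criteria are
inclusive (≥ 25 m, ≥ 32 s); dive start/end indices are the bounding
surface samples, so duration is surface-to-surface.

Phase segmentation smooths per-sample vertical speed with a 3-sample
moving mean; descent ends where smoothed speed first drops below 75% of
the initial descent rate, ascent begins at the mirror point, and the
bottom phase is clipped to the contiguous block of samples deeper than
50% of maximum depth that contains the deepest sample. When the
speed-based bottom collapses to the immediate neighborhood of the apex
the dive is treated as V-shaped with a single-sample bottom. The 75%
fraction is configurable; only the 50%-depth constraint is a hard
contract (asserted per dive in the tests).

A *wiggle* is one complete up-and-down oscillation in the bottom phase
with both legs of amplitude ≥ 2 × resolution. The post-dive interval is
start-of-next-dive minus end-of-dive, in seconds. Zero-PDI merging
recomputes statistics over the merged span from the corrected series,
not by averaging the old rows, and iterates until no zero PDIs remain.
The Level 3 plausibility filter removes rows *strictly* above 3 m/s or
150 min; exact-threshold values are kept.

## Track model

The CTCRW is the standard integrated Ornstein–Uhlenbeck velocity model,
per axis: state (x, v) with dv = −βv dt + σ dW and exact transition
matrices

    F = [[1, (1−e^{−βΔ})/β], [0, e^{−βΔ}]]

and the matching process covariance, so irregular fix intervals cost
nothing. Positions are filtered in a local azimuthal-equidistant plane
centered on the track centroid (spherical formulas, R = 6371.0088 km);
at ocean-basin scale the distortion is far below Argos noise. Both axes
share (β, σ); the likelihood is the sum of two axis-wise Kalman-filter
likelihoods and is maximized by Nelder–Mead in log-parameter space from
a fixed start (β₀ = 10⁻⁴ s⁻¹, σ₀ = 0.02), making refits deterministic.
Measurement SDs default to the nominal class error radii — 250/500/1500 m
for classes 3/2/1, 5 km for 0 and A, 10 km for B, 50 m for G — and an
error-ellipse semi-major axis overrides the class default when present.

Prediction inserts the regular grid times (anchored at the first fix,
3-h spacing) as missing observations and runs the RTS smoother; standard
errors are square roots of smoothed position variances, reported in
meters. The smoother's variance necessarily peaks inside observation
gaps — a property the tests assert rather than assume.

The speed filter removes, while any segment exceeds 3 m/s, the non-anchor
fix whose removal most reduces the violation count, evaluating each
candidate locally (its two adjacent segments are replaced by one bridging
segment). On small tracks the greedy result is validated against
exhaustive subset search. Colony anchors are immune; emptying the
non-anchor track is an error. The model is re-fit only when explicitly
requested after manual outlier removal (`--refit` workflow), mirroring
the inspect-and-rerun loop such programs use.

## Dive geolocation and solar position

Interpolation is linear in degrees (longitudes unwrapped across ±180°)
with one weight shared by latitude, longitude, and both standard errors;
at 3-h track spacing the difference from great-circle interpolation is
negligible for this application. Variance-correct SE interpolation
(interpolating σ² rather than σ) is a documented alternative; the linear
form matches how the errors accompany the coordinates downstream. Dives
outside the track's time span are clamped to the nearest endpoint and
flagged `extrapolated` rather than dropped, preserving row count.

Solar position uses the standard low-precision Keplerian ephemeris (mean
longitude/anomaly, first-order eccentric-anomaly correction, ecliptic
obliquity, right ascension/declination, local hour angle), without
refraction. Against an independent NOAA-formulation oracle (Julian
centuries, equation of center, nutation-corrected obliquity, equation of
time) the elevation agrees within ~0.012° over 2004–2020 — two orders of
magnitude tighter than any day/night classification needs.

## Quality control

Track flags: 5 = no fixes; 4 = under 2 locations/day averaged over the
data-collection period (departure to last fix, so days after a dead tag
don't count); otherwise 1/2/3 by the largest inter-fix gap (≤ 24 h /
≤ 2 days / > 2 days, with "up to 2 days" read as inclusive). Dive-record
flags use the same gap ladder, where a gap is an inter-sample interval
exceeding twice the sampling interval, and malfunction indications can
raise the flag: "minor" (severity 1) caps the record at flag 2,
"substantial" (severity 2) forces flag 4. The severity thresholds encode
what an experienced analyst flags by eye: > 10% of dives under 60 s is
minor; repeated identical deep maximum depths (> 20 occurrences deeper
than 200 m) or a spike burst (sliding 24-h spike density > 10× the
record's baseline) is substantial. A spike burst also yields a suggested
truncation time so the clean head of the record can be reprocessed —
after which the record is flagged 3 (incomplete).

## netCDF packaging

Two files per deployment, named `<TOPPID>_TrackTDR_RawCurated.nc` and
`<TOPPID>_TrackTDR_Processed.nc`. Variable names are upper-case inside
groups (full inventory in `docs/netcdf_schema.md`); datetimes are stored
as double seconds since 1970-01-01 UTC with a units attribute; missing
values are NaN for floats and −9999 for integers, declared per variable.
TDR records are published best-first (lowest QC flag, ties to Wildlife
Computers tags, then original order); records flagged 4 keep their raw
group but get no curated group or Level 3 products. Round-trip equality
of every array and attribute is property-tested on random bundles.

## Synthetic data

The generator's defaults emulate an adult female elephant seal on a
foraging trip: dives built on the sampling grid (8 s, 0.5 m resolution)
with depths drawn from a mixture peaking near 500 m (97% normal around
the mode, 3% exponential tail, clipped to 100–1500 m), descent/ascent
speeds of 0.8–1.5 m/s, bottom phases of 5–15 min in U/square/V shape mix
(60/25/15%), and 2–3.3 min surface intervals — giving ~10% surface time,
consistent with a deep-diving phocid. Tracks are simulated from the
exact CTCRW transition density (β = 10⁻⁴ s⁻¹, i.e. a ~2.8-h velocity
decorrelation time; σ chosen for ~1 m/s RMS speed, a transiting seal's
pace) and observed at Poisson times averaging 8 fixes/day — the typical
Argos yield for a surfacing seal — with class-dependent Gaussian noise
under a realistic class mix (10/10/15/15/25/25% for 3/2/1/0/A/B).

Because dives are constructed sample-by-sample on the grid, the truth
table is exact by construction, which is what lets the acceptance checks
demand exact dive counts and sub-resolution depth agreement. What the
generator does **not** emulate: tidal and sea-state surface noise,
temperature-dependent sensor drift (drift is injected as linear or
piecewise-constant), behaviorally structured movement (haulout timing,
area-restricted search), Argos error ellipses' anisotropy, or the
long-tailed non-Gaussian Argos error distribution. Passing tests
demonstrate the algorithms' correctness under the stated error models,
not performance on every real-world pathology; the QC stage exists
precisely because real records contain surprises.

Problem sizes used in tests and the acceptance script — records of
300–1000 dives (5–20 simulated days), tracks of ~500 fixes over ~60
days, 20 replicate fits, 10,000 randomized QC configurations, 50 random
netCDF bundles — were chosen so the whole verification chain exercises
every stage at statistically meaningful scale while remaining quick to
run on a single CPU.

## Known limitations

* Little Leonardo offset/compression estimation is out of scope; values
  are supplied per record.
* The bottom-phase and wiggle definitions are reasonable published-style
  interpretations; programs with their own supplementary definitions
  should reconcile before cross-study comparisons.
* The CTCRW is fit with a single (β, σ) per track; behavioral-state
  switching and move-persistence models are out of scope.
* Land masking requires the caller's bathymetry grid; none is bundled.
* Pressure-to-depth conversion and thermal sensor compensation are
  assumed done upstream by the manufacturer's decoding.
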