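# Methods

This note documents the models behind `phenosense`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the package's known limitations.

## Canonical representation and time

All data flow through one long-form table: `(timestamp, node_id, channel,
value, flag)` with a controlled channel vocabulary (`par_in`, `par_out`,
`sw_in`, `sw_out`, `air_temp`, `rel_hum`, `soil_moist`, `rain`) and exactly
one quality flag per record (`ok`, `out_of_range`, `malformed`, `gap`,
`failed_sensor`). Timestamps are naive **local standard time**; the library
never applies daylight-saving rules, because field loggers are configured to
standard time year-round and DST transitions are precisely the clock errors
the time-QA stage exists to catch. Interval samples are stamped at the
interval **start**, and aggregation buckets are labelled by their start, so
instantaneous and aggregated series align without off-by-one conventions.

The quantum conversion between shortwave energy and photon flux in the PAR
band is fixed package-wide at **4.57 µmol J⁻¹** (the McCree constant). The
same constant is used when synthesising data and when deriving indexes, so
pipeline round-trips are exact by construction; its absolute accuracy
(±~2 % across sky conditions) only matters if phenosense values are compared
against externally calibrated fluxes.

## Solar geometry

Zenith angle, solar noon and sunrise use the standard low-precision
NOAA-calculator algorithm: Spencer's Fourier series in the fractional-year
angle for declination and the equation of time, then the hour-angle form of
the zenith. Sunrise is the crossing of the −0.833° standard altitude
(semi-diameter + mean refraction). Accuracy is a few tenths of a degree in
zenith and ~1–2 min in sunrise — two orders of magnitude below the
whole-hour resolution of the clock check. Polar day/night dates are flagged
(`SunTimes.polar`) rather than raised, and the zenith function is total.

## Clock-shift estimation

* **Observed sunrise**: the day's irradiance series is smoothed with a
  3-sample centred moving average; sunrise is the first timestamp where the
  smoothed value exceeds `max(5 W m⁻², 2 % of the day's maximum)` and stays
  above it for 2 consecutive samples. The dual criterion tolerates small
  sensor offsets (absolute floor) and dim overcast days (relative floor);
  the persistence requirement rejects single-sample spikes. For PAR
  channels the absolute floor is quantum-converted (≈22.9 µmol m⁻² s⁻¹).
* **Estimate**: shift = median daily `(observed − expected)`, rounded to the
  nearest whole hour. The median resists a minority of late (overcast)
  mornings. The estimate is refused below 3 usable days, and when the
  interquartile range of the daily offsets exceeds **30 min** — the IQR was
  chosen over the median absolute deviation because a near-half mixture of
  conflicting offsets (e.g. alternating shifts) drives the MAD to zero while
  the IQR exposes it.
* **Scope**: the detector triggers a few minutes to ~one sampling interval
  *after* geometric sunrise (threshold lag + grid quantisation), a bias of
  roughly +5 to +25 min at 15-min sampling. This is why the method corrects
  whole hours only: the residual per-day offsets are reported
  (`ShiftEstimate.residuals_min`) but sub-hour drift is never "corrected",
  since the detection bias would be folded into the correction.
* `apply_shift` translates timestamps by −shift and appends the correction
  to the table's provenance; it is the identity at shift 0 and re-estimation
  after application returns 0.

## Ingestion policy

Vendors do not publish stable file layouts, so the package defines two
exemplar dialects — a wide single-node "tower logger" CSV and a long
multi-node "wireless export" TSV — plus a registration hook for new ones.
These exemplars are documented stand-ins, not reverse-engineered vendor
formats. Format sniffing requires a *unique* fully consistent dialect and
otherwise fails loudly, listing which checks failed per dialect; it never
guesses.

Parsing is **total** and follows a quarantine-not-repair policy: wrong
column counts, unparseable fields, unknown channels and timestamp
regressions put the whole physical record in the report (index, kind,
message) and never in the table. Missing-value sentinels become explicit
`gap` records. Merging tables resolves duplicate `(timestamp, node,
channel)` keys first-wins and reports every duplicate as a conflict, because
first-wins is deterministic and auditable where averaging is neither.

## Filters and aggregation

* Physical-range QC uses the sensor datasheet ranges (temperature −40–75 °C,
  RH 0–100 %, PAR 0–2500 µmol m⁻² s⁻¹, shortwave 0–1280 W m⁻², soil
  moisture 0–100 % VWC, rain 0–1270 mm h⁻¹); out-of-range values are
  flagged, never altered. No statistical outlier detection is attempted
  beyond these physical bounds.
* The midday window is half-open `[10:00, 14:00)` so a boundary sample
  belongs to exactly one window; the clear-sky screen keeps a record iff the
  same node has simultaneous `par_in` **strictly** greater than
  900 µmol m⁻² s⁻¹ (a value exactly at the threshold is dropped).
* Aggregation emits a bucket only when at least `min_coverage` (default
  0.75) of its expected samples are present; under-covered buckets become
  explicit gaps rather than misleading near-empty means. Monthly buckets use
  the calendar month length.
* Gap reporting returns maximal missing runs on the expected sampling grid
  with exclusive end timestamps, so a sensor failure window `[t0, t1)`
  injected by the generator is reported as exactly `(t0, t1)`.

## Derived products

* **Footprint**: `r = tan(view half-angle) × h`, default half-angle 85°
  (typical full-view radiometer); linear in `h`, strictly increasing in the
  angle, and an error at ≥90°.
* **Broadband reflectances**: PAR is the visible band; NIR is approximated
  as `(shortwave − PAR)` in energy units, i.e. the broadband-radiometer
  two-band methodology. Ratios are undefined below an incoming floor
  (`par_in > 100 µmol m⁻² s⁻¹` and `sw_in > 50 W m⁻²`) because both
  numerator and denominator vanish toward dawn/dusk and the ratio explodes;
  reflectances outside [0, 1] are returned but flagged, since over snow or
  senescent litter they can be legitimate data-quality signals.
* **Indexes**: NDVI and the two-band EVI2 (coefficients 2.5 / 2.4 / 1; no
  blue band exists in the sensor suite, so three-band EVI is impossible).
  Indexes are computed on **filtered instantaneous** records and then
  averaged per day (mean of ratios). The alternative — aggregating fluxes
  first — answers a different question and differs on real data; pinning the
  order here makes daily NDVI well-defined.
* **LAI**: no ecosystem conversion constants ship with the package, because
  the factor is site-characteristic; users supply either a linear factor
  (`LAI = c·max(NDVI, 0)`) or a Beer-law saturating form
  (`LAI = −(1/k)·ln((NDVI_max − NDVI)/(NDVI_max − NDVI_min))`, clipped just
  below NDVI_max).
* **VPD**: Magnus saturation vapour pressure
  `e_s = 0.6108·exp(17.27·T/(T+237.3))` kPa, `VPD = e_s·(1 − RH/100)`;
  inputs must have passed range QC.

## Spatial fields

Node coordinates live in a local planar frame (metres east/north); no
geodetic projection is attempted at deployment scales (≤ a few hundred
metres). Interpolation is inverse-distance weighting with default power
p = 2 and no search cutoff — chosen as the simplest scheme that is exact at
the nodes and a convex combination (hence bounded by the input extremes)
elsewhere; it is pluggable, and kriging is out of scope. Reliability is
defined as *working / installed sensors within the coverage radius* of each
cell (default radius: the radiometric footprint of the sensor height),
where "installed" counts only sensors carrying the mapped channel. Frame
sequences emit one raster per aggregation bucket regardless of failures —
an all-failed bucket yields an all-undefined frame with reliability 0 — so
animation cadence is independent of data quality.

## The synthetic generator

The generator defines the conditions under which the pipeline's guarantees
are tested:

* **Irradiance**: clear-sky shortwave = peak (default 1000 W m⁻²,
  folding top-of-atmosphere flux and a fixed transmittance) × cos(zenith),
  zero below the horizon; PAR = 45 % of shortwave energy,
  quantum-converted. Overcast days (off by default; Bernoulli per day when
  enabled) attenuate by ×0.15, keeping midday PAR below the 900-µmol
  screen.
* **Canopy**: a prescribed NDVI trajectory (default: seasonal sinusoid
  0.2–0.8 peaking near mid-year) is encoded exactly into the tower's
  channels by fixing ρ_PAR = 0.03 (a dense green canopy's visible
  reflectance) and solving ρ_NIR = ρ_PAR (1+NDVI)/(1−NDVI); recomputing
  NDVI from the emitted channels is the inverse operation, exact to machine
  precision before noise.
* **Micro-climate**: sinusoidal diurnal cycles (T = 22 ± 6 °C warmest at
  15:00, RH = 65 ∓ 20 % in anti-phase) with small deterministic per-node
  offsets; the analytic daily mean equals the cycle mean, which the
  aggregation tests exploit.
* **Defects**: whole-hour clock shifts move every emitted timestamp;
  failure windows delete all records of a (node, channel) in `[start, end)`
  (a dead sensor logs nothing); corruption at file-writing time damages a
  seeded random fraction of data records (extra column, missing column, or
  a garbled numeric field) and returns the injected indices as ground
  truth. Noise is multiplicative Gaussian per channel (relative SD), off by
  default. All randomness comes from one required, logged seed.
* **Default site**: a tropical dry-forest location (14.85° S, 43.97° W,
  UTC−3) typical of where such deployments run; sunrise there is steep
  year-round, which is representative of tropical deployments but means the
  clock-shift recovery tests do not probe high-latitude winter dawns.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: aerosol/airmass effects and broken-cloud
radiation spikes, sensor drift and calibration decay, canopy heterogeneity
within the footprint, rainfall and wind, and realistic vendor file layouts.
The guarantees that survive contact with real data are the structural ones
(accounting invariants, quarantine totality, filter semantics, whole-hour
shift recovery under clear mornings); the exact NDVI round-trip is a
self-consistency check, not a field validation.

## Problem sizes and tolerances

The test suite and acceptance script run on deliberately small problems:
7-day × 15-min deployments (a few thousand records), 140 seeded trials for
shift recovery (7 shifts × 20 seeds), 1,000-record corruption accounting,
and ~20 × 10 cell rasters. These sizes already exercise every code path;
the algorithms are vectorised and scale linearly in records and grid cells.
Numeric tolerances: NDVI round-trip ≤ 1e−6 noise-free (pure float
arithmetic), 3 standard errors under 2 % channel noise; solar sanity checks
at almanac precision (±10 min sunrise, ±1° zenith); everything else exact
or at 1e−9-scale floating-point slack.

## Known limitations

* Two exemplar dialects only; real vendor exports need a registered dialect.
* The sunrise detector assumes at least a handful of clear mornings; a week
  of uniform overcast refuses an estimate rather than guessing.
* Reliability maps use a binary working/failed notion per bucket; partial
  degradation (drifting but reporting sensors) is invisible to it.
* `fAPAR`-style spatial products and statistical despiking are out of scope.
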