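# phenosense

QA/QC and derived-product pipeline for **ground-based phenology and
micro-climate sensor deployments**: phenology towers carrying paired
up/down-looking radiometers over a forest canopy, plus understory wireless
nodes measuring air temperature and relative humidity. It is written for the
people who run such deployments — field ecologists and the data managers of
environmental sensor networks — whose raw material is a pile of delimited
logger exports with misconfigured clocks, failed sensors and structurally
corrupted records.

## What it does

1. **Ingestion** (`phenosense.ingest`) — sniffs the logger dialect, parses
   records into a canonical long-form table `(timestamp, node, channel,
   value, flag)`, and *quarantines* rather than repairs anything malformed
   (extra/missing columns, garbled fields, timestamp regressions), so that
   `accepted + quarantined = total` always. Every ingestion produces a
   provenance report (source, dialect, user, options, per-defect messages).
2. **Time QA** (`phenosense.time_qa`) — detects whole-hour clock shifts by
   comparing the sunrise observed in the radiation channels against the
   astronomically expected sunrise over several days:

   shift = round(median over days of (t_observed − t_expected) / 1 h)

   The estimate is refused when fewer than 3 days are usable or the
   interquartile range of the daily offsets exceeds 30 min. Sub-hour
   hardware drift is reported but deliberately never corrected.
3. **Filters and aggregation** (`phenosense.series_ops`) — datasheet
   physical-range QC, midday clock window (default half-open
   [10:00, 14:00)), clear-sky screening (keep records only when simultaneous
   incoming PAR > 900 µmol m⁻² s⁻¹, strict), coverage-aware
   hourly/daily/monthly aggregation, and gap reporting.
4. **Derived products** (`phenosense.products`) — broadband reflectances
   ρ_PAR = PAR↑/PAR↓ and ρ_NIR = (SW↑ − PAR↑)/(SW↓ − PAR↓) (PAR in energy
   units via 4.57 µmol J⁻¹), then

   NDVI = (ρ_NIR − ρ_PAR)/(ρ_NIR + ρ_PAR),
   EVI2 = 2.5 (ρ_NIR − ρ_PAR)/(ρ_NIR + 2.4 ρ_PAR + 1),

   LAI from NDVI via a user-supplied ecosystem conversion, VPD from the
   Magnus formula, and the radiometer footprint radius
   r = tan(view half-angle) × h.
5. **Spatial maps** (`phenosense.spatial`) — transect/star/grid node
   layouts, inverse-distance-weighted fields (exact at nodes, bounded by
   input extremes), and a co-registered **reliability** layer: per cell, the
   fraction of in-range sensors that are working.
6. **Synthetic deployments** (`phenosense.synth`) — a first-class generator
   of clear-sky diurnal irradiance, prescribed NDVI trajectories, diurnal
   temperature/RH cycles, and injected defects (clock shifts, failure
   windows, record corruption), so the whole pipeline is testable with no
   external data.

## Worked example

Generate five days of synthetic tower data with a +2 h clock
misconfiguration, ingest it, check the clock, and derive daily NDVI:

```sh
phenosense synth --days 5 --seed 3 --shift 2 --out tower.csv --truth truth.yaml
phenosense ingest tower.csv --dialect auto --out canon.csv --report report.yaml
phenosense timecheck canon.csv --lat -14.85 --lon -43.97 --utc-offset -3
phenosense derive --product ndvi --input canon.csv
phenosense derive --product footprint --height 5
```

prints

```
wrote tower.csv (1920 readings, 0 corrupted records)
tower.csv: dialect=tower_wide total=480 accepted=480 quarantined=0
verdict: shift +2 h (5 days, dispersion 0.4 min)
      date    value  n_samples
2021-05-01 0.606103         15
2021-05-02 0.610917         15
2021-05-03 0.615699         15
2021-05-04 0.620446         15
2021-05-05 0.625158         15
footprint radius: 57.15 m (h=5.0 m, 85.0 deg)
```

Reading the output: the dialect was identified automatically and all 480
physical records (5 days × 96 × one wide row carrying 4 channels) were
accepted; the sunrise comparison recovered the injected +2 h shift with a
0.4 min spread across days; the daily NDVI values reproduce the generator's
prescribed seasonal green-up trajectory (0.606 → 0.625 over these five
days of early green-up); and a radiometer 5 m above the canopy integrates a
ground disc of radius tan(85°) × 5 m = 57.15 m, which is why such masts
cover at least 50 m of canopy.

The same pipeline is available as a library — see
`phenosense.products.daily_ndvi` for the full chain in one call and
`phenosense.time_qa.estimate_clock_shift` / `apply_shift` for clock
correction.

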