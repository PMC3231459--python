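"""Synthetic deployments and logger files for end-to-end pipeline testing.

No public archive of raw logger exports exists for this kind of deployment,
so the package carries its own generator. It emulates the structure every
downstream stage assumes:

* clear-sky diurnal irradiance (incoming shortwave + PAR) from the solar
  geometry in :mod:`phenosense.solar`, with optional overcast days;
* a phenology-tower radiation quad (par_in/par_out/sw_in/sw_out) whose
  reflectance ratios encode a prescribed seasonal NDVI trajectory exactly
  (before noise), so index derivation can be tested against ground truth;
* understory air-temperature / relative-humidity diurnal cycles per node;
* injected defects: whole-hour clock shifts, sensor failure windows, and
  structural record corruption at file-writing time.

Everything is driven by one seeded :class:`numpy.random.Generator`; identical
configuration + seed reproduces identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import solar
from .types import (
    CHANNELS,
    QUANTUM_UMOL_PER_W,
    DeploymentGeometry,
    PhenosenseError,
    SiteLocation,
    make_series_table,
)

#: Irradiance attenuation applied on overcast days. Keeps midday PAR well
#: below the 900 umol m-2 s-1 clear-sky screening threshold.
OVERCAST_FACTOR = 0.15

#: Baseline PAR-band (visible) canopy reflectance used when encoding an
#: NDVI trajectory; green canopies absorb strongly in the visible.
RHO_PAR_BASELINE = 0.03


def default_ndvi_trajectory(doy: float) -> float:
    """Seasonal canopy green-up: NDVI 0.2-0.8 peaking near mid-year."""
    return 0.5 + 0.3 * np.sin(2.0 * np.pi * (doy - 100.0) / 365.0)


def default_site() -> SiteLocation:
    """A tropical dry-forest site (southern hemisphere, UTC-3, no DST)."""
    return SiteLocation(latitude=-14.85, longitude=-43.97, utc_offset_hours=-3)


@dataclass
class SynthConfig:
    """Parameters of the synthetic deployment.

    ``noise_sd`` maps channel name to a *relative* Gaussian noise standard
    deviation (0.02 = 2% of the instantaneous value); channels absent from
    the map are noise-free.
    """

    random_seed: int
    start_date: str = "2021-05-01"
    n_days: int = 7
    sampling_interval: int = 15  # minutes; typical logger configuration
    clear_sky_peak_shortwave: float = 1000.0  # W m-2
    par_fraction: float = 0.45  # PAR share of shortwave energy
    canopy_ndvi_trajectory: Callable[[float], float] = default_ndvi_trajectory
    cloudy_day_probability: float = 0.0
    noise_sd: dict = field(default_factory=dict)
    mean_air_temp: float = 22.0  # degC
    diurnal_temp_amplitude: float = 6.0  # degC
    mean_rel_hum: float = 65.0  # %
    diurnal_rh_amplitude: float = 20.0  # %

    def __post_init__(self):
        if 1440 % self.sampling_interval != 0:
            raise PhenosenseError("sampling_interval must divide 1440 minutes")
        if not 0.0 < self.par_fraction < 1.0:
            raise PhenosenseError("par_fraction must be in (0, 1)")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise PhenosenseError("noise SDs must be >= 0")
        if not 0.0 <= self.cloudy_day_probability <= 1.0:
            raise PhenosenseError("cloudy_day_probability must be in [0, 1]")


@dataclass
class DefectSpec:
    """Defects injected into the synthetic deployment."""

    clock_shift_hours: int = 0
    #: list of (node_id, channel, start, end): the sensor logs nothing in
    #: the half-open window [start, end).
    failure_windows: list = field(default_factory=list)
    corruption_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise PhenosenseError("corruption_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    ndvi_by_date: dict  # ISO date -> prescribed NDVI
    clock_shift_hours: int
    failure_windows: list  # (node_id, channel, start ISO, end ISO)
    cloudy_dates: list
    rho_par_baseline: float
    random_seed: int

    def to_dict(self) -> dict:
        return {
            "ndvi_by_date": dict(self.ndvi_by_date),
            "clock_shift_hours": self.clock_shift_hours,
            "failure_windows": [list(w) for w in self.failure_windows],
            "cloudy_dates": list(self.cloudy_dates),
            "rho_par_baseline": self.rho_par_baseline,
            "random_seed": self.random_seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)


def make_clear_sky_day(site: SiteLocation, date, cfg: SynthConfig) -> pd.DataFrame:
    """One day of clear-sky incoming shortwave and PAR at the site.

    The irradiance model is a top-of-atmosphere constant times a fixed
    transmittance, folded into ``clear_sky_peak_shortwave``, times the
    cosine of the solar zenith (zero when the sun is below the horizon):
    sufficient to exercise sunrise detection and cloud screening, with no
    aerosol or airmass realism intended.

    Returns a frame with columns ``timestamp, sw_in, par_in`` (W m-2 and
    umol m-2 s-1); ``frame.attrs['polar']`` is ``'polar_night'``,
    ``'midnight_sun'`` or ``None``.
    """
    d = pd.Timestamp(date).normalize()
    times = pd.date_range(d, periods=1440 // cfg.sampling_interval,
                          freq=f"{cfg.sampling_interval}min")
    zen = solar.solar_zenith(site, times)
    cosz = np.clip(np.cos(np.radians(zen)), 0.0, None)
    sw = cfg.clear_sky_peak_shortwave * cosz
    par = cfg.par_fraction * sw * QUANTUM_UMOL_PER_W
    out = pd.DataFrame({"timestamp": times, "sw_in": sw, "par_in": par})
    if np.all(sw == 0.0):
        out.attrs["polar"] = "polar_night"
    elif np.all(sw > 0.0):
        out.attrs["polar"] = "midnight_sun"
    else:
        out.attrs["polar"] = None
    return out


def _validate_defects(geom: DeploymentGeometry, cfg: SynthConfig,
                      defects: DefectSpec) -> list:
    start = pd.Timestamp(cfg.start_date).normalize()
    end = start + pd.Timedelta(days=cfg.n_days)
    known = set(geom.node_ids)
    windows = []
    for node_id, channel, w_start, w_end in defects.failure_windows:
        ws, we = pd.Timestamp(w_start), pd.Timestamp(w_end)
        if node_id not in known:
            raise PhenosenseError(f"failure window names unknown node {node_id!r}")
        if channel not in CHANNELS:
            raise PhenosenseError(f"failure window names unknown channel {channel!r}")
        if ws >= we:
            raise PhenosenseError(f"failure window start {ws} is not before end {we}")
        if ws < start or we > end:
            raise PhenosenseError(
                f"failure window [{ws}, {we}) outside simulated span [{start}, {end})"
            )
        windows.append((node_id, channel, ws, we))
    return windows


def make_deployment_series(
    geom: DeploymentGeometry,
    cfg: SynthConfig,
    defects: DefectSpec | None = None,
    tower_node_id: str | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a deployment and return (series table, ground truth).

    The first node of the geometry is the phenology tower (override with
    ``tower_node_id``) and carries the four radiation channels; remaining
    nodes are understory stations with air temperature and relative
    humidity. Tower reflectances are constructed so that recomputing NDVI
    from the emitted channels reproduces ``cfg.canopy_ndvi_trajectory``
    exactly before noise.
    """
    if defects is None:
        defects = DefectSpec()
    if not geom.nodes:
        raise PhenosenseError("geometry must contain at least one node")
    tower = tower_node_id or geom.nodes[0].node_id
    if tower not in geom.node_ids:
        raise PhenosenseError(f"tower node {tower!r} not in geometry")
    windows = _validate_defects(geom, cfg, defects)

    rng = np.random.default_rng(cfg.random_seed)
    start = pd.Timestamp(cfg.start_date).normalize()
    dates = [start + pd.Timedelta(days=i) for i in range(cfg.n_days)]
    cloudy = rng.random(cfg.n_days) < cfg.cloudy_day_probability

    frames = []
    ndvi_by_date: dict[str, float] = {}
    cloudy_dates: list[str] = []

    for day_idx, d in enumerate(dates):
        day = make_clear_sky_day(geom.site, d, cfg)
        atten = OVERCAST_FACTOR if cloudy[day_idx] else 1.0
        if cloudy[day_idx]:
            cloudy_dates.append(str(d.date()))
        sw_in = day["sw_in"].to_numpy() * atten
        par_in = day["par_in"].to_numpy() * atten
        times = day["timestamp"]

        # encode the prescribed NDVI through the two broadband reflectances
        n_target = float(np.clip(cfg.canopy_ndvi_trajectory(float(d.dayofyear)),
                                 -0.99, 0.99))
        ndvi_by_date[str(d.date())] = n_target
        rho_par = RHO_PAR_BASELINE
        rho_nir = rho_par * (1.0 + n_target) / (1.0 - n_target)
        par_out = rho_par * par_in
        par_in_w = par_in / QUANTUM_UMOL_PER_W
        par_out_w = par_out / QUANTUM_UMOL_PER_W
        sw_out = par_out_w + rho_nir * (sw_in - par_in_w)

        for channel, values in (
            ("par_in", par_in), ("par_out", par_out),
            ("sw_in", sw_in), ("sw_out", sw_out),
        ):
            frames.append(make_series_table(times, tower, channel, values))

        # understory micro-climate: smooth diurnal cycles, warmest ~15:00,
        # RH in anti-phase; small deterministic per-node offsets
        hour = times.dt.hour.to_numpy() + times.dt.minute.to_numpy() / 60.0
        phase = np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)
        for k, node in enumerate(nd for nd in geom.nodes if nd.node_id != tower):
            t_off = 0.3 * (k % 5)  # spatial micro-climate variation
            temp = cfg.mean_air_temp + t_off + cfg.diurnal_temp_amplitude * phase
            rh = np.clip(cfg.mean_rel_hum - cfg.diurnal_rh_amplitude * phase, 2.0, 100.0)
            frames.append(make_series_table(times, node.node_id, "air_temp", temp))
            frames.append(make_series_table(times, node.node_id, "rel_hum", rh))

    table = pd.concat(frames, ignore_index=True)

    # multiplicative Gaussian noise per channel (relative SD)
    for channel, sd in cfg.noise_sd.items():
        if sd == 0:
            continue
        mask = (table["channel"] == channel).to_numpy()
        vals = table.loc[mask, "value"].to_numpy()
        vals = vals * (1.0 + rng.normal(0.0, sd, size=vals.size))
        if channel in ("par_in", "par_out", "sw_in", "sw_out", "rain", "soil_moist"):
            vals = np.clip(vals, 0.0, None)
        if channel == "rel_hum":
            vals = np.clip(vals, 0.0, 100.0)
        table.loc[mask, "value"] = vals

    # sensor failures: the instrument logs nothing inside the window
    for node_id, channel, ws, we in windows:
        drop = (
            (table["node_id"] == node_id)
            & (table["channel"] == channel)
            & (table["timestamp"] >= ws)
            & (table["timestamp"] < we)
        )
        table = table[~drop]

    # a misconfigured logger clock stamps every record late (or early)
    if defects.clock_shift_hours:
        table = table.copy()
        table["timestamp"] = table["timestamp"] + pd.Timedelta(
            hours=defects.clock_shift_hours
        )

    table = table.sort_values(["node_id", "channel", "timestamp"],
                              kind="mergesort").reset_index(drop=True)
    truth = GroundTruth(
        ndvi_by_date=ndvi_by_date,
        clock_shift_hours=defects.clock_shift_hours,
        failure_windows=[(n, c, str(a), str(b)) for n, c, a, b in windows],
        cloudy_dates=cloudy_dates,
        rho_par_baseline=RHO_PAR_BASELINE,
        random_seed=cfg.random_seed,
    )
    return table, truth


def write_logger_file(
    table: pd.DataFrame,
    dialect: str,
    path,
    corruption_rate: float = 0.0,
    random_seed: int = 0,
) -> list[tuple[int, str]]:
    """Write ``table`` as a logger export in a registered dialect.

    With ``corruption_rate`` > 0, that fraction of data records (chosen with
    ``random_seed``) is structurally corrupted — an extra column, a missing
    column, or a garbled numeric field — emulating the record-level damage
    sensor faults and radio interference inflict on real exports. Returns
    the injected defects as (0-based data-record index, kind) pairs, for use
    as ingestion ground truth.
    """
    from . import ingest  # deferred: ingest owns the dialect registry

    d = ingest.get_dialect(dialect)
    lines = d.format_table(table)
    header, data = lines[: d.n_header_lines], lines[d.n_header_lines:]

    injected: list[tuple[int, str]] = []
    if corruption_rate > 0 and data:
        rng = np.random.default_rng(random_seed)
        hit = rng.random(len(data)) < corruption_rate
        kinds = rng.integers(0, 3, size=len(data))
        for i in np.flatnonzero(hit):
            fields = data[i].split(d.delimiter)
            kind = ("extra_column", "missing_column", "garbled_field")[kinds[i]]
            if kind == "extra_column":
                fields.append("999")
            elif kind == "missing_column":
                fields = fields[:-1]
            else:
                fields[-1] = "#ERR#"
            data[i] = d.delimiter.join(fields)
            injected.append((int(i), kind))

    with open(path, "w") as fh:
        fh.write("\n".join(header + data))
        if header or data:
            fh.write("\n")
    return injected
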