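"""Derived vegetation and micro-climate products.

A phenology tower carries two paired radiometer sets looking up and down:
quantum PAR sensors (400-700 nm, umol m-2 s-1) and broadband pyranometers
(~300-1100 nm, W m-2). Treating PAR as the "red/visible" band and
(shortwave - PAR) as the "NIR" band gives broadband reflectances

    rho_par = PAR_out / PAR_in
    rho_nir = (SW_out - PAR_out_W) / (SW_in - PAR_in_W)

(PAR converted to energy units with the package-wide quantum factor), from
which the standard two-band indexes follow:

    NDVI  = (rho_nir - rho_par) / (rho_nir + rho_par)
    EVI2  = 2.5 (rho_nir - rho_par) / (rho_nir + 2.4 rho_par + 1)

LAI is obtained from NDVI through a user-supplied ecosystem conversion
(linear factor, or a Beer-law saturating form); VPD from air temperature and
relative humidity through the Magnus saturation-vapour-pressure formula.

Indexes are computed on *filtered instantaneous* records and then averaged
daily (mean of ratios), never on aggregated fluxes: the two orders of
operation differ on real data, and this one matches how midday clear-sky
screening is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import series_ops
from .types import QUANTUM_UMOL_PER_W, PhenosenseError

#: Incoming-radiation floors below which reflectance ratios are undefined
#: (dawn/dusk ratios explode as both numerator and denominator vanish).
PAR_IN_FLOOR_UMOL = 100.0
SW_IN_FLOOR_W = 50.0


@dataclass(frozen=True)
class FootprintParams:
    """Geometry of a downward-facing radiometer's ground footprint."""

    h: float  # metres between sensor and monitored surface
    view_half_angle: float = 85.0  # degrees from nadir

    def __post_init__(self):
        if self.h < 0:
            raise PhenosenseError("sensor height h must be >= 0")
        if not 0.0 < self.view_half_angle < 90.0:
            raise PhenosenseError("view half-angle must be in (0, 90) degrees")


def footprint_radius(p: FootprintParams | float, view_half_angle: float = 85.0) -> float:
    """Ground footprint radius (m) of a downward-facing radiation sensor.

    ``radius = tan(view_half_angle) * h``: a sensor with an 85-degree view
    half-angle mounted h metres above the canopy integrates radiation from a
    disc of roughly ten times h (tan 85 deg ~ 11.43).
    """
    if not isinstance(p, FootprintParams):
        p = FootprintParams(h=float(p), view_half_angle=view_half_angle)
    return math.tan(math.radians(p.view_half_angle)) * p.h


@dataclass
class Reflectances:
    """Broadband visible (PAR) and NIR reflectances with validity flags."""

    rho_par: np.ndarray
    rho_nir: np.ndarray
    defined: np.ndarray  # bool; False where a floor or denominator failed
    reason: np.ndarray  # str; why undefined / flagged
    timestamp: pd.DatetimeIndex | None = None


def radiation_quad(table: pd.DataFrame, node_id: str | None = None) -> pd.DataFrame:
    """Pivot a series table into the four tower radiation channels.

    Returns a frame indexed by timestamp with columns
    ``par_in, par_out, sw_in, sw_out``; rows missing any channel are kept as
    NaN so downstream maths can flag them.
    """
    sel = table[table["channel"].isin(["par_in", "par_out", "sw_in", "sw_out"])]
    if node_id is not None:
        sel = sel[sel["node_id"] == node_id]
    if sel.empty:
        raise PhenosenseError("no radiation channels in table")
    return sel.pivot_table(index="timestamp", columns="channel", values="value",
                           aggfunc="first", dropna=False)


def broadband_reflectances(quad: pd.DataFrame) -> Reflectances:
    """Compute rho_par and rho_nir from a radiation quad.

    Ratios are only defined where incoming PAR exceeds
    :data:`PAR_IN_FLOOR_UMOL` and incoming shortwave exceeds
    :data:`SW_IN_FLOOR_W`; the NIR ratio additionally requires a positive
    NIR denominator (SW_in - PAR_in in energy units). Reflectances outside
    [0, 1] are returned but flagged.
    """
    par_in = quad["par_in"].to_numpy(dtype=float)
    par_out = quad["par_out"].to_numpy(dtype=float)
    sw_in = quad["sw_in"].to_numpy(dtype=float)
    sw_out = quad["sw_out"].to_numpy(dtype=float)

    par_in_w = par_in / QUANTUM_UMOL_PER_W
    par_out_w = par_out / QUANTUM_UMOL_PER_W
    nir_den = sw_in - par_in_w
    nir_num = sw_out - par_out_w

    n = len(par_in)
    rho_par = np.full(n, np.nan)
    rho_nir = np.full(n, np.nan)
    defined = np.ones(n, dtype=bool)
    reason = np.full(n, "", dtype=object)

    incomplete = np.isnan(par_in) | np.isnan(par_out) | np.isnan(sw_in) | np.isnan(sw_out)
    low_sun = (~incomplete) & ((par_in <= PAR_IN_FLOOR_UMOL) | (sw_in <= SW_IN_FLOOR_W))
    no_nir = (~incomplete) & (~low_sun) & (nir_den <= 0)
    defined &= ~(incomplete | low_sun | no_nir)
    reason[incomplete] = "missing channel"
    reason[low_sun] = "incoming radiation below floor (night/low sun)"
    reason[no_nir] = "no NIR signal: shortwave equals PAR in energy units"

    ok = defined
    rho_par[ok] = par_out[ok] / par_in[ok]
    rho_nir[ok] = nir_num[ok] / nir_den[ok]

    outside = ok & (
        (rho_par < 0) | (rho_par > 1) | (rho_nir < 0) | (rho_nir > 1)
    )
    reason[outside] = "reflectance outside [0, 1]"

    ts = quad.index if isinstance(quad.index, pd.DatetimeIndex) else None
    return Reflectances(rho_par=rho_par, rho_nir=rho_nir, defined=defined,
                        reason=np.asarray(reason, dtype=str), timestamp=ts)


def ndvi(rho_par, rho_nir):
    """Normalized Difference Vegetation Index from broadband reflectances.

    ``(rho_nir - rho_par) / (rho_nir + rho_par)``; NaN where the sum is 0.
    Bounded in [-1, 1] whenever both reflectances are in [0, 1].
    """
    rho_par = np.asarray(rho_par, dtype=float)
    rho_nir = np.asarray(rho_nir, dtype=float)
    s = rho_nir + rho_par
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s != 0, (rho_nir - rho_par) / np.where(s != 0, s, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def evi2(rho_par, rho_nir):
    """Two-band Enhanced Vegetation Index: 2.5 (N - R) / (N + 2.4 R + 1).

    The two-band variant is used because the sensor suite has no blue band.
    """
    rho_par = np.asarray(rho_par, dtype=float)
    rho_nir = np.asarray(rho_nir, dtype=float)
    out = 2.5 * (rho_nir - rho_par) / (rho_nir + 2.4 * rho_par + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LaiParams:
    """Ecosystem-specific NDVI -> LAI conversion.

    Two modes:

    * ``linear``: LAI = c * max(NDVI, 0); ``c`` is the ecosystem factor.
    * ``saturating`` (Beer-law form):
      LAI = -(1/k) * ln((ndvi_max - NDVI) / (ndvi_max - ndvi_min)),
      with NDVI clipped just below ``ndvi_max`` (flagged when clipping).

    No ecosystem values are built in — the factor is characteristic of each
    site and must be supplied.
    """

    mode: str = "linear"
    c: float = 1.0
    ndvi_min: float = 0.1
    ndvi_max: float = 0.9
    k: float = 0.6

    def __post_init__(self):
        if self.mode not in ("linear", "saturating"):
            raise PhenosenseError("LAI mode must be 'linear' or 'saturating'")
        if self.c <= 0 or self.k <= 0:
            raise PhenosenseError("LAI conversion factors must be > 0")
        if not self.ndvi_min < self.ndvi_max:
            raise PhenosenseError("ndvi_min must be < ndvi_max")


def lai_from_ndvi(ndvi_value, p: LaiParams, eps: float = 1e-6):
    """Leaf area index (m2 m-2) from NDVI via the supplied conversion.

    In saturating mode NDVI at or above ``ndvi_max`` is clipped to
    ``ndvi_max - eps`` (the conversion saturates); negative results are
    floored at 0.
    """
    v = np.asarray(ndvi_value, dtype=float)
    if p.mode == "linear":
        out = p.c * np.clip(v, 0.0, None)
    else:
        clipped = np.minimum(v, p.ndvi_max - eps)
        frac = (p.ndvi_max - clipped) / (p.ndvi_max - p.ndvi_min)
        out = np.clip(-np.log(frac) / p.k, 0.0, None)
    return float(out) if out.ndim == 0 else out


def vpd(air_temp_c, rel_hum_pct):
    """Vapour pressure deficit (kPa) from air temperature and RH.

    Magnus saturation vapour pressure
    ``es = 0.6108 * exp(17.27 T / (T + 237.3))`` (T in degC), then
    ``vpd = es * (1 - RH/100)``. RH outside [0, 100] raises: range QC
    should have flagged it first.
    """
    t = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(rel_hum_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise PhenosenseError("relative humidity outside [0, 100]%: run range QC first")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    out = es * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


def daily_ndvi(
    table: pd.DataFrame,
    cfg: series_ops.FilterConfig | None = None,
    node_id: str | None = None,
    index: str = "ndvi",
) -> pd.DataFrame:
    """The standard tower NDVI/EVI2 chain, one value per day.

    QC-excluded records are dropped, the midday clock window and the
    incoming-PAR cloud screen are applied, the index is computed on each
    surviving instantaneous radiation quad, and the instantaneous values are
    averaged per day. Returns a frame with columns
    ``date, value, n_samples``.
    """
    if index not in ("ndvi", "evi2"):
        raise PhenosenseError("index must be 'ndvi' or 'evi2'")
    cfg = cfg or series_ops.FilterConfig()
    t = series_ops.flag_filter(table, cfg)
    t = series_ops.span_filter(t, cfg)
    t = series_ops.window_filter(t, cfg)
    t = series_ops.cloud_filter(t, cfg)
    quad = radiation_quad(t, node_id=node_id)
    refl = broadband_reflectances(quad)
    fn = ndvi if index == "ndvi" else evi2
    values = fn(refl.rho_par, refl.rho_nir)
    values = np.where(refl.defined, values, np.nan)
    df = pd.DataFrame({"timestamp": quad.index, "value": values}).dropna()
    if df.empty:
        return pd.DataFrame(columns=["date", "value", "n_samples"])
    g = df.groupby(df["timestamp"].dt.normalize())["value"]
    out = pd.DataFrame(
        {"date": g.mean().index, "value": g.mean().to_numpy(),
         "n_samples": g.size().to_numpy()}
    ).reset_index(drop=True)
    return out


def vpd_series(table: pd.DataFrame) -> pd.DataFrame:
    """Per-record VPD for every node carrying both air_temp and rel_hum."""
    sel = table[table["channel"].isin(["air_temp", "rel_hum"])]
    wide = sel.pivot_table(index=["node_id", "timestamp"], columns="channel",
                           values="value", aggfunc="first")
    if "air_temp" not in wide or "rel_hum" not in wide:
        raise PhenosenseError("vpd_series needs both air_temp and rel_hum channels")
    wide = wide.dropna(subset=["air_temp", "rel_hum"]).reset_index()
    values = vpd(wide["air_temp"].to_numpy(), wide["rel_hum"].to_numpy())
    return pd.DataFrame(
        {"timestamp": wide["timestamp"], "node_id": wide["node_id"],
         "vpd_kpa": values}
    )
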