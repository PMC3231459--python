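"""Filtering, physical-range QC, aggregation and gap reporting.

These are the interactive operators a data manager applies before any
derived product: flag readings outside the sensor's physical range, keep a
midday clock-time window, screen cloudy records by an incoming-PAR
threshold, aggregate to hourly/daily/monthly statistics with a minimum
coverage rule, and report data gaps as a network-health proxy.

Filters never mutate values — they only change membership or flags — and
the time-of-day window is half-open ``[start, end)`` so boundary samples are
never double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd

from .types import PhenosenseError, empty_series_table


@dataclass(frozen=True)
class SensorSpec:
    """Physical measurement range of one channel (sensor datasheet values)."""

    channel: str
    vmin: float
    vmax: float
    accuracy: str = ""

    def __post_init__(self):
        if not self.vmin < self.vmax:
            raise PhenosenseError(f"{self.channel}: range min must be < max")


#: Datasheet ranges of the sensor families commonly deployed for this kind
#: of monitoring (temperature/RH probes, quantum PAR sensors, silicon
#: pyranometers, capacitance soil-moisture probes, tipping-bucket gauges).
DEFAULT_SENSOR_SPECS = {
    "air_temp": SensorSpec("air_temp", -40.0, 75.0, "0.2-0.7 degC"),
    "rel_hum": SensorSpec("rel_hum", 0.0, 100.0, "1.8-4.5 % RH"),
    "par_in": SensorSpec("par_in", 0.0, 2500.0, "5% or 5 umol m-2 s-1"),
    "par_out": SensorSpec("par_out", 0.0, 2500.0, "5% or 5 umol m-2 s-1"),
    "sw_in": SensorSpec("sw_in", 0.0, 1280.0, "5% or 10 W m-2"),
    "sw_out": SensorSpec("sw_out", 0.0, 1280.0, "5% or 10 W m-2"),
    "soil_moist": SensorSpec("soil_moist", 0.0, 100.0, "1-3 % VWC"),
    "rain": SensorSpec("rain", 0.0, 1270.0, "1%"),
}


@dataclass
class FilterConfig:
    """Configuration of the record-selection filters."""

    time_span: tuple | None = None  # (start, end) half-open
    time_of_day_window: tuple = (time(10, 0), time(14, 0))  # midday window
    clear_sky_par_threshold: float = 900.0  # umol m-2 s-1, strict >
    exclude_flags: frozenset = frozenset({"out_of_range", "malformed", "failed_sensor"})
    min_coverage: float = 0.75

    def __post_init__(self):
        if self.clear_sky_par_threshold <= 0:
            raise PhenosenseError("clear_sky_par_threshold must be > 0")
        if not 0.0 < self.min_coverage <= 1.0:
            raise PhenosenseError("min_coverage must be in (0, 1]")


@dataclass
class RangeCheckResult:
    table: pd.DataFrame
    n_flagged: dict = field(default_factory=dict)  # channel -> count
    skipped_channels: list = field(default_factory=list)


def range_check(table: pd.DataFrame, specs: dict | None = None) -> RangeCheckResult:
    """Flag values outside the sensor's physical range as ``out_of_range``.

    ``specs`` maps channel to :class:`SensorSpec` (defaults to the datasheet
    ranges in :data:`DEFAULT_SENSOR_SPECS`). Channels without a spec are
    skipped with a warning. In-range values are untouched.
    """
    specs = DEFAULT_SENSOR_SPECS if specs is None else specs
    out = table.copy()
    n_flagged: dict[str, int] = {}
    skipped = sorted(set(out["channel"].dropna().unique()) - set(specs))
    if skipped:
        warnings.warn(f"no sensor spec for channels {skipped}; range check skipped",
                      stacklevel=2)
    for channel, spec in specs.items():
        mask = (
            (out["channel"] == channel)
            & out["value"].notna()
            & ((out["value"] < spec.vmin) | (out["value"] > spec.vmax))
        )
        n = int(mask.sum())
        if n:
            out.loc[mask, "flag"] = "out_of_range"
            n_flagged[channel] = n
    return RangeCheckResult(table=out, n_flagged=n_flagged, skipped_channels=skipped)


def flag_filter(table: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Drop records whose flag is in ``cfg.exclude_flags``."""
    cfg = cfg or FilterConfig()
    return table[~table["flag"].isin(cfg.exclude_flags)].reset_index(drop=True)


def span_filter(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep records with timestamp in the half-open configured time span."""
    if cfg.time_span is None:
        return table.reset_index(drop=True)
    start, end = pd.Timestamp(cfg.time_span[0]), pd.Timestamp(cfg.time_span[1])
    keep = (table["timestamp"] >= start) & (table["timestamp"] < end)
    return table[keep].reset_index(drop=True)


def window_filter(table: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep records whose clock time lies in the half-open daily window.

    Default window 10:00-14:00 local standard time, the midday period where
    sun angles are high enough for stable reflectance ratios.
    """
    cfg = cfg or FilterConfig()
    start, end = cfg.time_of_day_window
    tod = table["timestamp"].dt.time
    keep = (tod >= start) & (tod < end) if start <= end else (tod >= start) | (tod < end)
    return table[keep].reset_index(drop=True)


def cloud_filter(
    table: pd.DataFrame,
    cfg: FilterConfig | None = None,
    counts: dict | None = None,
) -> pd.DataFrame:
    """Keep records simultaneous with incoming PAR above the clear-sky threshold.

    A record survives iff the same node has a ``par_in`` reading at the same
    timestamp strictly greater than ``cfg.clear_sky_par_threshold`` (a
    reading exactly at the threshold is dropped). Records without a
    ``par_in`` partner are dropped; pass a ``counts`` dict to receive
    ``counts['dropped_no_partner']``.
    """
    cfg = cfg or FilterConfig()
    par = table[(table["channel"] == "par_in") & table["value"].notna()]
    if par.empty:
        raise PhenosenseError("cloud_filter requires a par_in channel in the table")
    clear = set(
        map(
            tuple,
            par.loc[par["value"] > cfg.clear_sky_par_threshold,
                    ["node_id", "timestamp"]].itertuples(index=False, name=None),
        )
    )
    has_partner = set(
        map(tuple, par[["node_id", "timestamp"]].itertuples(index=False, name=None))
    )
    keys = list(zip(table["node_id"], table["timestamp"]))
    keep = np.array([k in clear for k in keys])
    if counts is not None:
        counts["dropped_no_partner"] = int(
            sum(1 for k in keys if k not in has_partner)
        )
    return table[keep].reset_index(drop=True)


_PERIOD_FREQ = {"hourly": "h", "daily": "D", "monthly": "M"}
_STATS = ("mean", "min", "max", "count")


def _expected_samples(bucket_start: pd.Timestamp, period: str, interval_min: int) -> int:
    if period == "hourly":
        return max(60 // interval_min, 1)
    if period == "daily":
        return max(1440 // interval_min, 1)
    # monthly: depends on the calendar month
    return max(bucket_start.days_in_month * 1440 // interval_min, 1)


def aggregate(
    table: pd.DataFrame,
    period: str,
    statistic: str,
    expected_interval: int,
    min_coverage: float = 0.75,
) -> pd.DataFrame:
    """Aggregate per (node, channel) into period buckets with a coverage rule.

    ``expected_interval`` is the sampling interval in minutes; a bucket with
    fewer than ``min_coverage`` of its expected samples is emitted as a gap
    (NaN value, flag ``gap``) rather than a misleading statistic. Buckets
    are labelled by their start in local standard time. Flag-based record
    exclusion is the caller's responsibility (see :func:`flag_filter`).
    """
    if period not in _PERIOD_FREQ:
        raise PhenosenseError(f"period must be one of {sorted(_PERIOD_FREQ)}")
    if statistic not in _STATS:
        raise PhenosenseError(f"statistic must be one of {_STATS}")
    if table.empty:
        return empty_series_table()
    valid = table[table["value"].notna()]
    if valid.empty:
        return empty_series_table()
    bucket = valid["timestamp"].dt.to_period(_PERIOD_FREQ[period]).dt.start_time
    grouped = valid.groupby([valid["node_id"], valid["channel"], bucket],
                            observed=True)["value"]
    agg = grouped.agg(statistic)
    n = grouped.size()
    rows = []
    for (node, channel, b), value in agg.items():
        expected = _expected_samples(b, period, expected_interval)
        covered = n.loc[(node, channel, b)] / expected >= min_coverage
        rows.append(
            {
                "timestamp": b,
                "node_id": node,
                "channel": channel,
                "value": float(value) if covered else np.nan,
                "flag": "ok" if covered else "gap",
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["node_id", "channel", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    out["node_id"] = out["node_id"].astype("string")
    out["channel"] = out["channel"].astype("string")
    out["flag"] = out["flag"].astype("string")
    return out


@dataclass
class GapReport:
    """Missing-data runs per (node, channel) plus per-node downtime."""

    gaps: pd.DataFrame  # columns: node_id, channel, gap_start, gap_end
    downtime: pd.Series  # node_id -> total missing time (Timedelta)


def gap_report(table: pd.DataFrame, expected_interval: int) -> GapReport:
    """Report maximal missing runs on the expected sampling grid.

    A gap is a maximal run of missing (absent or NaN-valued) samples between
    the first and last observed timestamps of a (node, channel) stream;
    ``gap_end`` is exclusive (the first timestamp with data again), so
    adjacent missing samples coalesce into one gap.
    """
    step = pd.Timedelta(minutes=expected_interval)
    rows = []
    downtime: dict[str, pd.Timedelta] = {}
    for (node, channel), grp in table.groupby(["node_id", "channel"], observed=True):
        present = grp.loc[grp["value"].notna(), "timestamp"]
        if present.empty:
            continue
        full = pd.date_range(present.min(), present.max(), freq=step)
        missing = full.difference(pd.DatetimeIndex(present))
        if missing.empty:
            continue
        # coalesce consecutive missing samples into maximal runs
        breaks = np.flatnonzero(np.diff(missing.values) > step.to_numpy())
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(missing) - 1]))
        for s, e in zip(starts, ends):
            g0, g1 = missing[s], missing[e] + step
            rows.append(
                {"node_id": node, "channel": channel, "gap_start": g0, "gap_end": g1}
            )
            downtime[node] = downtime.get(node, pd.Timedelta(0)) + (g1 - g0)
    gaps = pd.DataFrame(rows, columns=["node_id", "channel", "gap_start", "gap_end"])
    return GapReport(gaps=gaps, downtime=pd.Series(downtime, dtype="timedelta64[ns]"))
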