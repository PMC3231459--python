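"""Core domain types and the canonical in-memory series representation.

Every stage of the pipeline exchanges data through a *series table*: a
long-form :class:`pandas.DataFrame` with one row per reading and columns

========== =====================================================
column     meaning
========== =====================================================
timestamp  local **standard** time (naive ``datetime64[ns]``;
           daylight-saving time is never applied by this library)
node_id    string identifier of the sensor node
channel    one of :data:`CHANNELS`
value      reading in the channel's fixed unit (:data:`CHANNEL_UNITS`)
flag       one of :data:`FLAGS`
========== =====================================================

Helper constructors/validators for that frame live here, together with the
small frozen dataclasses describing a site and a deployment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Controlled channel vocabulary.
CHANNELS = (
    "par_in",      # incoming PAR, umol m-2 s-1
    "par_out",     # reflected PAR, umol m-2 s-1
    "sw_in",       # incoming shortwave, W m-2
    "sw_out",      # reflected shortwave, W m-2
    "air_temp",    # air temperature, degC
    "rel_hum",     # relative humidity, %
    "soil_moist",  # volumetric water content, %
    "rain",        # rainfall rate, mm/h
)

CHANNEL_UNITS = {
    "par_in": "umol m-2 s-1",
    "par_out": "umol m-2 s-1",
    "sw_in": "W m-2",
    "sw_out": "W m-2",
    "air_temp": "degC",
    "rel_hum": "%",
    "soil_moist": "% VWC",
    "rain": "mm/h",
}

#: Quality flags a record may carry (exactly one each).
FLAGS = ("ok", "out_of_range", "malformed", "gap", "failed_sensor")

#: Broadband quantum conversion: 1 W m-2 of PAR-band shortwave energy
#: corresponds to ~4.57 umol photons m-2 s-1 (McCree-style constant).
#: Used consistently for synthesis and for index derivation, so the
#: pipeline is self-consistent regardless of the constant's absolute
#: accuracy.
QUANTUM_UMOL_PER_W = 4.57

SERIES_COLUMNS = ("timestamp", "node_id", "channel", "value", "flag")


class PhenosenseError(Exception):
    """Base class for all errors raised by this package."""


def empty_series_table() -> pd.DataFrame:
    """Return an empty series table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "timestamp": pd.Series(dtype="datetime64[ns]"),
            "node_id": pd.Series(dtype="string"),
            "channel": pd.Series(dtype="string"),
            "value": pd.Series(dtype="float64"),
            "flag": pd.Series(dtype="string"),
        }
    )


def make_series_table(timestamp, node_id, channel, value, flag="ok") -> pd.DataFrame:
    """Build a series table from columnar inputs (scalars broadcast)."""
    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(timestamp),
            "node_id": node_id,
            "channel": channel,
            "value": np.asarray(value, dtype=float),
        }
    )
    df["flag"] = flag
    df["node_id"] = df["node_id"].astype("string")
    df["channel"] = df["channel"].astype("string")
    df["flag"] = df["flag"].astype("string")
    return df[list(SERIES_COLUMNS)]


def validate_series_table(table: pd.DataFrame, *, strict_order: bool = True) -> None:
    """Check the series-table contract; raise :class:`PhenosenseError` on violation.

    The contract: canonical columns, known channels and flags, and (when
    ``strict_order``) strictly increasing timestamps per (node, channel).
    """
    missing = set(SERIES_COLUMNS) - set(table.columns)
    if missing:
        raise PhenosenseError(f"series table missing columns: {sorted(missing)}")
    bad_ch = set(table["channel"].dropna().unique()) - set(CHANNELS)
    if bad_ch:
        raise PhenosenseError(f"unknown channels: {sorted(bad_ch)}")
    bad_fl = set(table["flag"].dropna().unique()) - set(FLAGS)
    if bad_fl:
        raise PhenosenseError(f"unknown flags: {sorted(bad_fl)}")
    if strict_order and len(table):
        grouped = table.groupby(["node_id", "channel"], observed=True)["timestamp"]
        if not grouped.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
            raise PhenosenseError(
                "timestamps must be strictly increasing per (node, channel)"
            )


@dataclass(frozen=True)
class SiteLocation:
    """Geographic site location in local standard time.

    Parameters
    ----------
    latitude, longitude : float
        Degrees; north and east positive.
    utc_offset_hours : int
        Signed offset of local *standard* time from UTC. Daylight-saving
        time is deliberately unsupported: field loggers are configured to
        local standard time year-round.
    """

    latitude: float
    longitude: float
    utc_offset_hours: int

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise PhenosenseError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise PhenosenseError(f"longitude out of range: {self.longitude}")
        if not -12 <= self.utc_offset_hours <= 14:
            raise PhenosenseError(f"utc_offset out of range: {self.utc_offset_hours}")


@dataclass(frozen=True)
class Node:
    """A sensor node in the deployment's local planar frame (metres)."""

    node_id: str
    x: float  # m east of the deployment reference point
    y: float  # m north
    sensor_height: float = 2.0  # m above the monitored surface

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise PhenosenseError(f"node {self.node_id}: non-finite coordinates")


@dataclass(frozen=True)
class DeploymentGeometry:
    """Site location plus node coordinates and layout kind."""

    site: SiteLocation
    nodes: tuple[Node, ...]
    layout_kind: str = "custom"  # transect | star | grid | custom

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise PhenosenseError("node ids must be unique")

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def positions(self) -> dict[str, tuple[float, float]]:
        return {n.node_id: (n.x, n.y) for n in self.nodes}


@dataclass
class IngestionReport:
    """Provenance and per-record validation outcome of one file ingestion."""

    source: str
    dialect: str
    ingested_at: str
    user: str
    options: dict = field(default_factory=dict)
    total: int = 0
    accepted: int = 0
    malformed: int = 0
    out_of_range: int = 0
    defects: list = field(default_factory=list)  # (record index, kind, message)

    def check(self) -> None:
        if self.accepted + self.malformed + self.out_of_range != self.total:
            raise PhenosenseError("ingestion report counts do not sum to total")
        for idx, kind, msg in self.defects:
            if not msg:
                raise PhenosenseError(f"defect at record {idx} has no message")

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "dialect": self.dialect,
            "ingested_at": self.ingested_at,
            "user": self.user,
            "options": dict(self.options),
            "counts": {
                "total": self.total,
                "accepted": self.accepted,
                "malformed": self.malformed,
                "out_of_range": self.out_of_range,
            },
            "defects": [
                {"record": i, "kind": k, "message": m} for i, k, m in self.defects
            ],
        }
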