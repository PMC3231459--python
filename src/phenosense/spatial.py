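"""Node layouts, interpolated scalar fields, and reliability maps.

Understory nodes are placed in one of three standard strategies — transects,
concentric rings ("star"), or regular grids — in a local planar frame
(metres east/north of a deployment reference point). Point readings are
turned into a field with inverse-distance weighting (IDW, exact at the
nodes, bounded by the input extremes), and every value field carries a
co-registered *reliability* layer: per cell, the fraction of installed
sensors within the sensor's coverage radius that are actually working, so a
map reader can see where the colour scale is trustworthy and where sensors
have failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import series_ops
from .products import footprint_radius
from .types import DeploymentGeometry, Node, PhenosenseError, SiteLocation


def layout(
    kind: str,
    site: SiteLocation | None = None,
    *,
    length: float | None = None,
    n: int | None = None,
    rings: list | None = None,
    rows: int | None = None,
    cols: int | None = None,
    spacing: float | None = None,
    sensor_height: float = 2.0,
) -> DeploymentGeometry:
    """Deterministic node coordinates for a named layout strategy.

    * ``transect``: ``n`` collinear nodes evenly spaced along ``length`` m
      (east axis, starting at the origin).
    * ``star``: concentric rings around the origin; ``rings`` is a list of
      (radius_m, n_nodes) with nodes evenly spaced in azimuth.
    * ``grid``: ``rows`` x ``cols`` lattice with ``spacing`` m.
    """
    site = site or SiteLocation(0.0, 0.0, 0)
    nodes: list[Node] = []
    if kind == "transect":
        if not n or n < 1 or length is None:
            raise PhenosenseError("transect needs length and n >= 1")
        step = 0.0 if n == 1 else length / (n - 1)
        nodes = [Node(f"t{i:02d}", i * step, 0.0, sensor_height) for i in range(n)]
    elif kind == "star":
        if not rings:
            raise PhenosenseError("star needs rings [(radius, n_nodes), ...]")
        k = 0
        for radius, count in rings:
            if count < 1 or radius <= 0:
                raise PhenosenseError("each ring needs radius > 0 and n >= 1")
            for j in range(count):
                theta = 2.0 * np.pi * j / count
                nodes.append(
                    Node(f"s{k:02d}", radius * np.cos(theta), radius * np.sin(theta),
                         sensor_height)
                )
                k += 1
    elif kind == "grid":
        if not rows or not cols or rows < 1 or cols < 1 or not spacing:
            raise PhenosenseError("grid needs rows, cols >= 1 and spacing")
        for r in range(rows):
            for c in range(cols):
                nodes.append(Node(f"g{r:02d}_{c:02d}", c * spacing, r * spacing,
                                  sensor_height))
    else:
        raise PhenosenseError(f"unknown layout kind {kind!r}")
    return DeploymentGeometry(site=site, nodes=tuple(nodes), layout_kind=kind)


@dataclass(frozen=True)
class GridParams:
    """Regular raster definition: extent (xmin, xmax, ymin, ymax) and cell size."""

    extent: tuple
    cell_size: float

    def __post_init__(self):
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin < xmax and ymin < ymax and self.cell_size > 0):
            raise PhenosenseError("invalid grid extent or cell size")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xmin, xmax, ymin, ymax = self.extent
        xs = np.arange(xmin + self.cell_size / 2, xmax, self.cell_size)
        ys = np.arange(ymin + self.cell_size / 2, ymax, self.cell_size)
        return xs, ys


def grid_covering(geom: DeploymentGeometry, cell_size: float = 5.0,
                  margin: float = 10.0) -> GridParams:
    """A grid that covers all nodes with a margin (convenience default)."""
    xs = [nd.x for nd in geom.nodes]
    ys = [nd.y for nd in geom.nodes]
    return GridParams(
        extent=(min(xs) - margin, max(xs) + margin, min(ys) - margin, max(ys) + margin),
        cell_size=cell_size,
    )


@dataclass
class GridRaster:
    """Value field plus co-registered reliability field on a regular grid."""

    x: np.ndarray  # cell-centre eastings, shape (nx,)
    y: np.ndarray  # cell-centre northings, shape (ny,)
    values: np.ndarray  # shape (ny, nx); NaN = undefined
    reliability: np.ndarray  # shape (ny, nx) in [0, 1]
    timestamp: pd.Timestamp | None = None

    def to_csv(self, path, layer: str = "values") -> None:
        arr = getattr(self, layer)
        pd.DataFrame(arr, index=self.y, columns=self.x).to_csv(path)


def idw_interpolate(
    geom: DeploymentGeometry,
    readings: dict,
    grid: GridParams,
    power: float = 2.0,
) -> GridRaster:
    """Inverse-distance-weighted field from node readings.

    ``readings`` maps node_id to a value; nodes absent from the map or with
    NaN values (failed/gap) do not contribute. The field is exact at node
    locations, a convex combination of inputs elsewhere (never outside their
    extremes), and all-NaN when no node contributes.
    """
    pos = geom.positions()
    pts, vals = [], []
    for node_id, v in readings.items():
        if node_id not in pos:
            raise PhenosenseError(f"reading for unknown node {node_id!r}")
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        pts.append(pos[node_id])
        vals.append(float(v))
    xs, ys = grid.centers()
    if not pts:
        nan = np.full((len(ys), len(xs)), np.nan)
        return GridRaster(x=xs, y=ys, values=nan, reliability=np.zeros_like(nan))

    p = np.asarray(pts)  # (k, 2)
    v = np.asarray(vals)  # (k,)
    gx, gy = np.meshgrid(xs, ys)
    d2 = (gx[..., None] - p[:, 0]) ** 2 + (gy[..., None] - p[:, 1]) ** 2
    dist = np.sqrt(d2)
    out = np.empty_like(gx, dtype=float)
    at_node = dist.min(axis=-1) == 0.0
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    w_sum = w.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        out = (w * v).sum(axis=-1) / w_sum
    if at_node.any():
        nearest = dist.argmin(axis=-1)
        out[at_node] = v[nearest[at_node]]
    return GridRaster(x=xs, y=ys, values=out, reliability=np.ones_like(out))


def reliability_map(
    geom: DeploymentGeometry,
    working: dict,
    grid: GridParams,
    coverage_radius: float | None = None,
) -> np.ndarray:
    """Per-cell fraction of in-range sensors that are working.

    ``working`` maps node_id to bool. For each cell, reliability =
    (working sensors within ``coverage_radius``) / (installed sensors within
    ``coverage_radius``), and 0 where no sensor is in range. The default
    radius is the radiometric footprint of the nodes' sensor height.
    """
    if coverage_radius is None:
        heights = {nd.sensor_height for nd in geom.nodes}
        coverage_radius = footprint_radius(max(heights))
    if coverage_radius <= 0:
        raise PhenosenseError("coverage radius must be > 0")
    xs, ys = grid.centers()
    gx, gy = np.meshgrid(xs, ys)
    installed = np.zeros_like(gx, dtype=float)
    ok = np.zeros_like(gx, dtype=float)
    for nd in geom.nodes:
        in_range = np.hypot(gx - nd.x, gy - nd.y) <= coverage_radius
        installed += in_range
        if working.get(nd.node_id, False):
            ok += in_range
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(installed > 0, ok / np.where(installed > 0, installed, 1.0), 0.0)
    return rel


def frame_sequence(
    geom: DeploymentGeometry,
    table: pd.DataFrame,
    channel: str,
    grid: GridParams,
    period: str = "hourly",
    expected_interval: int = 15,
    power: float = 2.0,
    coverage_radius: float | None = None,
    min_coverage: float = 0.25,
) -> list[GridRaster]:
    """One interpolated raster per aggregation bucket, in time order.

    Node readings per bucket come from :func:`phenosense.series_ops.aggregate`
    (mean). A node is *working* in a bucket when it produced an aggregate
    there; buckets where no node works still yield a frame (all-NaN values,
    reliability 0), so the animation cadence never depends on failures.
    """
    sel = table[table["channel"] == channel]
    agg = series_ops.aggregate(sel, period, "mean",
                               expected_interval, min_coverage=min_coverage)
    if agg.empty:
        return []
    # "installed" means carrying this channel: reliability of an air-temp map
    # is judged against the air-temp sensors, not the whole deployment
    installed = set(sel["node_id"].unique())
    geom = DeploymentGeometry(
        site=geom.site,
        nodes=tuple(nd for nd in geom.nodes if nd.node_id in installed),
        layout_kind=geom.layout_kind,
    )
    span = pd.period_range(
        agg["timestamp"].min(), agg["timestamp"].max(),
        freq=series_ops._PERIOD_FREQ[period],
    )
    frames = []
    for bucket in span.start_time:
        rows = agg[(agg["timestamp"] == bucket) & agg["value"].notna()]
        readings = dict(zip(rows["node_id"], rows["value"]))
        raster = idw_interpolate(geom, readings, grid, power=power)
        working = {nd.node_id: nd.node_id in readings for nd in geom.nodes}
        raster.reliability = reliability_map(geom, working, grid, coverage_radius)
        raster.timestamp = bucket
        frames.append(raster)
    return frames
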