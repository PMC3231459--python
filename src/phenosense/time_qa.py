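"""Clock-shift detection by sunrise comparison.

Field loggers are configured to local standard time, but replacement
laptops, confused users, or DST-enabled defaults introduce whole-hour
timestamp errors. Because the sun is an absolute clock, comparing the
sunrise observed in a radiation channel against the astronomically expected
sunrise over several days recovers such shifts: the method resolves whole
hours reliably but is deliberately *not* used to correct sub-hour hardware
drift, which it cannot distinguish from detection bias.

Procedure
---------
1. For each day, smooth the incoming shortwave (or PAR) series and find the
   first timestamp where it exceeds ``max(floor, 2% of the day's maximum)``
   and stays above it for ``persistence`` consecutive samples.
2. Difference against the expected sunrise (:mod:`phenosense.solar`).
3. The shift is the *median* daily offset rounded to the nearest whole hour
   (the median resists overcast mornings that bias a mean late); the
   estimate is refused when fewer than ``min_days`` days are usable or when
   the dispersion of the offsets exceeds ``dispersion_gate`` minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .types import QUANTUM_UMOL_PER_W, PhenosenseError, SiteLocation

#: Absolute irradiance floor of the sunrise detector, in W m-2 for
#: shortwave; PAR channels use the quantum-converted equivalent.
DEFAULT_FLOOR_W = 5.0
DEFAULT_PERSISTENCE = 2
DEFAULT_DISPERSION_GATE_MIN = 30.0


class InsufficientDataError(PhenosenseError):
    """Fewer usable days than the estimator requires."""


class UnreliableEstimateError(PhenosenseError):
    """Per-day sunrise offsets disagree too much to trust a correction."""


@dataclass(frozen=True)
class ShiftEstimate:
    """Whole-hour clock-shift estimate from multi-day sunrise comparison."""

    shift_hours: int
    per_day_offsets_min: dict  # ISO date -> (observed - expected) minutes
    n_days_used: int
    dispersion_min: float  # interquartile range of the per-day offsets

    @property
    def residuals_min(self) -> dict:
        """Per-day |offset - 60*shift| in minutes (sub-hour drift + bias)."""
        return {
            d: abs(off - 60.0 * self.shift_hours)
            for d, off in self.per_day_offsets_min.items()
        }


def detect_observed_sunrise(
    day_series: pd.DataFrame,
    floor: float = DEFAULT_FLOOR_W,
    persistence: int = DEFAULT_PERSISTENCE,
    smooth_window: int = 3,
) -> pd.Timestamp | None:
    """Observed sunrise in one day of irradiance records, or None.

    ``day_series`` needs columns ``timestamp`` and ``value`` for a single
    day of one irradiance channel; gap records (NaN) are ignored. Returns
    the first timestamp where the smoothed series exceeds
    ``max(floor, 0.02 * daily max)`` and remains above it for
    ``persistence`` consecutive samples; None when no sample qualifies
    (overcast or dead day).
    """
    s = day_series.dropna(subset=["value"]).sort_values("timestamp")
    if s.empty:
        return None
    vals = (
        s["value"].rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    vmax = float(np.nanmax(vals))
    if vmax <= 0:
        return None
    threshold = max(floor, 0.02 * vmax)
    above = vals > threshold
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= persistence:
            first = i - persistence + 1
            return pd.Timestamp(s["timestamp"].iloc[first])
    return None


def _daily_offsets(
    series: pd.DataFrame,
    site: SiteLocation,
    floor: float,
    persistence: int,
) -> dict[str, float]:
    offsets: dict[str, float] = {}
    for date, day in series.groupby(series["timestamp"].dt.normalize()):
        times = solar.expected_sunrise(site, date)
        if times.polar or times.expected_sunrise is None:
            continue
        observed = detect_observed_sunrise(day, floor=floor, persistence=persistence)
        if observed is None:
            continue
        offsets[str(date.date())] = (
            observed - times.expected_sunrise
        ).total_seconds() / 60.0
    return offsets


def estimate_clock_shift(
    table: pd.DataFrame,
    site: SiteLocation,
    date_range: tuple | None = None,
    channel: str | None = None,
    min_days: int = 3,
    dispersion_gate: float = DEFAULT_DISPERSION_GATE_MIN,
    floor: float | None = None,
    persistence: int = DEFAULT_PERSISTENCE,
) -> ShiftEstimate:
    """Estimate the whole-hour clock shift of a deployment's timestamps.

    Uses the ``sw_in`` channel when present, else ``par_in`` (with the
    irradiance floor converted to photon-flux units). Raises
    :class:`InsufficientDataError` with fewer than ``min_days`` usable days
    and :class:`UnreliableEstimateError` when the offset dispersion exceeds
    ``dispersion_gate`` minutes.
    """
    if channel is None:
        for cand in ("sw_in", "par_in"):
            if (table["channel"] == cand).any():
                channel = cand
                break
        else:
            raise InsufficientDataError("no irradiance channel (sw_in/par_in) in table")
    if floor is None:
        floor = DEFAULT_FLOOR_W
        if channel in ("par_in", "par_out"):
            floor *= QUANTUM_UMOL_PER_W

    sel = table[(table["channel"] == channel) & (table["flag"] != "malformed")]
    if date_range is not None:
        start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
        sel = sel[(sel["timestamp"] >= start) & (sel["timestamp"] < end)]
    if sel["node_id"].nunique() > 1:  # use the best-covered node
        counts = sel.groupby("node_id").size()
        sel = sel[sel["node_id"] == counts.idxmax()]

    offsets = _daily_offsets(sel, site, floor=floor, persistence=persistence)
    if len(offsets) < min_days:
        raise InsufficientDataError(
            f"only {len(offsets)} days with detectable sunrise; need >= {min_days}"
        )
    vals = np.array(list(offsets.values()))
    med = float(np.median(vals))
    # interquartile range: tolerant of a few biased (overcast) mornings but
    # sensitive to genuine disagreement, unlike the MAD, which a near-half
    # contamination can zero out
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    dispersion = float(q3 - q1)
    if dispersion > dispersion_gate:
        raise UnreliableEstimateError(
            f"per-day sunrise offsets disperse by {dispersion:.1f} min "
            f"(gate {dispersion_gate:.0f} min); refusing an estimate"
        )
    return ShiftEstimate(
        shift_hours=int(np.round(med / 60.0)),
        per_day_offsets_min=offsets,
        n_days_used=len(offsets),
        dispersion_min=dispersion,
    )


def apply_shift(table: pd.DataFrame, est: ShiftEstimate) -> pd.DataFrame:
    """Translate all timestamps by ``-shift_hours`` to undo the clock error.

    The correction is recorded in ``table.attrs['provenance']``; applying a
    zero-shift estimate is the identity, and after a correct application a
    re-estimated shift is zero.
    """
    out = table.copy()
    out["timestamp"] = out["timestamp"] - pd.Timedelta(hours=est.shift_hours)
    prov = list(table.attrs.get("provenance", []))
    prov.append(
        {
            "operation": "apply_shift",
            "shift_hours": est.shift_hours,
            "n_days_used": est.n_days_used,
            "dispersion_min": est.dispersion_min,
        }
    )
    out.attrs["provenance"] = prov
    return out
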