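"""Solar geometry: zenith angle, solar noon and sunrise in local standard time.

Implements the standard low-precision solar-position algorithm used by the
NOAA solar calculator: Spencer's Fourier expansions for solar declination
and the equation of time as a function of day-of-year, then the hour-angle
form of the zenith. Accuracy is a few tenths of a degree in zenith and
1-2 minutes in sunrise time, ample for whole-hour clock checks.

All timestamps are naive local *standard* time; the site's fixed UTC offset
converts to true solar time internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PhenosenseError, SiteLocation

#: Standard altitude of the sun's centre at rise/set: 16' semi-diameter
#: plus ~34' of atmospheric refraction.
SUNRISE_ALTITUDE_DEG = -0.833


def _day_angle(doy: np.ndarray, frac_hour: np.ndarray) -> np.ndarray:
    # fractional year in radians (365-day convention of the NOAA calculator)
    return 2.0 * np.pi / 365.0 * (doy - 1 + (frac_hour - 12.0) / 24.0)


def declination_rad(gamma: np.ndarray) -> np.ndarray:
    """Solar declination (radians) from the fractional-year angle ``gamma``."""
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def equation_of_time_min(gamma: np.ndarray) -> np.ndarray:
    """Equation of time (minutes) from the fractional-year angle ``gamma``."""
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )


def solar_zenith(site: SiteLocation, timestamp) -> np.ndarray | float:
    """Solar zenith angle in degrees for timestamps in local standard time.

    Total function: returns values in [0, 180] for any date; vectorised over
    array-like input.
    """
    ts = pd.to_datetime(timestamp)
    scalar = isinstance(ts, pd.Timestamp)
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)

    doy = idx.dayofyear.to_numpy(dtype=float)
    frac_hour = (
        idx.hour.to_numpy(dtype=float)
        + idx.minute.to_numpy(dtype=float) / 60.0
        + idx.second.to_numpy(dtype=float) / 3600.0
    )
    gamma = _day_angle(doy, frac_hour)
    decl = declination_rad(gamma)
    eqtime = equation_of_time_min(gamma)

    # minutes past local-standard midnight -> true solar time
    time_offset = eqtime + 4.0 * site.longitude - 60.0 * site.utc_offset_hours
    tst = frac_hour * 60.0 + time_offset
    ha = np.radians(tst / 4.0 - 180.0)

    lat = np.radians(site.latitude)
    cos_z = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    zen = np.degrees(np.arccos(np.clip(cos_z, -1.0, 1.0)))
    return float(zen[0]) if scalar else zen


@dataclass(frozen=True)
class SunTimes:
    """Expected sunrise and solar noon (local standard time) for one date.

    ``polar`` marks polar day/night, where sunrise is undefined and the
    sunrise field is None.
    """

    date: pd.Timestamp
    expected_sunrise: pd.Timestamp | None
    solar_noon: pd.Timestamp
    polar: bool = False


def expected_sunrise(site: SiteLocation, date) -> SunTimes:
    """Sunrise and solar noon for ``date`` at ``site``.

    Sunrise is the crossing of the -0.833 deg standard altitude (geometric
    horizon with the usual refraction + semi-diameter correction). On polar
    days/nights the sunrise is flagged undefined rather than raising.
    """
    d = pd.Timestamp(date).normalize()
    doy = float(d.dayofyear)
    gamma = _day_angle(np.array([doy]), np.array([12.0]))
    decl = float(declination_rad(gamma)[0])
    eqtime = float(equation_of_time_min(gamma)[0])

    lat = np.radians(site.latitude)
    cos_h0 = (
        np.cos(np.radians(90.0 - SUNRISE_ALTITUDE_DEG))
        - np.sin(lat) * np.sin(decl)
    ) / (np.cos(lat) * np.cos(decl))

    noon_min = 720.0 - 4.0 * site.longitude - eqtime + 60.0 * site.utc_offset_hours
    noon = d + pd.Timedelta(minutes=noon_min)

    if cos_h0 < -1.0 or cos_h0 > 1.0:
        return SunTimes(date=d, expected_sunrise=None, solar_noon=noon, polar=True)

    ha_deg = np.degrees(np.arccos(cos_h0))
    sunrise_min = noon_min - 4.0 * ha_deg
    return SunTimes(
        date=d,
        expected_sunrise=d + pd.Timedelta(minutes=float(sunrise_min)),
        solar_noon=noon,
        polar=False,
    )


def require_non_polar(times: SunTimes) -> pd.Timestamp:
    if times.polar or times.expected_sunrise is None:
        raise PhenosenseError(f"sunrise undefined (polar day/night) on {times.date.date()}")
    return times.expected_sunrise
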