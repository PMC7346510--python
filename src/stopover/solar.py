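"""Sunset/sunrise computation and night-referenced departure timing.

Implements the NOAA solar-position algorithm (the one behind the NOAA
sunrise/sunset spreadsheet): solar declination and the equation of time
from the Julian century, hour angle at the standard rise/set zenith of
90.833 degrees (atmospheric refraction plus the solar radius).  Accuracy
is within about +/-2 minutes of almanac values at mid latitudes, which
is ample for expressing a nocturnal departure as minutes after sunset
or as a proportion of the night.

Polar day/night is out of scope: latitudes must stay below 66 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Tuple

import pandas as pd

#: Zenith angle (degrees) defining "official" sunrise/sunset.
SET_RISE_ZENITH = 90.833


class PolarConditionsError(ValueError):
    """Sun does not rise or set on this date at this latitude."""


def _julian_day(d: date) -> float:
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _solar_params(jd: float) -> Tuple[float, float]:
    """(declination [rad], equation of time [minutes]) at Julian day jd."""
    t = (jd - 2451545.0) / 36525.0
    l0 = math.radians((280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0)
    m = math.radians(357.52911 + t * (35999.05029 - 0.0001537 * t))
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    c = (
        math.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * m) * (0.019993 - 0.000101 * t)
        + math.sin(3 * m) * 0.000289
    )
    true_long = math.degrees(l0) + c
    omega = math.radians(125.04 - 1934.136 * t)
    app_long = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    obliq0 = 23.0 + (26.0 + (21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = math.radians(obliq0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(obliq) * math.sin(app_long))
    y = math.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * y * y * math.sin(4 * l0)
        - 1.25 * ecc * ecc * math.sin(2 * m)
    )
    return decl, eqtime


def _hour_angle(lat_rad: float, decl: float) -> float:
    cos_h = (
        math.cos(math.radians(SET_RISE_ZENITH)) / (math.cos(lat_rad) * math.cos(decl))
        - math.tan(lat_rad) * math.tan(decl)
    )
    if not -1.0 <= cos_h <= 1.0:
        raise PolarConditionsError("sun does not cross the set/rise zenith on this date")
    return math.acos(cos_h)


def _event_utc(d: date, latitude: float, longitude: float, rising: bool) -> datetime:
    if abs(latitude) >= 66.0:
        raise PolarConditionsError(f"latitude {latitude} outside supported range (|lat| < 66)")
    jd = _julian_day(d)
    # One refinement pass: evaluate declination/eqtime at the event itself.
    minutes = 720.0
    for _ in range(2):
        decl, eqtime = _solar_params(jd + minutes / 1440.0)
        ha = _hour_angle(math.radians(latitude), decl)
        noon = 720.0 - 4.0 * longitude - eqtime
        minutes = noon + (-1.0 if rising else 1.0) * 4.0 * math.degrees(ha)
    base = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    return base + timedelta(minutes=minutes)


def sun_events(d: date, latitude: float, longitude: float) -> Tuple[datetime, datetime]:
    """(sunset on day ``d``, sunrise on the following day), both UTC."""
    sunset = _event_utc(d, latitude, longitude, rising=False)
    sunrise = _event_utc(d + timedelta(days=1), latitude, longitude, rising=True)
    return sunset, sunrise


@dataclass(frozen=True)
class NightTiming:
    """A departure instant referenced to the night it falls in."""

    sunset: datetime
    next_sunrise: datetime
    night_length_min: float
    minutes_after_sunset: float
    proportion_of_night: float | None
    diurnal: bool = False


def night_timing(take_off: datetime | pd.Timestamp, latitude: float, longitude: float) -> NightTiming:
    """Express a take-off instant as minutes after sunset / night fraction.

    The night is the one containing (or, for a diurnal take-off, the one
    starting on) the take-off's UTC date; take-offs after local midnight
    are referred back to the previous evening's sunset.  A take-off
    outside (sunset, sunrise) is flagged diurnal and the proportion left
    undefined.
    """
    t = pd.Timestamp(take_off)
    if t.tzinfo is None:
        t = t.tz_localize("UTC")
    t = t.tz_convert("UTC").to_pydatetime()
    sunset, sunrise = sun_events(t.date(), latitude, longitude)
    if t < sunset:
        # Possibly in the night that started the previous day.
        prev_set, prev_rise = sun_events(t.date() - timedelta(days=1), latitude, longitude)
        if t <= prev_rise:
            sunset, sunrise = prev_set, prev_rise
    night_len = (sunrise - sunset).total_seconds() / 60.0
    mins = (t - sunset).total_seconds() / 60.0
    if mins < 0 or t > sunrise:
        return NightTiming(sunset, sunrise, night_len, mins, None, diurnal=True)
    return NightTiming(sunset, sunrise, night_len, mins, mins / night_len)
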