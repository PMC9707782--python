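"""Sunrise and sunset from low-precision solar geometry.

Implements the NOAA/Meeus low-precision solar position algorithm with the
conventional -0.833 degree solar altitude for rise and set (solar radius plus
standard atmospheric refraction).  Accuracy is within about +/-2 minutes of
the NOAA reference calculator for non-polar latitudes, which is ample for
classifying camera-trap detections as diurnal or nocturnal.

Times are reported in a fixed civil UTC offset supplied by the caller; no
daylight-saving logic is applied (the offset is explicit per run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

__all__ = ["SunTimes", "sun_times", "PolarLatitudeError"]

#: Solar altitude (degrees) defining rise/set: -0.833 = refraction + solar radius.
RISE_SET_ALTITUDE = -0.833

#: Latitude band supported; beyond this polar day/night can occur.
MAX_LATITUDE = 66.5


class PolarLatitudeError(ValueError):
    """Raised for latitudes where the sun may not rise or set."""


@dataclass(frozen=True)
class SunTimes:
    """Sunrise and sunset for one site and civil date."""

    sunrise: datetime
    sunset: datetime
    date: date
    latitude: float
    longitude: float

    @property
    def day_length_hours(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


def _julian_day(d: date) -> float:
    """Julian day number at 00:00 UT for a Gregorian calendar date."""
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _solar_params(jd: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (degrees) at a Julian day."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long))))
    y = math.tan(math.radians(eps) / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * e * math.sin(mrad)
        + 4 * e * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mrad)
    )
    return eot, decl


def _hour_angle(latitude: float, decl: float) -> float:
    """Hour angle (degrees) of the rise/set altitude; raises in polar regimes."""
    lat_r = math.radians(latitude)
    dec_r = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(90.0 - RISE_SET_ALTITUDE)) / (math.cos(lat_r) * math.cos(dec_r))
        - math.tan(lat_r) * math.tan(dec_r)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise PolarLatitudeError(
            f"sun does not rise/set at latitude {latitude:.2f} on this date (polar day/night)"
        )
    return math.degrees(math.acos(cos_ha))


def sun_times(latitude: float, longitude: float, on: date, utc_offset: float = -8.0) -> SunTimes:
    """Sunrise and sunset for a coordinate and civil date.

    Parameters
    ----------
    latitude, longitude
        Decimal degrees; longitude east-positive. ``|latitude|`` must be
        below 66.5 (no polar day/night).
    on
        Civil date in the target offset.
    utc_offset
        Fixed civil offset in hours (default -8, Pacific Standard Time).

    Returns
    -------
    SunTimes with timezone-aware sunrise and sunset in the given offset.
    """
    if abs(latitude) >= MAX_LATITUDE:
        raise PolarLatitudeError(
            f"latitude {latitude:.2f} outside supported band (|lat| < {MAX_LATITUDE})"
        )
    tz = timezone(timedelta(hours=utc_offset))
    jd = _julian_day(on)
    # Evaluate solar parameters at local solar noon (first pass), then refine
    # each event once at its own time; one refinement is well within +/-2 min.
    eot, decl = _solar_params(jd + 0.5 - longitude / 360.0 - utc_offset / 24.0)
    noon_min = 720.0 - 4.0 * longitude - eot + utc_offset * 60.0

    def _event(sign: float) -> datetime:
        ha = _hour_angle(latitude, decl)
        minutes = noon_min + sign * 4.0 * ha
        # refine with parameters at the event time itself
        eot2, decl2 = _solar_params(jd + minutes / 1440.0 - utc_offset / 24.0)
        ha2 = _hour_angle(latitude, decl2)
        minutes = 720.0 - 4.0 * longitude - eot2 + utc_offset * 60.0 + sign * 4.0 * ha2
        base = datetime(on.year, on.month, on.day, tzinfo=tz)
        return base + timedelta(minutes=minutes)

    sunrise = _event(-1.0)
    sunset = _event(+1.0)
    return SunTimes(sunrise=sunrise, sunset=sunset, date=on, latitude=latitude, longitude=longitude)
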