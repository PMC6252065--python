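"""Sunrise/sunset computation, solar offsets, diel periods and seasons.

Sun times come from the NOAA solar-position equations (the spreadsheet
formulation of the Meeus algorithm) with the conventional refraction
zenith of 90.833 deg.  Accuracy is a minute or two at mid-latitudes,
far below the one-hour resolution of the downstream activity analysis.

Two conventions anchor everything downstream:

* **Offsets** — a detection between 00:00 and 11:59 is offset against
  that day's sunrise, one between 12:00 and 23:59 against sunset.  The
  offset is positive when the detection falls in daylight (between
  sunrise and sunset) and negative otherwise.  So a 22:10 detection with
  sunset at 20:00 has an offset of -2 h 10 min: nocturnal activity.
* **Diel periods** — dawn is [sunrise-1h, sunrise+1h), day is
  [sunrise+1h, sunset-1h), dusk is [sunset-1h, sunset+1h) and night is
  the remainder of the 24-h circle.  The four half-open intervals tile
  the circle exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date, datetime, time, timedelta

__all__ = [
    "SolarDay",
    "Offset",
    "sun_times",
    "offset_from_sun",
    "diel_period",
    "diel_durations",
    "season_of",
    "SEASONS",
]

SEASONS = ("spring", "summer", "autumn", "winter")

_ZENITH_DEG = 90.833  # official sunrise/sunset: refraction + solar radius
_MAX_ABS_LATITUDE = 66.5  # no polar day/night handling


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset for one date at one location, in local civil time."""

    date: Date
    latitude: float
    longitude: float
    utc_offset: float
    sunrise: datetime
    sunset: datetime

    @property
    def day_length(self) -> timedelta:
        return self.sunset - self.sunrise


@dataclass(frozen=True)
class Offset:
    """Signed detection offset from its solar anchor.

    ``hours`` is positive for daylight detections and negative for
    night-time ones; ``anchor`` records whether sunrise or sunset was the
    reference instant.
    """

    hours: float
    anchor: str  # "sunrise" | "sunset"

    @property
    def minutes(self) -> int:
        """Offset rounded to whole minutes (sign preserved)."""
        return round(self.hours * 60)


def _julian_day_number(d: Date) -> int:
    """Julian day number of the Gregorian date at 12:00 UT."""
    a = (14 - d.month) // 12
    y = d.year + 4800 - a
    m = d.month + 12 * a - 3
    return (
        d.day
        + (153 * m + 2) // 5
        + 365 * y
        + y // 4
        - y // 100
        + y // 400
        - 32045
    )


def sun_times(d: Date, latitude: float, longitude: float, utc_offset: float) -> SolarDay:
    """Compute local sunrise and sunset for a date and location.

    Parameters
    ----------
    d
        Calendar date.
    latitude, longitude
        Decimal degrees; east and north positive.  ``|latitude|`` must be
        below 66.5 deg (no polar day/night support).
    utc_offset
        Fixed offset of local civil time from UTC, in hours.

    Returns
    -------
    SolarDay
        With sunrise and sunset as timezone-naive local datetimes on ``d``.
    """
    if abs(latitude) >= _MAX_ABS_LATITUDE:
        raise ValueError(
            f"latitude {latitude} unsupported: polar day/night can occur above "
            f"{_MAX_ABS_LATITUDE} deg"
        )
    rad = math.radians
    deg = math.degrees

    # Julian centuries since J2000.0, evaluated at local civil noon.
    jd = _julian_day_number(d) - utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eccent = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_of_center = (
        math.sin(rad(geom_mean_anom)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(rad(2 * geom_mean_anom)) * (0.019993 - 0.000101 * jc)
        + math.sin(rad(3 * geom_mean_anom)) * 0.000289
    )
    true_long = geom_mean_long + eq_of_center
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(rad(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(rad(omega))
    declination = deg(math.asin(math.sin(rad(obliq)) * math.sin(rad(app_long))))

    var_y = math.tan(rad(obliq / 2.0)) ** 2
    eq_time = 4.0 * deg(
        var_y * math.sin(2.0 * rad(geom_mean_long))
        - 2.0 * eccent * math.sin(rad(geom_mean_anom))
        + 4.0 * eccent * var_y * math.sin(rad(geom_mean_anom)) * math.cos(2.0 * rad(geom_mean_long))
        - 0.5 * var_y * var_y * math.sin(4.0 * rad(geom_mean_long))
        - 1.25 * eccent * eccent * math.sin(2.0 * rad(geom_mean_anom))
    )

    cos_ha = (
        math.cos(rad(_ZENITH_DEG)) / (math.cos(rad(latitude)) * math.cos(rad(declination)))
        - math.tan(rad(latitude)) * math.tan(rad(declination))
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(f"sun does not rise/set on {d} at latitude {latitude}")
    ha_deg = deg(math.acos(cos_ha))

    solar_noon_min = 720.0 - 4.0 * longitude - eq_time + utc_offset * 60.0
    sunrise_min = solar_noon_min - 4.0 * ha_deg
    sunset_min = solar_noon_min + 4.0 * ha_deg

    midnight = datetime.combine(d, time(0, 0))
    return SolarDay(
        date=d,
        latitude=latitude,
        longitude=longitude,
        utc_offset=utc_offset,
        sunrise=midnight + timedelta(minutes=sunrise_min),
        sunset=midnight + timedelta(minutes=sunset_min),
    )


def offset_from_sun(timestamp: datetime, solar_day: SolarDay) -> Offset:
    """Offset of a detection from its sunrise/sunset anchor.

    Detections with a clock time before 12:00 are anchored to sunrise,
    those at or after 12:00 to sunset.  The magnitude is the absolute
    time difference to the anchor; the sign is positive iff the
    detection lies between sunrise and sunset (daylight).
    """
    if timestamp.date() != solar_day.date:
        raise ValueError(
            f"timestamp date {timestamp.date()} does not match SolarDay {solar_day.date}"
        )
    if timestamp.hour < 12:
        anchor_name, anchor = "sunrise", solar_day.sunrise
    else:
        anchor_name, anchor = "sunset", solar_day.sunset
    magnitude = abs((timestamp - anchor).total_seconds()) / 3600.0
    daylight = solar_day.sunrise <= timestamp <= solar_day.sunset
    return Offset(hours=magnitude if daylight else -magnitude, anchor=anchor_name)


def _hours_of_day(t: datetime) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9


def diel_period(timestamp: datetime, solar_day: SolarDay) -> str:
    """Assign a timestamp to dawn, day, dusk or night.

    Dawn/dusk are the two-hour windows centred on sunrise/sunset, day the
    interval between them, night the rest; intervals are closed at their
    start and open at their end so every instant gets exactly one label.
    """
    if timestamp.date() != solar_day.date:
        raise ValueError(
            f"timestamp date {timestamp.date()} does not match SolarDay {solar_day.date}"
        )
    t = _hours_of_day(timestamp)
    sr = _hours_of_day(solar_day.sunrise)
    ss = _hours_of_day(solar_day.sunset)
    if sr - 1.0 <= t < sr + 1.0:
        return "dawn"
    if sr + 1.0 <= t < ss - 1.0:
        return "day"
    if ss - 1.0 <= t < ss + 1.0:
        return "dusk"
    return "night"


def diel_durations(solar_day: SolarDay) -> dict[str, float]:
    """Durations (hours) of the four diel periods; they always sum to 24."""
    day_len = solar_day.day_length.total_seconds() / 3600.0
    return {
        "dawn": 2.0,
        "day": day_len - 2.0,
        "dusk": 2.0,
        "night": 24.0 - day_len - 2.0,
    }


def season_of(d: Date) -> str:
    """Meteorological season of a date.

    Spring is March-May, summer June-August, autumn September-November
    and winter December-February.
    """
    if 3 <= d.month <= 5:
        return "spring"
    if 6 <= d.month <= 8:
        return "summer"
    if 9 <= d.month <= 11:
        return "autumn"
    return "winter"
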