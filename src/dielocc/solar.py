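"""Solar geometry for diel-period classification.

Camera-trap photos are split into day and night records, where day runs
from one hour before sunrise to one hour after sunset and night is the
complement.  Sunrise and sunset are computed from the NOAA solar position
equations at a single reference point (the centroid of the study
landscape), so every site in a survey shares one diel clock.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

__all__ = [
    "UnsupportedLocationError",
    "solar_times",
    "classify_period",
    "SolarProvider",
    "DAY",
    "NIGHT",
    "DAY_BUFFER",
]

#: period labels used throughout the package (day = 1, night = 2 in the model)
DAY = "day"
NIGHT = "night"

#: the day window extends this far beyond the sun's own rise/set times
DAY_BUFFER = dt.timedelta(hours=1)

# refraction-corrected zenith for official sunrise/sunset
_ZENITH_DEG = 90.833


class UnsupportedLocationError(ValueError):
    """Raised for latitudes where the day/night partition breaks down."""


def _fractional_year(date: dt.date, hour: float) -> float:
    doy = date.timetuple().tm_yday
    return 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12) / 24.0)

def _equation_of_time(g: float) -> float:
    # minutes
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )

def _declination(g: float) -> float:
    # radians
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def solar_times(
    date: dt.date, lat: float, lon: float, utc_offset: float
) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset (local clock time) for ``date`` at (lat, lon).

    Parameters
    ----------
    date : datetime.date
        Calendar date, interpreted in the local clock defined by ``utc_offset``.
    lat, lon : float
        Geographic coordinates in decimal degrees (east/north positive).
    utc_offset : float
        Hours ahead of UTC of the local clock (negative for the Americas).

    Returns
    -------
    (sunrise, sunset) : pair of timezone-aware datetimes on ``date``.

    Raises
    ------
    UnsupportedLocationError
        Poleward of the polar circles, or on a date with no sunrise/sunset,
        the day/night partition is undefined for this analysis.
    """
    if abs(lat) >= 66.5:
        raise UnsupportedLocationError(
            f"latitude {lat:.2f} is beyond the polar circle; "
            "day/night classification is undefined"
        )
    g = _fractional_year(date, 12.0)
    eqtime = _equation_of_time(g)
    decl = _declination(g)
    lat_r = math.radians(lat)
    cos_ha = math.cos(math.radians(_ZENITH_DEG)) / (
        math.cos(lat_r) * math.cos(decl)
    ) - math.tan(lat_r) * math.tan(decl)
    if not -1.0 < cos_ha < 1.0:
        raise UnsupportedLocationError(
            f"no sunrise/sunset at latitude {lat:.2f} on {date}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime  # minutes UTC
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    tz = dt.timezone(dt.timedelta(hours=utc_offset))
    midnight = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    sunrise = (midnight + dt.timedelta(minutes=sunrise_min)).astimezone(tz)
    sunset = (midnight + dt.timedelta(minutes=sunset_min)).astimezone(tz)
    # express on the local calendar date (the UTC->local shift can move the
    # nominal date for longitudes far from the offset meridian)
    return sunrise, sunset


def classify_period(
    timestamp: dt.datetime, sunrise: dt.datetime, sunset: dt.datetime
) -> str:
    """Assign one photo timestamp to ``"day"`` or ``"night"``.

    Day is the half-open interval [sunrise − 1 h, sunset + 1 h); everything
    else on the same date is night.  The half-open right boundary makes the
    assignment deterministic for a photo stamped exactly one hour after
    sunset.
    """
    if timestamp.tzinfo is None:
        raise ValueError("naive timestamp: an explicit UTC offset is required")
    start = sunrise - DAY_BUFFER
    end = sunset + DAY_BUFFER
    return DAY if start <= timestamp < end else NIGHT


@dataclass(frozen=True)
class SolarProvider:
    """Per-survey source of sunrise/sunset at a fixed reference point.

    One provider is configured per survey with the landscape-centroid
    coordinates; results are cached per calendar date.
    """

    lat: float
    lon: float
    utc_offset: float

    def times(self, date: dt.date) -> tuple[dt.datetime, dt.datetime]:
        cached = _provider_cache.get((self.lat, self.lon, self.utc_offset, date))
        if cached is None:
            cached = solar_times(date, self.lat, self.lon, self.utc_offset)
            _provider_cache[(self.lat, self.lon, self.utc_offset, date)] = cached
        return cached

    def classify(self, timestamp: dt.datetime) -> str:
        sunrise, sunset = self.times(timestamp.date())
        return classify_period(timestamp, sunrise, sunset)

    @property
    def timezone(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset))


_provider_cache: dict[tuple, tuple[dt.datetime, dt.datetime]] = {}
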