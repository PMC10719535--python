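"""Solar ephemeris and daylight scheduling.

Implements a refraction-corrected solar position algorithm of the class used
by the NOAA solar calculator (truncated VSOP/Meeus series), accurate to about
0.1 degrees for years 1950-2050, which is far below the angular size of a
tree crown seen from across a field.  The frame convention for the whole
package is fixed here: azimuth is measured clockwise from geographic north
(0 deg = N, 90 deg = E) and the sun direction vector lives in a local
east-north-up (ENU) frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "Moment",
    "SunPosition",
    "SunVector",
    "sun_position",
    "sun_vector",
    "generate_moments",
    "schedule_frame",
]

_J2000 = 2451545.0  # julian day of 2000-01-01 12:00 UTC


@dataclass(frozen=True)
class Site:
    """Geographic site: latitude/longitude in degrees, fixed UTC offset in hours.

    The offset is the site's standard time (no daylight-saving transitions);
    the schedule grid is anchored on this local clock.
    """

    latitude: float
    longitude: float
    utc_offset: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range [-90, 90]: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range [-180, 180]: {self.longitude}")

    @property
    def tzinfo(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset))


@dataclass(frozen=True)
class SunPosition:
    """Sun bearing: azimuth clockwise from geographic north, altitude above horizon.

    The altitude is refraction-corrected (apparent altitude).
    """

    azimuth_deg: float
    altitude_deg: float


@dataclass(frozen=True)
class SunVector:
    """Unit vector toward the sun in the local east-north-up frame."""

    e: float
    n: float
    u: float


@dataclass
class Moment:
    """One timestamp in a simulation schedule.

    ``index`` is the ordinal position within the (filtered) schedule; ``sun``
    is attached by the schedule generator.
    """

    timestamp: datetime
    index: int = 0
    sun: Optional[SunPosition] = field(default=None, compare=False)


def _julian_day(times_utc: np.ndarray) -> np.ndarray:
    """Julian day from an array of numpy datetime64 values (UTC)."""
    epoch = np.datetime64("2000-01-01T12:00:00", "s")
    seconds = (times_utc.astype("datetime64[s]") - epoch) / np.timedelta64(1, "s")
    return _J2000 + seconds / 86400.0


def _solar_position_jd(jd: np.ndarray, latitude: float, longitude: float):
    """Vectorized apparent azimuth/altitude (degrees) for julian-day array."""
    jd = np.asarray(jd, dtype=float)
    T = (jd - _J2000) / 36525.0

    # Geometric mean longitude and anomaly of the sun, eccentricity.
    L0 = np.mod(280.46646 + T * (36000.76983 + T * 0.0003032), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)

    Mr = np.radians(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    # Obliquity (mean + nutation correction) and declination.
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(omega)
    eps_r = np.radians(eps)
    lam_r = np.radians(app_long)
    decl = np.arcsin(np.sin(eps_r) * np.sin(lam_r))

    # Equation of time, minutes.
    y = np.tan(eps_r / 2.0) ** 2
    L0r = np.radians(L0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )

    # True solar time -> hour angle.  jd fraction is UTC time of day.
    minutes_utc = np.mod(jd - 0.5, 1.0) * 1440.0
    tst = np.mod(minutes_utc + eot + 4.0 * longitude, 1440.0)
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)
    ha_r = np.radians(ha)

    lat_r = math.radians(latitude)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha_r)
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    zen = np.degrees(np.arccos(cos_zen))

    sin_zen = np.sin(np.radians(zen))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = (np.sin(lat_r) * cos_zen - np.sin(decl)) / (np.cos(lat_r) * sin_zen)
    cos_az = np.clip(np.where(np.isfinite(cos_az), cos_az, -1.0), -1.0, 1.0)
    az_base = np.degrees(np.arccos(cos_az))
    azimuth = np.where(ha > 0.0, np.mod(az_base + 180.0, 360.0), np.mod(540.0 - az_base, 360.0))

    altitude = 90.0 - zen + _refraction(90.0 - zen)
    return azimuth, altitude


def _refraction(elev_deg: np.ndarray) -> np.ndarray:
    """Atmospheric refraction correction (degrees) for true elevation."""
    e = np.asarray(elev_deg, dtype=float)
    te = np.tan(np.radians(np.where(np.abs(e) < 1e-9, 1e-9, e)))
    high = (58.1 / te - 0.07 / te**3 + 0.000086 / te**5) / 3600.0
    low = (1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))) / 3600.0
    deep = (-20.774 / te) / 3600.0
    corr = np.where(e > 85.0, 0.0, np.where(e > 5.0, high, np.where(e > -0.575, low, deep)))
    return corr


def _to_utc_array(timestamps: Sequence[datetime]) -> np.ndarray:
    utc = [t.astimezone(timezone.utc).replace(tzinfo=None) for t in timestamps]
    return np.array(utc, dtype="datetime64[s]")


def sun_position(moment: Moment | datetime, site: Site) -> SunPosition:
    """Apparent sun position for one moment at a site.

    The timestamp must carry a timezone (an unambiguous UTC mapping); naive
    timestamps are interpreted on the site's clock.
    """
    ts = moment.timestamp if isinstance(moment, Moment) else moment
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=site.tzinfo)
    jd = _julian_day(_to_utc_array([ts]))
    az, alt = _solar_position_jd(jd, site.latitude, site.longitude)
    return SunPosition(float(az[0]), float(alt[0]))


def sun_vector(pos: SunPosition) -> SunVector:
    """Unit ENU direction toward the sun: (cos a sin phi, cos a cos phi, sin a)."""
    phi = math.radians(pos.azimuth_deg)
    alpha = math.radians(pos.altitude_deg)
    return SunVector(
        math.cos(alpha) * math.sin(phi),
        math.cos(alpha) * math.cos(phi),
        math.sin(alpha),
    )


def _clock_grid(start: date, total_years: int, interval_minutes: int, site: Site):
    """All local-clock timestamps of the schedule as naive datetime64 array."""
    if total_years < 0:
        raise ValueError("total_years must be >= 0")
    if interval_minutes <= 0:
        raise ValueError("interval_minutes must be positive")
    t0 = np.datetime64(datetime(start.year, start.month, start.day), "s")
    end = start.replace(year=start.year + total_years)
    t1 = np.datetime64(datetime(end.year, end.month, end.day), "s")
    step = np.timedelta64(interval_minutes * 60, "s")
    return np.arange(t0, t1, step)


def generate_moments(
    start: date,
    total_years: int,
    interval_minutes: int,
    site: Site,
) -> list[Moment]:
    """Daylight schedule: every interval over ``total_years`` calendar years.

    Timestamps are generated on the site's local clock starting at 00:00 of
    the start date (leap days included); only moments whose refraction-
    corrected altitude is strictly above 0 deg are returned, each carrying its
    computed :class:`SunPosition`.
    """
    local = _clock_grid(start, total_years, interval_minutes, site)
    if local.size == 0:
        return []
    utc = local - np.timedelta64(int(round(site.utc_offset * 3600)), "s")
    az, alt = _solar_position_jd(_julian_day(utc), site.latitude, site.longitude)
    keep = alt > 0.0
    tz = site.tzinfo
    moments: list[Moment] = []
    for i, (t, a, h) in enumerate(zip(local[keep], az[keep], alt[keep])):
        ts = t.astype("datetime64[s]").item().replace(tzinfo=tz)
        moments.append(Moment(timestamp=ts, index=i, sun=SunPosition(float(a), float(h))))
    return moments


def daylight_count(start: date, total_years: int, interval_minutes: int, site: Site) -> int:
    """Number of schedule steps with apparent altitude > 0 (no Moment objects built)."""
    local = _clock_grid(start, total_years, interval_minutes, site)
    if local.size == 0:
        return 0
    utc = local - np.timedelta64(int(round(site.utc_offset * 3600)), "s")
    _, alt = _solar_position_jd(_julian_day(utc), site.latitude, site.longitude)
    return int(np.count_nonzero(alt > 0.0))


def schedule_frame(moments: Sequence[Moment]) -> pd.DataFrame:
    """Schedule as a DataFrame (timestamp, azimuth_deg, altitude_deg) for CSV dumps."""
    return pd.DataFrame(
        {
            "timestamp": [m.timestamp.isoformat() for m in moments],
            "azimuth_deg": [m.sun.azimuth_deg if m.sun else float("nan") for m in moments],
            "altitude_deg": [m.sun.altitude_deg if m.sun else float("nan") for m in moments],
        }
    )
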