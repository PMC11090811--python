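"""Solar position and day/night classification.

Implements the low-precision NOAA solar ephemeris (Julian centuries ->
solar declination and equation of time -> hour angle -> geometric
altitude).  Accuracy is a few hundredths of a degree over 2015-2025,
far below the tolerance that matters for day/night classification.

No atmospheric refraction is applied: the classification rule operates
on the geometric sun angle (negative = night, non-negative = day), and
refraction (~0.57 deg at the horizon) shifts sunrise/sunset by less
than four minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sun_altitude", "classify_day_night", "sun_times", "solar_declination_eot"]

_J2000 = 2451545.0


def _to_julian_day(utc_time) -> np.ndarray:
    """UTC instants -> Julian day (float). Accepts scalars or arrays."""
    ts = pd.to_datetime(utc_time, utc=True)
    if isinstance(ts, pd.Timestamp):
        ts = pd.DatetimeIndex([ts])
        scalar = True
    else:
        ts = pd.DatetimeIndex(ts)
        scalar = False
    # Unix epoch 1970-01-01 00:00 UTC is JD 2440587.5
    jd = 2440587.5 + ts.asi8 / 1e9 / 86400.0
    jd = np.asarray(jd, dtype=float)
    return jd[0] if scalar else jd


def solar_declination_eot(jd):
    """Solar declination (deg) and equation of time (minutes) at Julian day ``jd``.

    NOAA general solar-position equations (Meeus-style truncated series).
    """
    T = (np.asarray(jd, dtype=float) - _J2000) / 36525.0
    rad = np.deg2rad

    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        np.sin(rad(M)) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(rad(2 * M)) * (0.019993 - 0.000101 * T)
        + np.sin(rad(3 * M)) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(rad(omega))

    # mean obliquity (arcsec series) + nutation correction used by NOAA
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.8150 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(rad(omega))

    decl = np.rad2deg(np.arcsin(np.sin(rad(eps)) * np.sin(rad(app_long))))

    y = np.tan(rad(eps) / 2.0) ** 2
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * rad(L0))
        - 2.0 * e * np.sin(rad(M))
        + 4.0 * e * y * np.sin(rad(M)) * np.cos(2 * rad(L0))
        - 0.5 * y * y * np.sin(4 * rad(L0))
        - 1.25 * e * e * np.sin(2 * rad(M))
    )
    return decl, eot


def sun_altitude(latitude, longitude, utc_time):
    """Geometric solar altitude in degrees (no refraction).

    Parameters
    ----------
    latitude, longitude
        Degrees; longitude positive east. Scalars or arrays.
    utc_time
        Anything :func:`pandas.to_datetime` parses to UTC instants
        (tz-aware timestamps or ISO 8601 strings with offset; naive
        input is taken as UTC). Scalar or array-like.

    Returns
    -------
    float or ndarray
        Altitude in [-90, 90] degrees.
    """
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("latitude must be in [-90, 90] and longitude in [-180, 180]")

    jd = _to_julian_day(utc_time)
    decl, eot = solar_declination_eot(jd)

    frac_day = np.mod(np.asarray(jd) + 0.5, 1.0)  # fraction of UTC day since midnight
    true_solar_min = np.mod(frac_day * 1440.0 + eot + 4.0 * lon, 1440.0)
    hour_angle = true_solar_min / 4.0 - 180.0

    rad = np.deg2rad
    sin_alt = np.sin(rad(lat)) * np.sin(rad(decl)) + np.cos(rad(lat)) * np.cos(
        rad(decl)
    ) * np.cos(rad(hour_angle))
    alt = np.rad2deg(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    scalar_in = np.ndim(latitude) == 0 and np.ndim(longitude) == 0 and np.ndim(jd) == 0
    return float(alt) if scalar_in else np.asarray(alt)


def classify_day_night(altitude_deg):
    """Map solar altitude(s) to ``"day"`` / ``"night"``.

    Night is a strictly negative sun angle; altitude exactly 0 counts
    as day (documented tie rule; ties are measure-zero).
    """
    alt = np.asarray(altitude_deg, dtype=float)
    out = np.where(alt < 0.0, "night", "day")
    return str(out) if out.ndim == 0 else out


def sun_times(latitude, longitude, date):
    """Sunrise and sunset (UTC) for the given civil date at a location.

    Returns ``(sunrise, sunset)`` as pandas Timestamps (UTC) for the
    date's solar day centred on local solar noon, or ``None`` for polar
    day / polar night.  Uses the closed-form hour-angle solution with
    declination and equation of time evaluated at local solar noon,
    refined by a few bisection steps on the geometric altitude.
    """
    day = pd.Timestamp(date).tz_localize(None).normalize().tz_localize("UTC")
    jd0 = _to_julian_day(day)

    # local solar noon (minutes UTC)
    _, eot = solar_declination_eot(jd0 + 0.5)
    noon_min = 720.0 - 4.0 * float(longitude) - float(eot)
    noon = day + pd.Timedelta(minutes=noon_min)

    decl, _ = solar_declination_eot(_to_julian_day(noon))
    rad = np.deg2rad
    cos_h0 = -np.tan(rad(float(latitude))) * np.tan(rad(float(decl)))
    if cos_h0 >= 1.0 or cos_h0 <= -1.0:
        return None  # polar night (>=1) or polar day (<=-1)
    h0 = np.rad2deg(np.arccos(cos_h0))  # degrees; 4 min per degree
    sunrise = noon - pd.Timedelta(minutes=4.0 * h0)
    sunset = noon + pd.Timedelta(minutes=4.0 * h0)

    def _refine(lo, hi):
        # altitude crosses zero once in [lo, hi]
        for _ in range(20):
            mid = lo + (hi - lo) / 2
            if sun_altitude(latitude, longitude, lo) * sun_altitude(latitude, longitude, mid) <= 0:
                hi = mid
            else:
                lo = mid
        return lo + (hi - lo) / 2

    half = pd.Timedelta(minutes=20)
    sunrise = _refine(sunrise - half, sunrise + half)
    sunset = _refine(sunset - half, sunset + half)
    return sunrise, sunset
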