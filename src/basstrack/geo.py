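"""Spherical geodesy and the seasonal calendar convention."""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "season_of", "season_year"]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees (WGS84).

    Accepts scalars or broadcastable arrays. Rejects non-finite
    coordinates and latitudes outside [-90, 90].
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for arr in (lat1, lon1, lat2, lon2):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite coordinate")
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


_MONTH_SEASON = {
    12: "Dec-Feb", 1: "Dec-Feb", 2: "Dec-Feb",
    3: "Mar-May", 4: "Mar-May", 5: "Mar-May",
    6: "Jun-Aug", 7: "Jun-Aug", 8: "Jun-Aug",
    9: "Sep-Nov", 10: "Sep-Nov", 11: "Sep-Nov",
}


def season_of(day) -> str:
    """Season label of a date: Dec-Feb (winter), Mar-May (spring),
    Jun-Aug (summer), Sep-Nov (autumn)."""
    if isinstance(day, (datetime.date, datetime.datetime)):
        month = day.month
    else:
        month = pd.Timestamp(day).month
    return _MONTH_SEASON[month]


def season_year(day) -> int:
    """Year a season belongs to; December is grouped with the following
    January-February."""
    ts = pd.Timestamp(day)
    return ts.year + 1 if ts.month == 12 else ts.year
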