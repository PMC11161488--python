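"""Domain containers shared by every pipeline stage.

The study objects are: archival tag records (depth/temperature series from
data-storage tags), gridded ocean reference fields (bathymetry plus daily
two-layer temperature), acoustic detection logs with their receiver
stations, mark-recapture records, and named sea-area polygons used to
label daily positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "TagSeries",
    "DailyObservation",
    "GriddedField",
    "DetectionSet",
    "RecaptureRecord",
    "AreaSet",
    "SEASONS",
]

SEASONS = ("Dec-Feb", "Mar-May", "Jun-Aug", "Sep-Nov")


@dataclass(frozen=True)
class TagSeries:
    """Raw time-stamped depth/temperature record of one archival tag.

    ``records`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``depth_m`` (positive down; small negatives down to -1 m tolerated as
    sensor noise) and ``temp_c``.
    """

    tag_id: str
    records: pd.DataFrame
    sampling_interval: float  # seconds
    release: tuple[Date, float, float]  # (date, lat, lon)
    recovery: Optional[tuple[Date, float, float]] = None

    def __post_init__(self) -> None:
        ts = self.records["timestamp"]
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(ts) and ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing (duplicates)")
        depth = self.records["depth_m"].to_numpy()
        if len(depth) and not np.all(np.isfinite(depth)):
            raise ValueError("depth must be finite")
        if len(depth) and depth.min() < -1.0:
            raise ValueError("depth below -1 m violates the sensor-noise tolerance")
        if len(ts):
            first_day = ts.iloc[0].date()
            if (pd.Timestamp(first_day) - pd.Timestamp(self.release[0])).days < -1:
                raise ValueError("release date must precede the record start")

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class DailyObservation:
    """One calendar day of summarised tag data."""

    date: Date
    max_depth: float
    min_depth: float
    med_depth: float
    mean_temp: float
    temp_range: float
    activity_index: float  # sum |successive depth differences| within day, m
    cooling_water: bool = False
    inshore_variability: bool = False
    presumed_dead: bool = False
    activity_defined: bool = True

    def __post_init__(self) -> None:
        if self.max_depth < self.min_depth:
            raise ValueError("max_depth must be >= min_depth")
        if self.activity_defined and self.activity_index < 0:
            raise ValueError("activity_index must be non-negative")


class GriddedField:
    """Regular lat/lon grid carrying bathymetry and daily two-layer temperature.

    Bathymetry is positive-down in metres; cells with bathymetry <= 0 are
    land. Temperatures are daily surface and bottom layers on the same grid.
    """

    def __init__(
        self,
        lats: np.ndarray,
        lons: np.ndarray,
        bathymetry: np.ndarray,
        dates: pd.DatetimeIndex,
        temp_surface: np.ndarray,
        temp_bottom: np.ndarray,
    ) -> None:
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        for name, v in (("lat", lats), ("lon", lons)):
            if v.ndim != 1 or len(v) < 2:
                raise ValueError(f"{name} axis must be a 1-D vector of length >= 2")
            steps = np.diff(v)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"non-uniform {name} grid spacing")
        bathymetry = np.asarray(bathymetry, dtype=float)
        if bathymetry.shape != (len(lats), len(lons)):
            raise ValueError("bathymetry shape must be (nlat, nlon)")
        temp_surface = np.asarray(temp_surface, dtype=float)
        temp_bottom = np.asarray(temp_bottom, dtype=float)
        expected = (len(dates), len(lats), len(lons))
        if temp_surface.shape != expected or temp_bottom.shape != expected:
            raise ValueError("temperature shape must be (time, nlat, nlon)")
        water = bathymetry > 0
        for name, t in (("surface", temp_surface), ("bottom", temp_bottom)):
            if not np.all(np.isfinite(t[:, water])):
                raise ValueError(f"{name} temperature undefined on water cells")
        self.lats = lats
        self.lons = lons
        self.bathymetry = bathymetry
        self.dates = pd.DatetimeIndex(dates)
        self.temp_surface = temp_surface
        self.temp_bottom = temp_bottom

    # -- geometry helpers -------------------------------------------------
    @property
    def land_mask(self) -> np.ndarray:
        return self.bathymetry <= 0

    @property
    def water_mask(self) -> np.ndarray:
        return self.bathymetry > 0

    @property
    def lat_spacing(self) -> float:
        return float(self.lats[1] - self.lats[0])

    @property
    def lon_spacing(self) -> float:
        return float(self.lons[1] - self.lons[0])

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the nearest cell centre (ties toward the lower index)."""
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j

    def day_index(self, day) -> int:
        ts = pd.Timestamp(day)
        loc = self.dates.get_indexer([ts])
        if loc[0] < 0:
            raise KeyError(f"date {ts.date()} outside field range")
        return int(loc[0])

    def is_water(self, lat: float, lon: float) -> bool:
        i, j = self.nearest_cell(lat, lon)
        return bool(self.water_mask[i, j])

    def __eq__(self, other) -> bool:  # round-trip tests
        if not isinstance(other, GriddedField):
            return NotImplemented
        return (
            np.allclose(self.lats, other.lats)
            and np.allclose(self.lons, other.lons)
            and np.allclose(self.bathymetry, other.bathymetry)
            and self.dates.equals(other.dates)
            and np.allclose(self.temp_surface, other.temp_surface, equal_nan=True)
            and np.allclose(self.temp_bottom, other.temp_bottom, equal_nan=True)
        )


@dataclass(frozen=True)
class DetectionSet:
    """Receiver stations and the acoustic detections logged on them.

    ``stations``: DataFrame(station_id, lat, lon, array).
    ``detections``: DataFrame(tag_id, timestamp, station_id).
    """

    stations: pd.DataFrame
    detections: pd.DataFrame

    def __post_init__(self) -> None:
        known = set(self.stations["station_id"])
        used = set(self.detections["station_id"]) if len(self.detections) else set()
        missing = used - known
        if missing:
            raise ValueError(f"detections reference unknown stations: {sorted(missing)}")

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    def for_tag(self, tag_id: str) -> pd.DataFrame:
        sub = self.detections[self.detections["tag_id"] == tag_id]
        return sub.sort_values("timestamp").reset_index(drop=True)

    def station_lookup(self) -> pd.DataFrame:
        return self.stations.set_index("station_id")


@dataclass(frozen=True)
class RecaptureRecord:
    """One marked fish released and later recaptured."""

    tag_id: str
    release: tuple[Date, float, float]
    recapture: tuple[Date, float, float]

    def __post_init__(self) -> None:
        if self.recapture[0] < self.release[0]:
            raise ValueError("recapture date precedes release date")

    @property
    def days_at_large(self) -> int:
        return (self.recapture[0] - self.release[0]).days


class AreaSet:
    """Named, non-overlapping sea-area polygons (ICES-division analogues).

    Optionally carries cooling-water point sources (power-plant outfalls)
    as (lat, lon, radius_km) triples.
    """

    def __init__(
        self,
        polygons: dict[str, BaseGeometry],
        cooling_sources: Sequence[tuple[float, float, float]] = (),
    ) -> None:
        names = list(polygons)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                inter = polygons[names[a]].intersection(polygons[names[b]])
                if inter.area > 1e-9:
                    raise ValueError(
                        f"areas {names[a]!r} and {names[b]!r} overlap"
                    )
        self.polygons = dict(polygons)
        self.cooling_sources = tuple(cooling_sources)
        self._names = list(self.polygons)
        self._tree = STRtree(list(self.polygons.values()))

    def area_of(self, lat: float, lon: float) -> Optional[str]:
        """Name of the polygon containing the point, or None."""
        pt = Point(lon, lat)
        for k in self._tree.query(pt):
            if self.polygons[self._names[int(k)]].covers(pt):
                return self._names[int(k)]
        return None

    def __eq__(self, other) -> bool:
        if not isinstance(other, AreaSet):
            return NotImplemented
        if set(self.polygons) != set(other.polygons):
            return False
        return all(
            self.polygons[n].equals_exact(other.polygons[n], 1e-9)
            for n in self.polygons
        )
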