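"""Readers and writers for the pipeline's file formats.

Tag series, detections, stations and recaptures travel as headered CSV
with ISO-8601 UTC timestamps; gridded reference fields as NetCDF
(time, lat, lon); area polygons as GeoJSON FeatureCollections with a
``name`` property. Malformed rows are rejected (dropped and counted in
the log), never silently coerced.
"""

from __future__ import annotations

import json
import logging
from datetime import date as Date
from pathlib import Path
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .types import AreaSet, DetectionSet, GriddedField, RecaptureRecord, TagSeries

log = logging.getLogger("basstrack.io")

TAG_COLUMNS = ["tag_id", "timestamp", "depth_m", "temp_c"]
DET_COLUMNS = ["tag_id", "timestamp", "station_id"]
STATION_COLUMNS = ["station_id", "lat", "lon", "array"]
RECAPTURE_COLUMNS = [
    "tag_id",
    "release_date", "release_lat", "release_lon",
    "recapture_date", "recapture_lat", "recapture_lon",
]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def _parse_utc(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")


def _drop_bad(df: pd.DataFrame, bad: pd.Series, what: str) -> pd.DataFrame:
    n = int(bad.sum())
    if n:
        log.warning("%s: rejected %d malformed rows", what, n)
    return df.loc[~bad].reset_index(drop=True)


# --------------------------------------------------------------------------
# tag series
# --------------------------------------------------------------------------

def write_tag_series(series: TagSeries, path) -> None:
    """Write the record CSV plus a ``<stem>_meta.csv`` sidecar carrying
    release/recovery anchors and the sampling interval."""
    path = Path(path)
    out = series.records.copy()
    out.insert(0, "tag_id", series.tag_id)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)
    meta = {
        "tag_id": series.tag_id,
        "sampling_interval_s": series.sampling_interval,
        "release_date": series.release[0].isoformat(),
        "release_lat": series.release[1],
        "release_lon": series.release[2],
    }
    if series.recovery is not None:
        meta.update(
            recovery_date=series.recovery[0].isoformat(),
            recovery_lat=series.recovery[1],
            recovery_lon=series.recovery[2],
        )
    pd.DataFrame([meta]).to_csv(path.with_name(path.stem + "_meta.csv"), index=False)


def read_tag_series(path, meta_path=None) -> TagSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TAG_COLUMNS, f"tag series {path.name}")
    df["timestamp"] = _parse_utc(df["timestamp"])
    df["depth_m"] = pd.to_numeric(df["depth_m"], errors="coerce")
    df["temp_c"] = pd.to_numeric(df["temp_c"], errors="coerce")
    bad = df["timestamp"].isna() | df["depth_m"].isna() | df["temp_c"].isna()
    df = _drop_bad(df, bad, f"tag series {path.name}")
    if df["tag_id"].nunique() > 1:
        raise ValueError(f"tag series {path.name}: more than one tag_id")
    tag_id = str(df["tag_id"].iloc[0]) if len(df) else path.stem

    if meta_path is None:
        meta_path = path.with_name(path.stem + "_meta.csv")
    meta = pd.read_csv(meta_path).iloc[0]
    release = (
        Date.fromisoformat(str(meta["release_date"])),
        float(meta["release_lat"]),
        float(meta["release_lon"]),
    )
    recovery = None
    if "recovery_date" in meta.index and not pd.isna(meta["recovery_date"]):
        recovery = (
            Date.fromisoformat(str(meta["recovery_date"])),
            float(meta["recovery_lat"]),
            float(meta["recovery_lon"]),
        )
    return TagSeries(
        tag_id=tag_id,
        records=df[["timestamp", "depth_m", "temp_c"]].reset_index(drop=True),
        sampling_interval=float(meta["sampling_interval_s"]),
        release=release,
        recovery=recovery,
    )


# --------------------------------------------------------------------------
# detections / stations
# --------------------------------------------------------------------------

def write_detections(det: DetectionSet, det_path, station_path) -> None:
    out = det.detections.copy()
    if len(out):
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(det_path, index=False)
    det.stations.to_csv(station_path, index=False)


def read_detections(det_path, station_path) -> DetectionSet:
    stations = pd.read_csv(station_path)
    _require_columns(stations, STATION_COLUMNS, f"stations {Path(station_path).name}")
    try:
        det = pd.read_csv(det_path)
    except pd.errors.EmptyDataError:
        det = pd.DataFrame(columns=DET_COLUMNS)
    if len(det) == 0 and not set(DET_COLUMNS) <= set(det.columns):
        det = pd.DataFrame(columns=DET_COLUMNS)
    _require_columns(det, DET_COLUMNS, f"detections {Path(det_path).name}")
    if len(det):
        det["timestamp"] = _parse_utc(det["timestamp"])
        det = _drop_bad(det, det["timestamp"].isna(), f"detections {Path(det_path).name}")
    else:
        det = det.assign(timestamp=pd.to_datetime(det["timestamp"], utc=True))
    return DetectionSet(stations=stations, detections=det[DET_COLUMNS])


# --------------------------------------------------------------------------
# recaptures
# --------------------------------------------------------------------------

def write_recaptures(records: list[RecaptureRecord], path) -> None:
    rows = [
        {
            "tag_id": r.tag_id,
            "release_date": r.release[0].isoformat(),
            "release_lat": r.release[1],
            "release_lon": r.release[2],
            "recapture_date": r.recapture[0].isoformat(),
            "recapture_lat": r.recapture[1],
            "recapture_lon": r.recapture[2],
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECAPTURE_COLUMNS).to_csv(path, index=False)


def read_recaptures(path) -> list[RecaptureRecord]:
    df = pd.read_csv(path)
    _require_columns(df, RECAPTURE_COLUMNS, f"recaptures {Path(path).name}")
    records = []
    n_bad = 0
    for _, row in df.iterrows():
        try:
            records.append(
                RecaptureRecord(
                    tag_id=str(row["tag_id"]),
                    release=(
                        Date.fromisoformat(str(row["release_date"])),
                        float(row["release_lat"]),
                        float(row["release_lon"]),
                    ),
                    recapture=(
                        Date.fromisoformat(str(row["recapture_date"])),
                        float(row["recapture_lat"]),
                        float(row["recapture_lon"]),
                    ),
                )
            )
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        log.warning("recaptures %s: rejected %d malformed rows", Path(path).name, n_bad)
    return records


# --------------------------------------------------------------------------
# gridded field (NetCDF)
# --------------------------------------------------------------------------

def write_field(field: GriddedField, path) -> None:
    ds = xr.Dataset(
        {
            "bathymetry": (("lat", "lon"), field.bathymetry),
            "temp_surface": (("time", "lat", "lon"), field.temp_surface),
            "temp_bottom": (("time", "lat", "lon"), field.temp_bottom),
        },
        coords={"time": field.dates, "lat": field.lats, "lon": field.lons},
    )
    ds.to_netcdf(path, engine="scipy")


def read_field(path) -> GriddedField:
    with xr.open_dataset(path, engine="scipy") as ds:
        for v in ("bathymetry", "temp_surface", "temp_bottom"):
            if v not in ds:
                raise ValueError(f"field {Path(path).name}: missing variable {v}")
        return GriddedField(
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            bathymetry=ds["bathymetry"].values,
            dates=pd.DatetimeIndex(ds["time"].values),
            temp_surface=ds["temp_surface"].values,
            temp_bottom=ds["temp_bottom"].values,
        )


# --------------------------------------------------------------------------
# area polygons (GeoJSON)
# --------------------------------------------------------------------------

def write_areas(areas: AreaSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(geom),
        }
        for name, geom in areas.polygons.items()
    ]
    doc = {"type": "FeatureCollection", "features": features}
    if areas.cooling_sources:
        doc["cooling_sources"] = [list(s) for s in areas.cooling_sources]
    Path(path).write_text(json.dumps(doc))


def read_areas(path) -> AreaSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"areas {Path(path).name}: not a FeatureCollection")
    polygons = {}
    for feat in doc.get("features", []):
        name = feat.get("properties", {}).get("name")
        if name is None:
            raise ValueError(f"areas {Path(path).name}: feature without a name property")
        polygons[name] = shape(feat["geometry"])
    cooling = [tuple(s) for s in doc.get("cooling_sources", [])]
    return AreaSet(polygons, cooling)
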