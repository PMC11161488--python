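"""Raw tag series and detection logs -> clean daily observations.

Stages: depth-sensor drift correction (running minimum over 7 days),
daily summarisation, mortality truncation, cooling-water plume and
inshore-variability flagging, and acoustic-detection quality control.
The mortality/plume/inshore rules automate judgements the original
analyses made by eye, so all thresholds are exposed as arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .geo import haversine_km
from .types import DailyObservation, DetectionSet, GriddedField, TagSeries

log = logging.getLogger("basstrack.preprocess")

__all__ = [
    "CleanSeries",
    "correct_depth_drift",
    "summarize_daily",
    "detect_mortality",
    "flag_plume_days",
    "truncate_inshore_variability",
    "qc_detections",
    "clean_series",
]


@dataclass
class CleanSeries:
    """A tag series after corrections, with its daily summaries and the
    window of days usable for geolocation."""

    series: TagSeries
    daily: list[DailyObservation]
    alive_until: Date
    truncation_date: Date

    @property
    def usable_daily(self) -> list[DailyObservation]:
        """Days from release up to the mortality cut, excluding the
        inshore-variability tail."""
        end = min(self.alive_until, self.truncation_date)
        return [
            d
            for d in self.daily
            if d.date <= end and not d.inshore_variability
        ]


def correct_depth_drift(series: TagSeries, window: float = 7.0) -> TagSeries:
    """Remove depth-sensor drift by subtracting a centred running minimum
    over ``window`` days (edge windows shrink to the record), clamping the
    result at 0. Temperature is untouched."""
    if window < 1.0:
        raise ValueError("drift-correction window must be at least 1 day")
    if series.n_records == 0:
        return series
    w = max(int(round(window * 86400.0 / series.sampling_interval)), 1)
    depth = series.records["depth_m"].to_numpy(dtype=float)
    running_min = minimum_filter1d(depth, size=w, mode="nearest")
    corrected = np.clip(depth - running_min, 0.0, None)
    records = series.records.copy()
    records["depth_m"] = corrected
    return TagSeries(
        tag_id=series.tag_id,
        records=records,
        sampling_interval=series.sampling_interval,
        release=series.release,
        recovery=series.recovery,
    )


def summarize_daily(series: TagSeries) -> list[DailyObservation]:
    """Per-calendar-day (00:00-24:00 UTC) summaries. Small negative depths
    are clamped to 0 m. Days with fewer than two samples have an undefined
    activity index and are flagged."""
    if series.n_records == 0:
        return []
    rec = series.records
    depth = np.clip(rec["depth_m"].to_numpy(dtype=float), 0.0, None)
    df = pd.DataFrame(
        {
            "date": rec["timestamp"].dt.date,
            "depth": depth,
            "temp": rec["temp_c"].to_numpy(dtype=float),
        }
    )
    out = []
    for day, grp in df.groupby("date", sort=True):
        d = grp["depth"].to_numpy()
        tmp = grp["temp"].to_numpy()
        defined = len(d) >= 2
        activity = float(np.abs(np.diff(d)).sum()) if defined else 0.0
        out.append(
            DailyObservation(
                date=day,
                max_depth=float(d.max()),
                min_depth=float(d.min()),
                med_depth=float(np.median(d)),
                mean_temp=float(tmp.mean()),
                temp_range=float(tmp.max() - tmp.min()),
                activity_index=activity,
                activity_defined=defined,
            )
        )
    return out


def detect_mortality(
    daily: list[DailyObservation],
    activity_threshold: float = 1.0,
    range_threshold: float = 0.5,
    min_run: int = 7,
) -> Date:
    """Last date the fish is presumed alive.

    A terminal run of >= ``min_run`` flat days (activity index below
    ``activity_threshold`` m and daily depth range below
    ``range_threshold`` m) through the end of the record marks death;
    ``alive_until`` is the day before the run starts. Flat spells that end
    before the record does never truncate."""
    if not daily:
        raise ValueError("no daily records")
    flat = [
        d.activity_defined
        and d.activity_index < activity_threshold
        and (d.max_depth - d.min_depth) < range_threshold
        for d in daily
    ]
    run = 0
    for f in reversed(flat):
        if f:
            run += 1
        else:
            break
    if run >= min_run:
        return daily[len(daily) - run - 1].date if run < len(daily) else daily[0].date
    return daily[-1].date


def flag_plume_days(
    daily: list[DailyObservation],
    field: GriddedField,
    delta_t_flag: float = 2.0,
    max_depth_limit: float = 15.0,
) -> list[DailyObservation]:
    """Flag cooling-water days: mean temperature exceeding the domain-wide
    surface maximum for that date by more than ``delta_t_flag`` °C while
    the fish stayed shallower than ``max_depth_limit`` m. Flagged days are
    excluded from the temperature likelihood downstream."""
    water = field.water_mask
    out = []
    for d in daily:
        obs = DailyObservation(**vars(d))
        try:
            k = field.day_index(d.date)
        except KeyError:
            out.append(obs)
            continue
        domain_max = float(field.temp_surface[k][water].max())
        if d.mean_temp > domain_max + delta_t_flag and d.max_depth < max_depth_limit:
            obs.cooling_water = True
        out.append(obs)
    return out


def truncate_inshore_variability(
    daily: list[DailyObservation],
    range_threshold: float = 5.0,
    depth_threshold: float = 5.0,
    min_run: int = 7,
) -> Date:
    """First day of a sustained shallow/high-temperature-variability
    episode (>= ``min_run`` consecutive days with daily temperature range
    above ``range_threshold`` °C at depths shallower than
    ``depth_threshold`` m); the series after that day is unusable for
    geolocation because the reference field cannot represent it. Returns
    the last date when no such episode exists."""
    if not daily:
        raise ValueError("no daily records")
    hot = [
        d.temp_range > range_threshold and d.max_depth < depth_threshold
        for d in daily
    ]
    run = 0
    for idx, h in enumerate(hot):
        run = run + 1 if h else 0
        if run >= min_run:
            return daily[idx - run + 1].date
    return daily[-1].date


def qc_detections(
    det: DetectionSet, max_jump_km: float = 100.0, return_counts: bool = False
):
    """Quality-control acoustic detections.

    Removes, in order: (a) detections that are the sole detection of a tag
    on an entire receiver array; (b) isolated detections implying an
    out-and-back movement of more than ``max_jump_km`` relative to both
    flanking detections within the same day."""
    stations = det.station_lookup()
    d = det.detections.copy()
    if len(d) == 0:
        return (det, {"array_singletons": 0, "implausible_jumps": 0}) if return_counts else det

    d = d.merge(
        det.stations[["station_id", "lat", "lon", "array"]], on="station_id", how="left"
    )
    # (a) array singletons
    counts = d.groupby(["tag_id", "array"])["station_id"].transform("size")
    singles = counts == 1
    n_singletons = int(singles.sum())
    d = d.loc[~singles].reset_index(drop=True)

    # (b) implausible out-and-back movements
    drop = np.zeros(len(d), dtype=bool)
    for _, grp in d.groupby("tag_id"):
        grp = grp.sort_values("timestamp")
        idx = grp.index.to_numpy()
        if len(idx) < 3:
            continue
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        ts = grp["timestamp"].to_numpy()
        for k in range(1, len(idx) - 1):
            back = haversine_km(lat[k - 1], lon[k - 1], lat[k], lon[k])
            forth = haversine_km(lat[k], lon[k], lat[k + 1], lon[k + 1])
            within_day = (ts[k + 1] - ts[k - 1]) <= np.timedelta64(24, "h")
            if back > max_jump_km and forth > max_jump_km and within_day:
                drop[d.index.get_loc(idx[k])] = True
    n_jumps = int(drop.sum())
    d = d.loc[~drop, ["tag_id", "timestamp", "station_id"]].reset_index(drop=True)
    if n_singletons or n_jumps:
        log.info(
            "detection QC removed %d array singletons, %d implausible jumps",
            n_singletons,
            n_jumps,
        )
    cleaned = DetectionSet(stations=det.stations, detections=d)
    if return_counts:
        return cleaned, {
            "array_singletons": n_singletons,
            "implausible_jumps": n_jumps,
        }
    return cleaned


def clean_series(
    series: TagSeries,
    field: Optional[GriddedField] = None,
    drift_window: float = 7.0,
    **thresholds,
) -> CleanSeries:
    """Full preprocessing of one tag: drift correction, daily summaries,
    mortality and inshore truncation, plume flagging."""
    corrected = correct_depth_drift(series, window=drift_window)
    daily = summarize_daily(corrected)
    # mortality is judged on the raw series: the centred running-minimum
    # correction smears the flat-trace onset across its window
    daily_raw = summarize_daily(series)
    if field is not None:
        daily = flag_plume_days(
            daily,
            field,
            delta_t_flag=thresholds.get("delta_t_flag", 2.0),
            max_depth_limit=thresholds.get("plume_depth_limit", 15.0),
        )
    alive_until = detect_mortality(
        daily_raw,
        activity_threshold=thresholds.get("activity_threshold", 1.0),
        range_threshold=thresholds.get("range_threshold", 0.5),
        min_run=thresholds.get("mortality_min_run", 7),
    )
    truncation = truncate_inshore_variability(
        daily,
        range_threshold=thresholds.get("inshore_range_threshold", 5.0),
        depth_threshold=thresholds.get("inshore_depth_threshold", 5.0),
        min_run=thresholds.get("inshore_min_run", 7),
    )
    for d in daily:
        if d.date > alive_until:
            d.presumed_dead = True
        if d.date >= truncation and truncation < daily[-1].date:
            d.inshore_variability = True
    return CleanSeries(
        series=corrected,
        daily=daily,
        alive_until=alive_until,
        truncation_date=truncation,
    )
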