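"""Movement-ecology summaries over tracks, detections and recaptures.

Residency (detection-positive days and residency index), area fidelity,
recapture displacement statistics, daily area assignment with the
multi-track agreement rule, migration-strategy classification,
per-strategy summaries, and seasonal movement networks over grouped
receiver stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geo import haversine_km, season_of
from .geolocate import PosteriorTrack
from .types import AreaSet, DailyObservation, DetectionSet, RecaptureRecord

__all__ = [
    "percent",
    "detection_positive_days",
    "residency_index",
    "fidelity",
    "recapture_stats",
    "AreaTrack",
    "assign_areas",
    "classify_strategy",
    "track_distance_km",
    "strategy_summary",
    "MovementNetwork",
    "build_network",
]

RECAPTURE_BINS = ("<5 km", "5-100 km", ">100 km")

#: distality order of the named areas for strategy classification
_AREA_RANK = {
    "North Sea": 0,
    "English Channel E": 1,
    "English Channel W": 2,
    "Celtic Sea": 3,
    "Bay of Biscay": 3,
}
_STRATEGY_BY_RANK = {
    0: "North Sea",
    1: "English Channel E",
    2: "English Channel W",
    3: "Celtic Sea-Bay of Biscay",
}


def percent(numerator: float, denominator: float) -> float:
    """Share as a percentage rounded half-up to one decimal, the format
    used in the cohort summaries."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    x = 100.0 * numerator / denominator
    return math.floor(x * 10.0 + 0.5) / 10.0


# --------------------------------------------------------------------------
# residency & fidelity
# --------------------------------------------------------------------------

def detection_positive_days(
    detections: pd.DataFrame, station_ids: Optional[set] = None
) -> int:
    """Number of distinct calendar days with at least one detection,
    optionally restricted to a set of stations (e.g. those inside a named
    area)."""
    if len(detections) == 0:
        return 0
    d = detections
    if station_ids is not None:
        d = d[d["station_id"].isin(station_ids)]
    if len(d) == 0:
        return 0
    return int(pd.to_datetime(d["timestamp"]).dt.date.nunique())


def residency_index(dpd: int, time_at_large: int) -> float:
    """DPD divided by days at large (tagging to battery end or
    recapture)."""
    if time_at_large <= 0:
        raise ValueError("time at large must be at least 1 day")
    if dpd > time_at_large:
        raise ValueError("DPD cannot exceed the time at large")
    return dpd / time_at_large


def fidelity(
    observations: pd.DataFrame,
    tagging_date: Date,
    area: str = "North Sea",
    horizon_days: int = 180,
) -> bool:
    """True when the fish was observed (recapture, detection or
    reconstructed position — ``observations`` has columns date, area) in
    the area at least ``horizon_days`` after tagging."""
    if len(observations) == 0:
        return False
    days = pd.to_datetime(observations["date"]).dt.date
    lag = np.array([(d - tagging_date).days for d in days])
    return bool(((observations["area"] == area) & (lag >= horizon_days)).any())


# --------------------------------------------------------------------------
# mark-recapture
# --------------------------------------------------------------------------

def recapture_stats(
    records: Sequence[RecaptureRecord],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-record great-circle displacement and days at large, plus counts
    in the displacement bins [0, 5), [5, 100), [100, inf) km."""
    rows = []
    for r in records:
        dist = haversine_km(r.release[1], r.release[2], r.recapture[1], r.recapture[2])
        rows.append(
            {
                "tag_id": r.tag_id,
                "distance_km": float(dist),
                "days_at_large": r.days_at_large,
            }
        )
    df = pd.DataFrame(rows, columns=["tag_id", "distance_km", "days_at_large"])
    bins = pd.Series(0, index=list(RECAPTURE_BINS), dtype=int)
    if len(df):
        cut = pd.cut(
            df["distance_km"],
            bins=[0.0, 5.0, 100.0, np.inf],
            labels=RECAPTURE_BINS,
            right=False,  # closed on the left
            include_lowest=True,
        )
        df["bin"] = cut
        bins = cut.value_counts().reindex(list(RECAPTURE_BINS)).fillna(0).astype(int)
    else:
        df["bin"] = pd.Series(dtype="object")
    return df, bins


# --------------------------------------------------------------------------
# areas & strategies
# --------------------------------------------------------------------------

@dataclass
class AreaTrack:
    """Daily area labels of one fish and its migration strategy."""

    tag_id: str
    dates: list[Date]
    labels: list[str]  # area name, "cooling waters" or "unknown"
    strategy: str = "unclassified"

    @property
    def n_days(self) -> int:
        return len(self.dates)


def assign_areas(
    track: PosteriorTrack,
    areas: AreaSet,
    plume_days: Optional[set[Date]] = None,
) -> AreaTrack:
    """Daily area label from the Viterbi position, demoted to "unknown"
    whenever the posterior-mode or posterior-mean position falls in a
    different area (the three-track agreement rule), and overridden to
    "cooling waters" on plume-flagged days."""
    if track.reliability == "unreliable":
        raise ValueError("refusing to assign areas for an unreliable track")
    plume_days = plume_days or set()
    labels = []
    for t, day in enumerate(track.dates):
        if day in plume_days:
            labels.append("cooling waters")
            continue
        v = areas.area_of(*track.viterbi_track[t])
        m = areas.area_of(*track.modal_track[t])
        g = areas.area_of(*track.mean_track[t])
        if v is None or v != m or v != g:
            labels.append("unknown")
        else:
            labels.append(v)
    return AreaTrack(tag_id=track.tag_id, dates=list(track.dates), labels=labels)


def classify_strategy(
    area_track: AreaTrack,
    min_days: int = 5,
    min_series_days: int = 90,
) -> str:
    """Migration strategy: the most distal area class occupied for at
    least ``min_days`` known-label days, in the order North Sea <
    Channel E < Channel W < Celtic Sea-Bay of Biscay. Series of
    ``min_series_days`` or fewer days stay unclassified."""
    if area_track.n_days <= min_series_days:
        return "unclassified"
    counts: dict[int, int] = {}
    for lab in area_track.labels:
        rank = _AREA_RANK.get(lab)
        if rank is not None:
            counts[rank] = counts.get(rank, 0) + 1
    qualified = [r for r, c in counts.items() if c >= min_days and r > 0]
    if qualified:
        return _STRATEGY_BY_RANK[max(qualified)]
    if counts:
        return "North Sea"
    return "unclassified"


def track_distance_km(track: PosteriorTrack) -> float:
    """Cumulative great-circle distance along the Viterbi track."""
    v = track.viterbi_track
    if len(v) < 2:
        return 0.0
    return float(
        np.sum(haversine_km(v[:-1, 0], v[:-1, 1], v[1:, 0], v[1:, 1]))
    )


def strategy_summary(
    tracks: dict[str, PosteriorTrack],
    strategies: dict[str, str],
    daily: Optional[dict[str, Sequence[DailyObservation]]] = None,
) -> pd.DataFrame:
    """Per-strategy table of n, distance travelled, fitted diffusion
    coefficient and (when daily summaries are given) experienced depth
    and temperature, each as median and range over individuals."""
    rows = []
    for tag_id, track in tracks.items():
        row = {
            "tag_id": tag_id,
            "strategy": strategies.get(tag_id, "unclassified"),
            "distance_km": track_distance_km(track),
            "d_km2_day": float(np.mean(track.d_fit)),
        }
        if daily and tag_id in daily:
            obs = daily[tag_id]
            row["depth_m"] = float(np.median([o.med_depth for o in obs]))
            row["temp_c"] = float(np.median([o.mean_temp for o in obs]))
        rows.append(row)
    per_tag = pd.DataFrame(rows)
    if per_tag.empty:
        return per_tag
    value_cols = [c for c in per_tag.columns if c not in ("tag_id", "strategy")]
    agg = per_tag.groupby("strategy")[value_cols].agg(["count", "median", "min", "max"])
    agg.columns = ["_".join(c) for c in agg.columns]
    agg = agg.rename(columns={f"{value_cols[0]}_count": "n"})
    agg = agg.drop(columns=[c for c in agg.columns if c.endswith("_count")])
    return agg.reset_index()


# --------------------------------------------------------------------------
# movement networks
# --------------------------------------------------------------------------

@dataclass
class MovementNetwork:
    """Seasonal movement graph over grouped receiver locations."""

    nodes: pd.DataFrame  # group, lat, lon, n_animals, + per-season columns
    edges: pd.DataFrame  # origin, destination, season, count

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["group"], lat=row["lat"], lon=row["lon"],
                       n_animals=int(row["n_animals"]))
        for _, row in self.edges.iterrows():
            g.add_edge(row["origin"], row["destination"],
                       season=row["season"], count=int(row["count"]))
        return g


def build_network(
    det: DetectionSet, station_groups: dict[str, str]
) -> MovementNetwork:
    """Group receiver stations, count distinct animals per group, and
    count directed between-group transitions of consecutive detections
    per tag, attributed to the season of the origin detection."""
    missing = set(det.stations["station_id"]) - set(station_groups)
    if missing:
        raise ValueError(f"stations missing from the grouping map: {sorted(missing)}")
    st = det.stations.copy()
    st["group"] = st["station_id"].map(station_groups)
    node_pos = st.groupby("group")[["lat", "lon"]].mean()

    d = det.detections.copy()
    if len(d) == 0:
        nodes = node_pos.reset_index().assign(n_animals=0)
        return MovementNetwork(
            nodes=nodes,
            edges=pd.DataFrame(columns=["origin", "destination", "season", "count"]),
        )
    d = d.merge(st[["station_id", "group"]], on="station_id", how="left")
    d = d.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)
    d["season"] = [season_of(ts) for ts in d["timestamp"]]

    animals = d.groupby("group")["tag_id"].nunique()
    season_counts = (
        d.groupby(["group", "season"]).size().unstack(fill_value=0)
    )
    nodes = node_pos.join(animals.rename("n_animals")).join(season_counts)
    nodes = nodes.fillna(0).reset_index()
    nodes["n_animals"] = nodes["n_animals"].astype(int)

    edge_rows = []
    for _, grp in d.groupby("tag_id"):
        g = grp["group"].to_numpy()
        s = grp["season"].to_numpy()
        moved = np.where(g[1:] != g[:-1])[0]
        for k in moved:
            edge_rows.append({"origin": g[k], "destination": g[k + 1], "season": s[k]})
    if edge_rows:
        edges = (
            pd.DataFrame(edge_rows)
            .groupby(["origin", "destination", "season"])
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        edges = pd.DataFrame(columns=["origin", "destination", "season", "count"])
    return MovementNetwork(nodes=nodes, edges=edges)
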