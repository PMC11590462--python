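"""Site revisitation and wetland-layer classification.

``detect_visits`` turns per-fix point-in-polygon membership into entry-exit
episodes, merging excursions shorter than ``min_gap_h``.  Visit timing uses
fix timestamps directly — no boundary-crossing interpolation, since 6-hourly
grids would lend it false precision.  ``classify_areas`` flags residency
polygons by non-empty intersection with named wetland/breeding layers
(closed-set convention: edge-touching counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape

LAYER_KEYS = ("ramsar", "diwa", "managed_floodplain", "breeding_sites", "basin")


@dataclass
class Visit:
    bird_id: str
    area_id: str
    arrival: pd.Timestamp
    departure: pd.Timestamp
    duration_days: float
    gap_to_next_days: float  # NaN for the last visit


def detect_visits(track, polygon, area_id: str = "", min_gap_h: float = 12.0) -> list:
    """Entry-exit visits of one track to one polygon.

    Maximal runs of inside-fixes form visits; an excursion outside shorter
    than ``min_gap_h`` hours does not split a visit.  Arrival and departure
    are the first/last inside-fix timestamps.
    """
    if not polygon.is_valid:
        raise ValueError("polygon is invalid (self-intersecting?)")
    f = track.fixes
    if f.empty:
        return []
    pts = shapely.points(f["lon"].to_numpy(), f["lat"].to_numpy())
    inside = shapely.covers(polygon, pts)  # closed set: boundary counts
    if not inside.any():
        return []

    # maximal runs of inside fixes
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])

    ts = f["timestamp"]
    runs = [(ts.iloc[s], ts.iloc[e]) for s, e in zip(starts, ends)]
    merged = [runs[0]]
    gap = pd.Timedelta(hours=min_gap_h)
    for arr, dep in runs[1:]:
        if min_gap_h > 0 and arr - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], dep)
        else:
            merged.append((arr, dep))

    visits = []
    for i, (arr, dep) in enumerate(merged):
        nxt = merged[i + 1][0] if i + 1 < len(merged) else None
        visits.append(
            Visit(
                bird_id=track.bird_id,
                area_id=area_id,
                arrival=arr,
                departure=dep,
                duration_days=(dep - arr).total_seconds() / 86400.0,
                gap_to_next_days=((nxt - dep).total_seconds() / 86400.0) if nxt is not None else np.nan,
            )
        )
    return visits


def visits_frame(visits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bird_id": v.bird_id,
                "area_id": v.area_id,
                "arrival": v.arrival,
                "departure": v.departure,
                "duration_days": v.duration_days,
                "gap_to_next_days": v.gap_to_next_days,
            }
            for v in visits
        ],
        columns=["bird_id", "area_id", "arrival", "departure", "duration_days", "gap_to_next_days"],
    )


def revisit_summary(visits: pd.DataFrame) -> tuple:
    """Per-area and per-bird visitation tables.

    Per area: distinct birds, total visits, arrival/departure counts per
    calendar month.  Per bird: distinct areas and the distribution
    (median/mean/SD/min/max) of visit durations and between-visit gaps.
    """
    if visits.empty:
        empty_a = pd.DataFrame(columns=["area_id", "n_birds", "n_visits"])
        empty_b = pd.DataFrame(columns=["bird_id", "n_areas", "n_visits"])
        return empty_a, empty_b

    per_area_rows = []
    for area_id, grp in visits.groupby("area_id"):
        arr_months = pd.DatetimeIndex(grp["arrival"]).month.value_counts().to_dict()
        dep_months = pd.DatetimeIndex(grp["departure"]).month.value_counts().to_dict()
        per_area_rows.append(
            {
                "area_id": area_id,
                "n_birds": grp["bird_id"].nunique(),
                "n_visits": len(grp),
                "arrivals_by_month": {int(k): int(v) for k, v in sorted(arr_months.items())},
                "departures_by_month": {int(k): int(v) for k, v in sorted(dep_months.items())},
            }
        )

    def dist_stats(series, prefix):
        vals = series.dropna().to_numpy()
        if len(vals) == 0:
            return {f"{prefix}_{s}": np.nan for s in ("median", "mean", "sd", "min", "max")}
        return {
            f"{prefix}_median": float(np.median(vals)),
            f"{prefix}_mean": float(np.mean(vals)),
            f"{prefix}_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            f"{prefix}_min": float(np.min(vals)),
            f"{prefix}_max": float(np.max(vals)),
        }

    per_bird_rows = []
    for bird_id, grp in visits.groupby("bird_id"):
        per_bird_rows.append(
            {
                "bird_id": bird_id,
                "n_areas": grp["area_id"].nunique(),
                "n_visits": len(grp),
                **dist_stats(grp["duration_days"], "duration_days"),
                **dist_stats(grp["gap_to_next_days"], "gap_days"),
            }
        )
    return pd.DataFrame(per_area_rows), pd.DataFrame(per_bird_rows)


def classify_areas(areas: dict, layers: dict) -> pd.DataFrame:
    """Flag each residency polygon by intersection with each named layer.

    ``areas`` maps area_id to a shapely polygon (WGS84); ``layers`` maps a
    layer name to a list of polygons.  A missing layer yields None (unknown),
    not False.  Intersection is the closed-set predicate: touching counts.
    """
    rows = []
    for area_id, poly in areas.items():
        row = {"area_id": area_id}
        for key in LAYER_KEYS:
            polys = layers.get(key)
            if polys is None:
                row[key] = None
            else:
                row[key] = bool(any(poly.intersects(lp) for lp in polys))
        rows.append(row)
    return pd.DataFrame(rows)


def read_geojson_polygons(path) -> list:
    """All (Multi)Polygon geometries from a GeoJSON file or FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        for feat in gj["features"]:
            geoms.append(shape(feat["geometry"]))
    elif gj.get("type") == "Feature":
        geoms.append(shape(gj["geometry"]))
    else:
        geoms.append(shape(gj))
    return [g for g in geoms if g.geom_type in ("Polygon", "MultiPolygon")]
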