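"""Telemetry fix tables: reading, filtering, grid regularization, monthly splits.

A ``Track`` is one bird's chronological fix table (UTC timestamps, WGS84
lon/lat).  ``regularize`` places fixes on a common grid (6-hourly by default,
anchored at UTC midnight) by nearest-within-tolerance assignment — positions
are never interpolated.  ``split_months`` cuts a regular track into calendar
month segments judged in local time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES_CODES = ("SNI", "AWI", "RSB", "other")
AGE_CLASSES = ("adult", "juvenile")

#: Default CSV column names.
DEFAULT_COLUMNS = {
    "bird_id": "bird_id",
    "species": "species",
    "age_class": "age_class",
    "timestamp": "timestamp_iso8601",
    "lon": "lon",
    "lat": "lat",
    "utc_offset": "utc_offset_h",
}

#: Column mapping for Movebank-style exports.
MOVEBANK_COLUMNS = {
    "bird_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}


class FormatError(ValueError):
    """Raised when an input table is missing mandatory columns."""


@dataclass
class Track:
    """One bird's chronological fixes.

    ``fixes`` columns: ``timestamp`` (tz-aware UTC), ``lon``, ``lat``.
    ``utc_offset_h`` converts UTC to local clock time for diel/seasonal logic.
    """

    bird_id: str
    fixes: pd.DataFrame
    species: str = "other"
    age_class: str = "adult"
    utc_offset_h: float = 0.0

    def __post_init__(self):
        f = self.fixes
        for col in ("timestamp", "lon", "lat"):
            if col not in f.columns:
                raise FormatError(f"fix table missing column {col!r}")
        if len(f) and f["timestamp"].duplicated().any():
            raise ValueError(f"duplicate timestamps for bird {self.bird_id}")
        if len(f) and not f["timestamp"].is_monotonic_increasing:
            raise ValueError(f"fixes out of order for bird {self.bird_id}")
        bad_lon = (f["lon"].abs() > 180).any()
        bad_lat = (f["lat"].abs() > 90).any()
        if bad_lon or bad_lat:
            raise ValueError(f"coordinates out of range for bird {self.bird_id}")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def span_days(self) -> float:
        if len(self.fixes) < 2:
            return 0.0
        dt = self.fixes["timestamp"].iloc[-1] - self.fixes["timestamp"].iloc[0]
        return dt.total_seconds() / 86400.0

    def local_timestamps(self) -> pd.Series:
        return self.fixes["timestamp"] + pd.to_timedelta(self.utc_offset_h, unit="h")


@dataclass
class RegularTrack:
    """Track constrained to a common grid, with explicit missing slots.

    ``data`` is indexed by the grid timestamps (UTC); missing slots carry NaN
    coordinates.  ``source_time`` records the raw fix actually assigned.
    """

    bird_id: str
    data: pd.DataFrame
    grid_interval_h: float = 6.0
    species: str = "other"
    age_class: str = "adult"
    utc_offset_h: float = 0.0

    @property
    def filled(self) -> pd.DataFrame:
        return self.data[self.data["lon"].notna()]

    def to_track(self) -> Track:
        """Filled slots as a plain Track (timestamps = grid times)."""
        f = self.filled
        df = pd.DataFrame(
            {"timestamp": f.index, "lon": f["lon"].to_numpy(), "lat": f["lat"].to_numpy()}
        ).reset_index(drop=True)
        return Track(self.bird_id, df, self.species, self.age_class, self.utc_offset_h)


@dataclass
class MonthSegment:
    """The slice of a regular track falling in one local calendar month."""

    bird_id: str
    year: int
    month: int
    data: pd.DataFrame  # filled slots only; columns timestamp, lon, lat
    species: str = "other"
    age_class: str = "adult"
    utc_offset_h: float = 0.0

    @property
    def n_fixes(self) -> int:
        return len(self.data)

    @property
    def window_h(self) -> float:
        """Span of the calendar month in hours."""
        start = pd.Timestamp(year=self.year, month=self.month, day=1)
        return ((start + pd.offsets.MonthBegin(1)) - start).total_seconds() / 3600.0


def read_fixes(path, dialect: str | dict = "default") -> list[Track]:
    """Read a fix CSV and return one Track per bird.

    ``dialect`` is either ``"default"``, ``"movebank"`` or a mapping from the
    canonical keys (bird_id, timestamp, lon, lat, ...) to column names.  Rows
    with unparseable coordinates or timestamps are dropped with a logged
    count; duplicated timestamps within a bird keep the first row.
    """
    if dialect == "default":
        cols = DEFAULT_COLUMNS
    elif dialect == "movebank":
        cols = {**DEFAULT_COLUMNS, **MOVEBANK_COLUMNS}
    elif isinstance(dialect, dict):
        cols = {**DEFAULT_COLUMNS, **dialect}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    raw = pd.read_csv(path, dtype=str)
    if raw.empty and not len(raw.columns):
        return []
    for key in ("bird_id", "timestamp", "lon", "lat"):
        if cols[key] not in raw.columns:
            raise FormatError(f"missing mandatory column {cols[key]!r}")

    df = pd.DataFrame(
        {
            "bird_id": raw[cols["bird_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[cols["timestamp"]], errors="coerce", utc=True),
            "lon": pd.to_numeric(raw[cols["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[cols["lat"]], errors="coerce"),
        }
    )
    for opt, default in (("species", "other"), ("age_class", "adult"), ("utc_offset", 0.0)):
        name = cols.get(opt)
        key = "utc_offset_h" if opt == "utc_offset" else opt
        if name is not None and name in raw.columns:
            if opt == "utc_offset":
                df[key] = pd.to_numeric(raw[name], errors="coerce").fillna(0.0)
            else:
                df[key] = raw[name].fillna(default)
        else:
            df[key] = default

    bad = df["timestamp"].isna() | df["lon"].isna() | df["lat"].isna()
    bad |= (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
    if bad.any():
        logger.warning("read_fixes: dropped %d unparseable/invalid rows", int(bad.sum()))
    df = df[~bad]

    tracks = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        grp = grp.sort_values("timestamp")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            logger.warning("read_fixes: bird %s: dropped %d duplicate-timestamp rows", bird_id, int(dup.sum()))
            grp = grp[~dup]
        tracks.append(
            Track(
                bird_id=str(bird_id),
                fixes=grp[["timestamp", "lon", "lat"]].reset_index(drop=True),
                species=str(grp["species"].iloc[0]),
                age_class=str(grp["age_class"].iloc[0]),
                utc_offset_h=float(grp["utc_offset_h"].iloc[0]),
            )
        )
    return tracks


def filter_tracks(tracks, min_days: float = 30.0, exclusion_windows: dict | None = None) -> list[Track]:
    """Drop excluded fix windows, then birds whose remaining span < ``min_days``.

    ``exclusion_windows`` maps bird_id to a list of (start, end) timestamps
    (inclusive) identifying nesting / pre-dispersal periods to remove.
    """
    exclusion_windows = exclusion_windows or {}
    out = []
    for tr in tracks:
        fixes = tr.fixes
        for start, end in exclusion_windows.get(tr.bird_id, []):
            start = pd.Timestamp(start)
            end = pd.Timestamp(end)
            if start.tzinfo is None:
                start = start.tz_localize("UTC")
            if end.tzinfo is None:
                end = end.tz_localize("UTC")
            fixes = fixes[(fixes["timestamp"] < start) | (fixes["timestamp"] > end)]
        if len(fixes) < 2:
            continue
        span = (fixes["timestamp"].iloc[-1] - fixes["timestamp"].iloc[0]).total_seconds() / 86400.0
        if span < min_days:
            continue
        out.append(replace(tr, fixes=fixes.reset_index(drop=True)))
    return out


def regularize(track, grid_interval_h: float = 6.0, tolerance_min: float = 90.0) -> RegularTrack:
    """Place fixes on a UTC-midnight-anchored grid, nearest within tolerance.

    Each raw fix is assigned to at most one grid slot (its nearest; ties break
    toward the earlier slot) and each slot takes the nearest assigned fix.
    Slots with no fix within ``tolerance_min`` minutes stay missing; no
    positions are interpolated.  Idempotent on already-regular tracks.
    """
    if grid_interval_h <= 0:
        raise ValueError("grid_interval_h must be positive")
    if isinstance(track, RegularTrack):
        track = track.to_track()
    fixes = track.fixes
    if fixes.empty:
        data = pd.DataFrame(columns=["lon", "lat", "source_time"], index=pd.DatetimeIndex([], tz="UTC"))
        return RegularTrack(track.bird_id, data, grid_interval_h, track.species, track.age_class, track.utc_offset_h)

    step = pd.to_timedelta(grid_interval_h, unit="h")
    t0 = fixes["timestamp"].iloc[0].floor(step)
    t1 = fixes["timestamp"].iloc[-1].ceil(step)
    grid = pd.date_range(t0, t1, freq=step)

    ts = fixes["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None).to_numpy()
    grid_np = grid.tz_convert("UTC").tz_localize(None).to_numpy()
    # nearest slot per fix; exact midpoints round down (earlier slot)
    pos = ((ts - grid_np[0]) / np.timedelta64(1, "s")) / (grid_interval_h * 3600.0)
    slot = np.floor(pos + 0.5).astype(int)
    frac = pos - np.floor(pos)
    slot[np.isclose(frac, 0.5)] = np.floor(pos[np.isclose(frac, 0.5)]).astype(int)
    slot = np.clip(slot, 0, len(grid) - 1)
    offset_s = np.abs(pos - slot) * grid_interval_h * 3600.0

    tol_s = tolerance_min * 60.0
    lon = np.full(len(grid), np.nan)
    lat = np.full(len(grid), np.nan)
    src = np.full(len(grid), np.datetime64("NaT"), dtype="datetime64[ns]")
    order = np.lexsort((np.arange(len(ts)), offset_s))  # by offset, then earlier fix
    taken = np.zeros(len(grid), dtype=bool)
    for i in order:
        s = slot[i]
        if offset_s[i] <= tol_s and not taken[s]:
            taken[s] = True
            lon[s] = fixes["lon"].iloc[i]
            lat[s] = fixes["lat"].iloc[i]
            src[s] = np.datetime64(fixes["timestamp"].iloc[i].tz_convert(None))

    data = pd.DataFrame({"lon": lon, "lat": lat, "source_time": src}, index=grid)
    data.index.name = "grid_time"
    return RegularTrack(track.bird_id, data, grid_interval_h, track.species, track.age_class, track.utc_offset_h)


def split_months(rt: RegularTrack) -> list[MonthSegment]:
    """One segment per local calendar month containing at least one fix."""
    filled = rt.filled
    if filled.empty:
        return []
    local = filled.index + pd.to_timedelta(rt.utc_offset_h, unit="h")
    keys = pd.MultiIndex.from_arrays([local.year, local.month])
    segments = []
    df = pd.DataFrame(
        {"timestamp": filled.index, "lon": filled["lon"].to_numpy(), "lat": filled["lat"].to_numpy()}
    )
    for (year, month), grp in df.groupby([keys.get_level_values(0), keys.get_level_values(1)], sort=True):
        segments.append(
            MonthSegment(
                bird_id=rt.bird_id,
                year=int(year),
                month=int(month),
                data=grp.reset_index(drop=True),
                species=rt.species,
                age_class=rt.age_class,
                utc_offset_h=rt.utc_offset_h,
            )
        )
    return segments


def track_to_geojson(track: Track) -> dict:
    """GeoJSON LineString feature for quick inspection of one bird."""
    coords = track.fixes[["lon", "lat"]].to_numpy().tolist()
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "bird_id": track.bird_id,
            "species": track.species,
            "age_class": track.age_class,
            "n_fixes": track.n_fixes,
        },
    }


def write_tracks_geojson(tracks, path) -> None:
    fc = {"type": "FeatureCollection", "features": [track_to_geojson(t) for t in tracks]}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def regular_to_csv(rt: RegularTrack, path) -> None:
    df = rt.data.reset_index()
    df.insert(0, "bird_id", rt.bird_id)
    df.insert(1, "species", rt.species)
    df.insert(2, "age_class", rt.age_class)
    df.insert(3, "utc_offset_h", rt.utc_offset_h)
    df["grid_interval_h"] = rt.grid_interval_h
    df.to_csv(path, index=False)


def regular_from_csv(path) -> RegularTrack:
    df = pd.read_csv(path, parse_dates=["grid_time", "source_time"])
    if df["grid_time"].dt.tz is None:
        df["grid_time"] = df["grid_time"].dt.tz_localize("UTC")
    data = df.set_index("grid_time")[["lon", "lat", "source_time"]]
    return RegularTrack(
        bird_id=str(df["bird_id"].iloc[0]),
        data=data,
        grid_interval_h=float(df["grid_interval_h"].iloc[0]),
        species=str(df["species"].iloc[0]),
        age_class=str(df["age_class"].iloc[0]),
        utc_offset_h=float(df["utc_offset_h"].iloc[0]),
    )
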