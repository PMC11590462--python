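"""Distance statistics and permutation comparisons.

Daily metrics follow the roost-centric definitions: the roost is the raw fix
nearest local midnight (within ±3 h), ``max_from_roost_km`` the furthest the
bird got from that day's roost, ``roost_shift_km`` the displacement between
successive midnight fixes, and ``cumulative_km`` the sum of step lengths
whose starting fix falls in the local day.

Group comparisons use two-sided label-permutation tests on a percentile
statistic (median / p10 / p80) with the +1 finite-sample correction, and
Holm step-down adjustment for pairwise batteries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km

SEASONS = {  # southern hemisphere
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}

_STAT_Q = {"median": 50.0, "p10": 10.0, "p80": 80.0}


def season_of(month: int) -> str:
    """Southern-hemisphere season of a calendar month (1-12)."""
    if month not in SEASONS:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return SEASONS[month]


def _step_lengths(track):
    f = track.fixes
    lon = f["lon"].to_numpy()
    lat = f["lat"].to_numpy()
    return haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])


def daily_metrics(track, midnight_tolerance_h: float = 3.0) -> pd.DataFrame:
    """One row per local day: cumulative_km, max_from_roost_km, roost_shift_km.

    Days without a fix within ``midnight_tolerance_h`` of local midnight get
    NaN roost-based metrics; cumulative_km is still summed from observed
    steps.
    """
    if track.n_fixes < 2:
        raise ValueError("daily_metrics requires at least two fixes")
    f = track.fixes
    local = track.local_timestamps()
    dates = local.dt.normalize()
    lon = f["lon"].to_numpy()
    lat = f["lat"].to_numpy()
    steps = _step_lengths(track)

    unique_dates = dates.unique()
    # roost per date: raw fix nearest that date's local midnight, within tol
    roost_idx = {}
    tol = pd.Timedelta(hours=midnight_tolerance_h)
    for d in unique_dates:
        delta = (local - d).abs()
        i = int(delta.idxmin())
        if delta.loc[i] <= tol:
            roost_idx[d] = i

    rows = []
    for d in unique_dates:
        day_mask = (dates == d).to_numpy()
        cum = float(steps[day_mask[:-1]].sum()) if day_mask[:-1].any() else 0.0
        ri = roost_idx.get(d)
        if ri is not None:
            max_from_roost = float(
                haversine_km(lon[ri], lat[ri], lon[day_mask], lat[day_mask]).max()
            )
            prev = roost_idx.get(d - pd.Timedelta(days=1))
            roost_shift = (
                float(haversine_km(lon[prev], lat[prev], lon[ri], lat[ri]))
                if prev is not None
                else np.nan
            )
        else:
            max_from_roost = np.nan
            roost_shift = np.nan
        rows.append(
            {
                "bird_id": track.bird_id,
                "species": track.species,
                "age_class": track.age_class,
                "date": d,
                "cumulative_km": cum,
                "max_from_roost_km": max_from_roost,
                "roost_shift_km": roost_shift,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CumulativeRates:
    hourly: pd.Series  # km per local clock hour (indexed by local hour timestamp)
    daily: pd.DataFrame  # date, km, partial flag
    annual_km: float | None
    annual_complete: bool


def cumulative_rates(track, expected_interval_h: float | None = None) -> CumulativeRates:
    """Cumulative distance per hour, per local day, and the annual total.

    A day is flagged partial when it holds fewer fixes than the expected
    schedule implies (modal inter-fix interval unless given).  The annual
    total is only reported when >= 365 distinct local days are present.
    """
    if track.n_fixes < 2:
        raise ValueError("cumulative_rates requires at least two fixes")
    f = track.fixes
    local = track.local_timestamps()
    steps = _step_lengths(track)
    start_local = local.iloc[:-1]

    hourly = pd.Series(steps, index=start_local.dt.floor("h")).groupby(level=0).sum()
    hourly.name = "km_per_h"

    dates = start_local.dt.normalize()
    daily_km = pd.Series(steps, index=dates).groupby(level=0).sum()
    counts = local.dt.normalize().value_counts()
    if expected_interval_h is None:
        diffs = local.diff().dropna().dt.total_seconds() / 3600.0
        expected_interval_h = float(diffs.mode().iloc[0]) if len(diffs) else np.nan
    expected_per_day = (
        int(round(24.0 / expected_interval_h)) if expected_interval_h and expected_interval_h > 0 else 1
    )
    daily = pd.DataFrame({"km": daily_km})
    daily["n_fixes"] = counts.reindex(daily.index).fillna(0).astype(int)
    daily["partial"] = daily["n_fixes"] < expected_per_day
    daily.index.name = "date"
    daily = daily.reset_index()

    n_days = int(local.dt.normalize().nunique())
    complete = n_days >= 365
    annual = float(steps.sum()) if complete else None
    return CumulativeRates(hourly=hourly, daily=daily, annual_km=annual, annual_complete=complete)


def monthly_summary(df: pd.DataFrame, value: str, by=()) -> pd.DataFrame:
    """Median / p10 / p80 of ``value`` per calendar month (and extra groupers).

    Percentiles use linear interpolation between order statistics.  Expects a
    ``month`` column (or a ``date`` column from which it is derived).
    """
    df = df.copy()
    if "month" not in df.columns:
        if "date" not in df.columns:
            raise ValueError("need a 'month' or 'date' column")
        df["month"] = pd.DatetimeIndex(df["date"]).month
    keys = list(by) + ["month"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        vals = grp[value].dropna().to_numpy()
        if len(vals) == 0:
            continue  # empty group: omitted row
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(keys, key))
            | {
                "n": len(vals),
                "p10": float(np.percentile(vals, 10)),
                "median": float(np.percentile(vals, 50)),
                "p80": float(np.percentile(vals, 80)),
            }
        )
    return pd.DataFrame(rows)


def _stat(values: np.ndarray, statistic: str, axis=None):
    try:
        q = _STAT_Q[statistic]
    except KeyError:
        raise ValueError(f"statistic must be one of {sorted(_STAT_Q)}") from None
    return np.percentile(values, q, axis=axis)


def percentile_permutation_test(
    group_a, group_b, statistic: str = "median", n_perm: int = 1000, seed=None
) -> float:
    """Two-sided label-permutation p-value for a percentile difference.

    p = (1 + #{permuted |diff| >= observed |diff|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    observed = abs(_stat(a, statistic) - _stat(b, statistic))
    # sorting makes the pooled array canonical, so p is exactly invariant to
    # swapping the two group labels at a fixed seed
    pooled = np.sort(np.concatenate([a, b]))
    n = len(pooled)
    rng = np.random.default_rng(seed)
    # vectorised label permutations via random-key argsort
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[order]
    diff = np.abs(_stat(perm[:, : len(a)], statistic, axis=1) - _stat(perm[:, len(a):], statistic, axis=1))
    exceed = int(np.sum(diff >= observed - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def pairwise_percentile_tests(
    groups: dict, statistic: str = "median", n_perm: int = 1000, seed=None, adjust: str = "holm"
) -> pd.DataFrame:
    """All unordered pairwise permutation tests with Holm step-down adjustment."""
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            p = percentile_permutation_test(
                groups[na], groups[nb], statistic, n_perm, seed=rng.integers(2**63)
            )
            rows.append({"group_a": na, "group_b": nb, "p_raw": p})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    elif adjust in (None, "none"):
        out["p_adj"] = out["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
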