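"""Synthetic telemetry with known ground truth.

Simulators for the movement modes the downstream classifier must separate:

* ``simulate_ouf_track`` — stationary position-velocity Gaussian process
  (per-axis variance ``sigma2``, positional timescale ``tau_p``, velocity
  timescale ``tau_v``) stepped by its exact discrete-time transition, so the
  sampled fixes carry no discretisation bias.
* ``simulate_nomadic_track`` — correlated-heading random walk whose net
  displacement grows without bound (negative control for residency).
* ``simulate_mixed_track`` — mode schedule stitched into one track, emitting
  per-month truth labels (majority-of-month rule).
* ``simulate_diel_track`` — roost-at-midnight / forage-by-day structure with
  constructed daily-distance truth.

All simulation happens on a local km plane about ``centre`` and is
inverse-projected to lon/lat at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .geo import LocalPlane
from .track_io import Track

DEFAULT_CENTRE = (144.0, -30.0)  # inland eastern Australia
DEFAULT_START = "2021-01-01T00:00:00Z"

RESIDENT = "resident"
NOMADIC = "nomadic"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one resident (OUF) simulation.

    sigma2   per-axis stationary positional variance, km²
    tau_p    positional decorrelation timescale, h
    tau_v    velocity decorrelation timescale, h (must satisfy tau_p > tau_v > 0)
    """

    sigma2: float
    tau_p: float
    tau_v: float
    fix_interval: float = 6.0  # h
    duration: float = 30.0  # days
    centre: tuple = DEFAULT_CENTRE
    seed: int = 0
    start: str = DEFAULT_START
    utc_offset_h: float = 0.0
    bird_id: str = "sim"

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not (self.tau_p > self.tau_v > 0):
            raise ValueError("require tau_p > tau_v > 0")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.duration * 24.0 < 2 * self.fix_interval:
            raise ValueError("duration shorter than two fix intervals")


def _ouf_transition(sigma2: float, tau_p: float, tau_v: float, dt_h: float):
    """Exact discrete transition (Phi, chol(Q), stationary cov) of one axis.

    The process is the CAR(2) system with characteristic timescales tau_p and
    tau_v: state z = (position, velocity), dz = A z dt + noise, whose
    stationary positional variance is sigma2 and positional autocovariance is
    sigma2 * (tau_p e^{-t/tau_p} - tau_v e^{-t/tau_v}) / (tau_p - tau_v).
    """
    A = np.array([[0.0, 1.0], [-1.0 / (tau_p * tau_v), -(1.0 / tau_p + 1.0 / tau_v)]])
    Sigma_inf = np.diag([sigma2, sigma2 / (tau_p * tau_v)])
    Phi = expm(A * dt_h)
    Q = Sigma_inf - Phi @ Sigma_inf @ Phi.T
    Q = 0.5 * (Q + Q.T)
    # eigen clip guards tiny negative round-off; Q is PSD for a stable A
    w, V = np.linalg.eigh(Q)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return Phi, L, Sigma_inf


def _ouf_positions_km(sigma2, tau_p, tau_v, n_steps, dt_h, rng):
    """(n_steps, 2) stationary positions, exact transition, axes independent."""
    if sigma2 == 0.0:
        return np.zeros((n_steps, 2))
    Phi, L, Sigma_inf = _ouf_transition(sigma2, tau_p, tau_v, dt_h)
    S = np.diag(np.sqrt(np.diag(Sigma_inf)))
    out = np.empty((n_steps, 2))
    for axis in range(2):
        z = S @ rng.standard_normal(2)
        noise = rng.standard_normal((n_steps, 2))
        for k in range(n_steps):
            out[k, axis] = z[0]
            z = Phi @ z + L @ noise[k]
    return out


def _grid_times(start, duration_days, fix_interval_h):
    start = pd.Timestamp(start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    n = int(np.floor(duration_days * 24.0 / fix_interval_h)) + 1
    return start + pd.to_timedelta(np.arange(n) * fix_interval_h, unit="h")


def _make_track(times, xy_km, centre, bird_id, utc_offset_h, species="other", age_class="adult"):
    plane = LocalPlane(*centre)
    lon, lat = plane.to_lonlat(xy_km[:, 0], xy_km[:, 1])
    fixes = pd.DataFrame({"timestamp": times, "lon": lon, "lat": lat})
    return Track(bird_id, fixes, species=species, age_class=age_class, utc_offset_h=utc_offset_h)


def simulate_ouf_track(config: SimConfig) -> Track:
    """Exactly-sampled resident track (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    times = _grid_times(config.start, config.duration, config.fix_interval)
    xy = _ouf_positions_km(config.sigma2, config.tau_p, config.tau_v, len(times), config.fix_interval, rng)
    return _make_track(times, xy, config.centre, config.bird_id, config.utc_offset_h)


def simulate_nomadic_track(
    speed_kmh: float,
    heading_persistence: float,
    duration: float,
    fix_interval: float = 6.0,
    seed: int = 0,
    centre=DEFAULT_CENTRE,
    start=DEFAULT_START,
    utc_offset_h: float = 0.0,
    bird_id: str = "nomad",
) -> Track:
    """Correlated-heading random walk; net displacement grows without bound.

    Per step the heading receives a Gaussian turn with standard deviation
    sqrt(2 * (1 - heading_persistence)) radians, so persistence near 1 gives
    near-ballistic motion and persistence 0 a diffusive walk.
    """
    if speed_kmh < 0:
        raise ValueError("speed_kmh must be >= 0")
    if not (0.0 <= heading_persistence < 1.0):
        raise ValueError("heading_persistence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    times = _grid_times(start, duration, fix_interval)
    n = len(times)
    turn_sd = np.sqrt(2.0 * (1.0 - heading_persistence))
    headings = rng.uniform(0, 2 * np.pi) + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, turn_sd, n - 1))])
    step = speed_kmh * fix_interval
    dxy = step * np.column_stack([np.cos(headings), np.sin(headings)])
    xy = np.concatenate([np.zeros((1, 2)), np.cumsum(dxy[:-1], axis=0)])
    return _make_track(times, xy, centre, bird_id, utc_offset_h)


@dataclass(frozen=True)
class ModeWindow:
    """One contiguous stretch of a single movement mode."""

    start: pd.Timestamp
    end: pd.Timestamp
    mode: str  # RESIDENT or NOMADIC
    params: dict = field(default_factory=dict)


@dataclass
class ModeSchedule:
    """Chronologically ordered, gap-free sequence of mode windows."""

    windows: list

    def __post_init__(self):
        ws = []
        for w in self.windows:
            start = pd.Timestamp(w.start)
            end = pd.Timestamp(w.end)
            if start.tzinfo is None:
                start = start.tz_localize("UTC")
            if end.tzinfo is None:
                end = end.tz_localize("UTC")
            if end <= start:
                raise ValueError("mode window must have end > start")
            if w.mode not in (RESIDENT, NOMADIC):
                raise ValueError(f"unknown mode {w.mode!r}")
            ws.append(ModeWindow(start, end, w.mode, dict(w.params)))
        for a, b in zip(ws, ws[1:]):
            if b.start != a.end:
                raise ValueError("mode schedule has a gap or overlap")
        self.windows = ws

    @property
    def start(self):
        return self.windows[0].start

    @property
    def end(self):
        return self.windows[-1].end


def simulate_mixed_track(
    schedule: ModeSchedule,
    seed: int = 0,
    fix_interval: float = 6.0,
    centre=DEFAULT_CENTRE,
    utc_offset_h: float = 0.0,
    bird_id: str = "mixed",
):
    """Stitch per-window simulations into one continuous track.

    Each window is simulated independently (spawned RNG streams) and then
    translated so its first position coincides with the previous window's
    last position.  Returns ``(track, labels)`` where ``labels`` is a frame
    (bird_id, year, month, mode) giving, per local calendar month, the mode
    occupying the majority of that month's fixes.
    """
    if not isinstance(schedule, ModeSchedule):
        schedule = ModeSchedule(schedule)
    seeds = np.random.SeedSequence(seed).spawn(len(schedule.windows))
    plane = LocalPlane(*centre)

    all_times = []
    all_xy = []
    offset = np.zeros(2)
    for i, w in enumerate(schedule.windows):
        duration_days = (w.end - w.start).total_seconds() / 86400.0
        sub_seed = int(seeds[i].generate_state(1)[0])
        if w.mode == RESIDENT:
            cfg = SimConfig(
                sigma2=w.params.get("sigma2", 100.0),
                tau_p=w.params.get("tau_p", 24.0),
                tau_v=w.params.get("tau_v", 1.0),
                fix_interval=fix_interval,
                duration=duration_days,
                centre=centre,
                seed=sub_seed,
                start=str(w.start),
                utc_offset_h=utc_offset_h,
            )
            rng = np.random.default_rng(sub_seed)
            times = _grid_times(w.start, duration_days, fix_interval)
            xy = _ouf_positions_km(cfg.sigma2, cfg.tau_p, cfg.tau_v, len(times), fix_interval, rng)
        else:
            rng = np.random.default_rng(sub_seed)
            times = _grid_times(w.start, duration_days, fix_interval)
            tr = simulate_nomadic_track(
                w.params.get("speed_kmh", 15.0),
                w.params.get("heading_persistence", 0.98),
                duration_days,
                fix_interval,
                seed=sub_seed,
                centre=centre,
                start=str(w.start),
            )
            xy = np.column_stack(plane.to_km(tr.fixes["lon"].to_numpy(), tr.fixes["lat"].to_numpy()))
        xy = xy - xy[0] + offset
        if i < len(schedule.windows) - 1:
            # last point of this window == first point of the next: drop it here
            offset = xy[-1]
            times, xy = times[:-1], xy[:-1]
        all_times.append(times)
        all_xy.append(xy)

    times = pd.DatetimeIndex(np.concatenate([t.tz_convert(None).values for t in all_times])).tz_localize("UTC")
    xy = np.concatenate(all_xy)
    track = _make_track(times, xy, centre, bird_id, utc_offset_h)
    labels = month_truth_labels(schedule, fix_interval, utc_offset_h, bird_id)
    return track, labels


def month_truth_labels(schedule: ModeSchedule, fix_interval=6.0, utc_offset_h=0.0, bird_id="mixed") -> pd.DataFrame:
    """Per-local-calendar-month truth: the mode holding the majority of fixes."""
    times = _grid_times(schedule.start, (schedule.end - schedule.start).total_seconds() / 86400.0, fix_interval)
    times = times[times < schedule.end]  # the terminal instant belongs to no month
    modes = np.empty(len(times), dtype=object)
    for w in schedule.windows:
        sel = (times >= w.start) & (times <= w.end)
        modes[np.asarray(sel)] = w.mode  # later windows win the shared boundary
    local = times + pd.to_timedelta(utc_offset_h, unit="h")
    df = pd.DataFrame({"year": local.year, "month": local.month, "mode": modes})
    out = (
        df.groupby(["year", "month"])["mode"]
        .agg(lambda s: s.value_counts().idxmax())
        .reset_index()
    )
    out.insert(0, "bird_id", bird_id)
    return out


def simulate_diel_track(
    roost_lonlat,
    forage_distance_km: float,
    duration: float,
    fix_interval: float = 1.0,
    seed: int = 0,
    roost_shift_km: float = 0.0,
    start=DEFAULT_START,
    utc_offset_h: float = 0.0,
    bird_id: str = "diel",
):
    """Roost-at-midnight / forage-by-day track with constructed truth.

    The bird sits exactly at the roost at every local midnight and moves
    toward a daily foraging site drawn at ``forage_distance_km`` in a random
    direction, with displacement profile sin(pi * hour / 24) peaking at local
    noon.  Optionally the roost itself shifts ``roost_shift_km`` (random
    direction) at each midnight.  Returns ``(track, truth)`` where truth has
    one row per local day: max_from_roost_km and roost_shift_km.
    """
    if forage_distance_km < 0:
        raise ValueError("forage_distance_km must be >= 0")
    if roost_shift_km < 0:
        raise ValueError("roost_shift_km must be >= 0")
    rng = np.random.default_rng(seed)
    times = _grid_times(start, duration, fix_interval)
    local = times + pd.to_timedelta(utc_offset_h, unit="h")
    days = (local - local[0].normalize()).days.to_numpy()
    hours = (local.hour + local.minute / 60.0).to_numpy()

    n_days = int(days.max()) + 1
    angles = rng.uniform(0, 2 * np.pi, n_days)
    forage_dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    shift_angles = rng.uniform(0, 2 * np.pi, n_days)
    roosts = np.zeros((n_days, 2))
    for d in range(1, n_days):
        roosts[d] = roosts[d - 1] + roost_shift_km * np.array(
            [np.cos(shift_angles[d]), np.sin(shift_angles[d])]
        )

    profile = np.sin(np.pi * hours / 24.0)
    xy = roosts[days] + (forage_distance_km * profile)[:, None] * forage_dirs[days]

    track = _make_track(times, xy, tuple(roost_lonlat), bird_id, utc_offset_h)
    day_max = forage_distance_km * np.array(
        [profile[days == d].max() if (days == d).any() else np.nan for d in range(n_days)]
    )
    truth = pd.DataFrame(
        {
            "bird_id": bird_id,
            "day": np.arange(n_days),
            "max_from_roost_km": day_max,
            "roost_shift_km": np.concatenate([[np.nan], np.full(n_days - 1, roost_shift_km)]),
        }
    )
    return track, truth


def write_truth_csv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False)
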