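"""Autocorrelation-aware kernel utilisation distributions, overlap, blocks.

The kernel density uses the bivariate-normal reference bandwidth with the
sample size replaced by an effective sample size N_eff = span / tau_p — the
autocorrelation correction that distinguishes AKDE from naive KDE.  The 95%
contour is the highest-density region of the gridded UD.  Overlap between
two UDs is the Bhattacharyya coefficient; the merge test uses a parametric
bootstrap of each UD's Gaussian approximation and requires the lower CI
bound to exceed 0.01.  Consecutive resident months passing the test chain
into a 'block', whose area is re-estimated from the pooled fixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geo import LocalPlane
from .track_io import MonthSegment
from .variogram import OUFFit, UnusableSegmentError, empirical_svf, fit_ouf, segment_svf

CHI2_95_2D = stats.chi2.ppf(0.95, df=2)  # = 5.991...; Gaussian 95% HDR area = this * pi * sigma^2
BC_MERGE_THRESHOLD = 0.01


@dataclass
class UD:
    """Gridded utilisation distribution on a local km plane.

    ``mass`` holds per-cell probability mass (sums to 1).  ``mu_km`` /
    ``cov_km2`` are the UD's Gaussian summary (sample mean; sample covariance
    plus squared bandwidth), used by the closed-form overlap path.
    """

    x_centres: np.ndarray
    y_centres: np.ndarray
    mass: np.ndarray  # shape (len(x), len(y))
    cell_km: float
    plane: LocalPlane
    mu_km: np.ndarray
    cov_km2: np.ndarray
    n_eff: float
    bird_id: str = ""
    period: tuple = ()
    point_mass: bool = False


@dataclass
class ResidencyArea:
    ud: UD
    area95_km2: float
    polygon95: object | None  # shapely polygon in lon/lat, or None if not built


@dataclass
class Block:
    bird_id: str
    months: list  # ordered (year, month) tuples
    area: ResidencyArea
    n_fixes: int


@dataclass
class BCResult:
    bc: float
    ci_low: float
    ci_high: float
    n_boot: int
    ok: bool = True


def effective_n(n_fixes: int, fix_interval_h: float, tau_p_h: float) -> float:
    """Autocorrelation-corrected sample size: span / tau_p in [1, n_fixes]."""
    if n_fixes <= 0 or fix_interval_h <= 0 or tau_p_h <= 0:
        raise ValueError("inputs must be positive")
    span = n_fixes * fix_interval_h
    return float(np.clip(span / tau_p_h, 1.0, n_fixes))


def akde_ud(segment_df: pd.DataFrame, fit: OUFFit, cell_km: float = 1.0,
            fix_interval_h: float = 6.0, bird_id: str = "", period=()) -> UD:
    """Gaussian-kernel UD of one segment's fixes with AKDE bandwidth.

    Per-axis bandwidth h^2 = sample_var * N_eff^{-1/3} (bivariate normal
    reference rule at the effective sample size).  The grid spans ±4 total
    standard deviations about the mean, so > 99.99% of mass is covered.
    """
    if not fit.converged:
        raise ValueError("akde_ud requires a converged fit")
    lon = segment_df["lon"].to_numpy()
    lat = segment_df["lat"].to_numpy()
    plane = LocalPlane(float(np.mean(lon)), float(np.mean(lat)))
    x, y = plane.to_km(lon, lat)
    n = len(x)

    if n < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0):
        mu = np.array([np.mean(x), np.mean(y)])
        return UD(
            x_centres=np.array([mu[0]]), y_centres=np.array([mu[1]]),
            mass=np.ones((1, 1)), cell_km=cell_km, plane=plane, mu_km=mu,
            cov_km2=np.zeros((2, 2)), n_eff=1.0, bird_id=bird_id, period=tuple(period),
            point_mass=True,
        )

    n_eff = effective_n(n, fix_interval_h, fit.tau_p_hat)
    sx2 = float(np.var(x, ddof=1))
    sy2 = float(np.var(y, ddof=1))
    h2x = sx2 * n_eff ** (-1.0 / 3.0)
    h2y = sy2 * n_eff ** (-1.0 / 3.0)

    mux, muy = float(np.mean(x)), float(np.mean(y))
    half_x = 4.0 * (np.sqrt(sx2) + np.sqrt(h2x))
    half_y = 4.0 * (np.sqrt(sy2) + np.sqrt(h2y))
    xc = _grid_axis(mux, half_x, cell_km)
    yc = _grid_axis(muy, half_y, cell_km)

    # separable Gaussian kernels: mass = Kx @ Ky^T / n, cell-integrated approx
    kx = np.exp(-0.5 * (xc[:, None] - x[None, :]) ** 2 / h2x) / np.sqrt(2 * np.pi * h2x)
    ky = np.exp(-0.5 * (yc[:, None] - y[None, :]) ** 2 / h2y) / np.sqrt(2 * np.pi * h2y)
    dens = kx @ ky.T / n  # density at cell centres
    mass = dens * cell_km**2
    mass /= mass.sum()

    cov = np.cov(np.vstack([x, y]), ddof=1) + np.diag([h2x, h2y])
    return UD(
        x_centres=xc, y_centres=yc, mass=mass, cell_km=cell_km, plane=plane,
        mu_km=np.array([mux, muy]), cov_km2=cov, n_eff=n_eff,
        bird_id=bird_id, period=tuple(period),
    )


def _grid_axis(centre: float, half_width: float, cell: float) -> np.ndarray:
    k = max(1, int(np.ceil(half_width / cell)))
    return centre + cell * np.arange(-k, k + 1)


def contour_area(ud: UD, level: float = 0.95, build_polygon: bool = True):
    """Highest-density region: smallest cell set holding >= ``level`` mass.

    Returns ``(area_km2, polygon)``; the polygon (lon/lat, shapely) is the
    dissolved union of the selected cells' boundaries, or None when
    ``build_polygon`` is false.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if ud.point_mass:
        return 0.0, None
    flat = ud.mass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level) + 1)
    selected = order[:k]
    area = k * ud.cell_km**2

    polygon = None
    if build_polygon:
        import shapely
        from shapely.ops import transform, unary_union

        ii, jj = np.unravel_index(selected, ud.mass.shape)
        half = ud.cell_km / 2.0
        boxes = shapely.box(
            ud.x_centres[ii] - half, ud.y_centres[jj] - half,
            ud.x_centres[ii] + half, ud.y_centres[jj] + half,
        )
        merged = unary_union(boxes)
        polygon = transform(lambda x, y: ud.plane.to_lonlat(np.asarray(x), np.asarray(y)), merged)
    return float(area), polygon


def residency_area(segment_df, fit, cell_km=1.0, fix_interval_h=6.0, level=0.95,
                   build_polygon=True, bird_id="", period=()) -> ResidencyArea:
    ud = akde_ud(segment_df, fit, cell_km, fix_interval_h, bird_id=bird_id, period=period)
    area, poly = contour_area(ud, level, build_polygon=build_polygon)
    return ResidencyArea(ud=ud, area95_km2=area, polygon95=poly)


def _gaussian_params_in_frame(ud: UD, frame: LocalPlane):
    """The UD's Gaussian summary expressed in another local plane (km)."""
    lon, lat = ud.plane.to_lonlat(ud.mu_km[0], ud.mu_km[1])
    x, y = frame.to_km(lon, lat)
    # covariance carried over unrotated: both planes are metric-true near the
    # means and residency areas are tens of km across, so rotation is negligible
    return np.array([float(x), float(y)]), ud.cov_km2


def bhattacharyya_gaussian(mu1, cov1, mu2, cov2) -> float:
    """Closed-form BC of two bivariate normals: exp(-D_B)."""
    mu1 = np.asarray(mu1, float)
    mu2 = np.asarray(mu2, float)
    cov1 = np.asarray(cov1, float)
    cov2 = np.asarray(cov2, float)
    cbar = 0.5 * (cov1 + cov2)
    diff = mu2 - mu1
    db = 0.125 * diff @ np.linalg.solve(cbar, diff) + 0.5 * np.log(
        np.linalg.det(cbar) / np.sqrt(np.linalg.det(cov1) * np.linalg.det(cov2))
    )
    return float(np.exp(-db))


def bhattacharyya(ud1: UD, ud2: UD) -> float:
    """Grid-sum BC = sum sqrt(p_i q_i) after resampling to a common grid."""
    if ud1.point_mass or ud2.point_mass:
        return 1.0 if (ud1.point_mass and ud2.point_mass and np.allclose(ud1.mu_km, ud2.mu_km)) else 0.0
    frame = ud1.plane
    # bounding boxes of both UDs in ud1's frame
    def bounds(ud):
        if ud is ud1:
            return ud.x_centres.min(), ud.x_centres.max(), ud.y_centres.min(), ud.y_centres.max()
        lon, lat = np.meshgrid(*_axis_lonlat(ud))
        x, y = frame.to_km(lon, lat)
        return x.min(), x.max(), y.min(), y.max()

    x0a, x1a, y0a, y1a = bounds(ud1)
    x0b, x1b, y0b, y1b = bounds(ud2)
    if x0a > x1b or x0b > x1a or y0a > y1b or y0b > y1a:
        warnings.warn("UD grids are disjoint; BC = 0")
        return 0.0
    cell = min(ud1.cell_km, ud2.cell_km)
    xs = np.arange(min(x0a, x0b), max(x1a, x1b) + cell, cell)
    ys = np.arange(min(y0a, y0b), max(y1a, y1b) + cell, cell)
    p = _resample_mass(ud1, frame, xs, ys, cell)
    q = _resample_mass(ud2, frame, xs, ys, cell)
    return float(np.sqrt(p * q).sum())


def _axis_lonlat(ud: UD):
    lon, _ = ud.plane.to_lonlat(ud.x_centres, np.full_like(ud.x_centres, ud.mu_km[1]))
    _, lat = ud.plane.to_lonlat(np.full_like(ud.y_centres, ud.mu_km[0]), ud.y_centres)
    return lon, lat


def _resample_mass(ud: UD, frame: LocalPlane, xs, ys, cell):
    from scipy.interpolate import RegularGridInterpolator

    dens = ud.mass / ud.cell_km**2
    interp = RegularGridInterpolator(
        (ud.x_centres, ud.y_centres), dens, bounds_error=False, fill_value=0.0
    )
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    if ud.plane is not frame:
        lon, lat = frame.to_lonlat(gx.ravel(), gy.ravel())
        ux, uy = ud.plane.to_km(lon, lat)
        pts = np.column_stack([ux, uy])
    else:
        pts = np.column_stack([gx.ravel(), gy.ravel()])
    mass = interp(pts).reshape(gx.shape) * cell**2
    total = mass.sum()
    return mass / total if total > 0 else mass


def bc_confidence(ud1: UD, ud2: UD, n_boot: int = 200, seed=None) -> BCResult:
    """Parametric-bootstrap CI for the Gaussian-approximation BC.

    Each replicate redraws the mean from N(mu, cov / N_eff) and the
    covariance from a Wishart with N_eff - 1 degrees of freedom; the CI is
    the 2.5/97.5 percentile band.  Fails closed (``ok=False``, no merge) when
    either effective sample size is too small to define the bootstrap.
    """
    mu2, cov2 = _gaussian_params_in_frame(ud2, ud1.plane)
    point = bhattacharyya_gaussian(ud1.mu_km, ud1.cov_km2, mu2, cov2)
    if ud1.point_mass or ud2.point_mass or ud1.n_eff < 2.0 + 1e-9 or ud2.n_eff < 2.0 + 1e-9:
        return BCResult(bc=point, ci_low=np.nan, ci_high=np.nan, n_boot=0, ok=False)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    params = ((ud1.mu_km, ud1.cov_km2, ud1.n_eff), (mu2, cov2, ud2.n_eff))
    for b in range(n_boot):
        drawn = []
        for mu, cov, neff in params:
            m = rng.multivariate_normal(mu, cov / neff)
            df = neff - 1.0
            c = stats.wishart.rvs(df=df, scale=cov / df, random_state=rng)
            drawn.append((m, c))
        reps[b] = bhattacharyya_gaussian(drawn[0][0], drawn[0][1], drawn[1][0], drawn[1][1])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BCResult(bc=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, ok=True)


@dataclass
class MonthRecord:
    """One resident month ready for overlap testing."""

    year: int
    month: int
    segment: MonthSegment
    fit: OUFFit
    ud: UD


def _consecutive(a, b) -> bool:
    ya, ma = a
    yb, mb = b
    return (yb, mb) == ((ya + 1, 1) if ma == 12 else (ya, ma + 1))


def merge_blocks(
    bird_id: str,
    records: list,
    cell_km: float = 1.0,
    fix_interval_h: float = 6.0,
    n_boot: int = 200,
    seed=None,
    chain: bool = True,
    build_polygon: bool = False,
) -> list:
    """Merge consecutive overlapping resident months into blocks.

    Consecutive-calendar-month pairs whose BC lower confidence bound exceeds
    0.01 join the same block (transitively when ``chain``, else pairwise
    only).  Each block's area is re-estimated: pooled fixes, re-fitted model,
    re-run AKDE.  Non-consecutive resident months never merge.
    """
    rng = np.random.default_rng(seed)
    records = sorted(records, key=lambda r: (r.year, r.month))
    blocks: list[list[MonthRecord]] = []
    current = []
    for rec in records:
        if not current:
            current = [rec]
            continue
        prev = current[-1]
        mergeable = _consecutive((prev.year, prev.month), (rec.year, rec.month))
        if mergeable and not chain and len(current) >= 2:
            mergeable = False  # pairwise-only mode: a block holds at most two months
        if mergeable:
            bcres = bc_confidence(prev.ud, rec.ud, n_boot=n_boot, seed=rng.integers(2**63))
            mergeable = bcres.ok and bcres.ci_low > BC_MERGE_THRESHOLD
        if mergeable:
            current.append(rec)
        else:
            blocks.append(current)
            current = [rec]
    if current:
        blocks.append(current)

    out = []
    for members in blocks:
        pooled = pd.concat([m.segment.data for m in members], ignore_index=True)
        try:
            svf = _pooled_svf(pooled)
            fit = fit_ouf(svf)
        except UnusableSegmentError:
            fit = members[0].fit
        if not fit.converged:
            fit = members[0].fit
        period = (
            (members[0].year, members[0].month),
            (members[-1].year, members[-1].month),
        )
        ra = residency_area(
            pooled, fit, cell_km=cell_km, fix_interval_h=fix_interval_h,
            build_polygon=build_polygon, bird_id=bird_id, period=period,
        )
        out.append(
            Block(
                bird_id=bird_id,
                months=[(m.year, m.month) for m in members],
                area=ra,
                n_fixes=len(pooled),
            )
        )
    return out


def _pooled_svf(df: pd.DataFrame):
    plane = LocalPlane(df["lon"].mean(), df["lat"].mean())
    x, y = plane.to_km(df["lon"].to_numpy(), df["lat"].to_numpy())
    t0 = df["timestamp"].iloc[0]
    times_h = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    return empirical_svf(times_h, np.column_stack([x, y]))


def build_blocks(rt, calls: pd.DataFrame, cell_km: float = 1.0, n_boot: int = 200,
                 seed=None, chain: bool = True, build_polygon: bool = False) -> list:
    """Pipeline helper: resident calls for one regular track -> blocks."""
    from .track_io import split_months

    resident = {
        (int(r.year), int(r.month))
        for r in calls.itertuples()
        if r.usable and r.resident and r.bird_id == rt.bird_id
    }
    records = []
    for seg in split_months(rt):
        if (seg.year, seg.month) not in resident:
            continue
        try:
            fit = fit_ouf(segment_svf(seg))
        except UnusableSegmentError:
            continue
        if not fit.converged:
            continue
        ud = akde_ud(seg.data, fit, cell_km, rt.grid_interval_h,
                     bird_id=rt.bird_id, period=((seg.year, seg.month),))
        records.append(MonthRecord(seg.year, seg.month, seg, fit, ud))
    return merge_blocks(
        rt.bird_id, records, cell_km=cell_km, fix_interval_h=rt.grid_interval_h,
        n_boot=n_boot, seed=seed, chain=chain, build_polygon=build_polygon,
    )


def block_summaries(blocks_df: pd.DataFrame, by=("species", "age_class"),
                    n_perm: int = 1000, seed=None) -> tuple:
    """Median/mean area per group plus pairwise median permutation tests.

    ``blocks_df`` needs columns ``area95_km2`` and the grouping columns.
    Returns ``(summary_table, pairwise_tests)``; the tests frame is empty
    when fewer than two groups are present.
    """
    from .metrics import pairwise_percentile_tests

    by = list(by)
    summary = (
        blocks_df.groupby(by)["area95_km2"]
        .agg(n="count", median_km2="median", mean_km2="mean")
        .reset_index()
    )
    groups = {
        "|".join(map(str, k if isinstance(k, tuple) else (k,))): g["area95_km2"].to_numpy()
        for k, g in blocks_df.groupby(by)
    }
    if len(groups) >= 2:
        tests = pairwise_percentile_tests(groups, "median", n_perm=n_perm, seed=seed)
    else:
        tests = pd.DataFrame(columns=["group_a", "group_b", "p_raw", "p_adj"])
    return summary, tests
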