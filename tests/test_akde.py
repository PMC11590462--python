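import numpy as np
import pandas as pd
import pytest
from scipy import stats

from movestrat.akde import (
    CHI2_95_2D,
    UD,
    MonthRecord,
    akde_ud,
    bc_confidence,
    bhattacharyya,
    bhattacharyya_gaussian,
    block_summaries,
    build_blocks,
    contour_area,
    effective_n,
    merge_blocks,
)
from movestrat.geo import LocalPlane
from movestrat.synthetic import SimConfig, simulate_ouf_track
from movestrat.track_io import regularize, split_months
from movestrat.variogram import OUFFit, classify_all_months, fit_ouf, segment_svf

FIT = OUFFit(100.0, 24.0, 1.0, 0.0, True)


def gaussian_ud(mu, cov_diag, cell=0.05, half=6.0):
    """Exact discretised Gaussian as a UD (oracle construction)."""
    xc = np.arange(mu[0] - half, mu[0] + half + cell, cell)
    yc = np.arange(mu[1] - half, mu[1] + half + cell, cell)
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    d = np.exp(-0.5 * ((gx - mu[0]) ** 2 / cov_diag[0] + (gy - mu[1]) ** 2 / cov_diag[1]))
    mass = d / d.sum()
    return UD(xc, yc, mass, cell, LocalPlane(144.0, -30.0), np.asarray(mu, float), np.diag(cov_diag), 100.0)


class TestEffectiveN:
    def test_span_over_tau(self):
        assert effective_n(120, 6.0, 24.0) == 30.0

    def test_floor_one(self):
        assert effective_n(10, 6.0, 1e6) == 1.0

    def test_cap_at_n(self):
        assert effective_n(120, 6.0, 1e-9) == 120.0

    def test_validation(self):
        with pytest.raises(ValueError):
            effective_n(0, 6.0, 24.0)


class TestAkdeUd:
    def test_mass_sums_to_one(self, resident_month_track):
        ud = akde_ud(resident_month_track.fixes, FIT, cell_km=1.0)
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_fix_point_mass(self):
        df = pd.DataFrame({"lon": [144.0], "lat": [-30.0]})
        ud = akde_ud(df, FIT)
        assert ud.point_mass

    def test_identical_positions_point_mass(self):
        df = pd.DataFrame({"lon": [144.0] * 5, "lat": [-30.0] * 5})
        ud = akde_ud(df, FIT)
        assert ud.point_mass

    def test_marginals_near_gaussian_at_large_neff(self):
        tr = simulate_ouf_track(
            SimConfig(sigma2=100, tau_p=6, tau_v=0.5, fix_interval=6, duration=240, seed=1)
        )
        ud = akde_ud(tr.fixes, OUFFit(100.0, 6.0, 0.5, 0.0, True), cell_km=1.0)
        # sample from the UD and KS-test each marginal against N(mu, sigma_ud)
        rng = np.random.default_rng(0)
        flat = ud.mass.ravel()
        idx = rng.choice(len(flat), size=500, p=flat)
        ii, jj = np.unravel_index(idx, ud.mass.shape)
        xs = ud.x_centres[ii] + rng.uniform(-0.5, 0.5, 500)
        ys = ud.y_centres[jj] + rng.uniform(-0.5, 0.5, 500)
        for vals, m, v in ((xs, ud.mu_km[0], ud.cov_km2[0, 0]), (ys, ud.mu_km[1], ud.cov_km2[1, 1])):
            assert stats.kstest(vals, "norm", args=(m, np.sqrt(v))).pvalue > 0.01

    def test_requires_converged_fit(self):
        df = pd.DataFrame({"lon": [144.0, 144.1], "lat": [-30.0, -30.1]})
        with pytest.raises(ValueError):
            akde_ud(df, OUFFit(np.nan, np.nan, np.nan, np.inf, False))


class TestContourArea:
    def test_gaussian_closed_form(self):
        ud = gaussian_ud([0.0, 0.0], [4.0, 4.0], cell=0.05, half=10.0)
        area, _ = contour_area(ud, build_polygon=False)
        assert area == pytest.approx(CHI2_95_2D * np.pi * 4.0, rel=0.05)

    def test_monotone_in_level(self):
        ud = gaussian_ud([0.0, 0.0], [1.0, 1.0])
        areas = [contour_area(ud, lv, build_polygon=False)[0] for lv in (0.5, 0.8, 0.95, 0.99)]
        assert (np.diff(areas) > 0).all()

    def test_uniform_selects_ceil(self):
        k = 40
        xc = np.arange(k, dtype=float)
        ud = UD(xc, np.array([0.0]), np.full((k, 1), 1.0 / k), 1.0, LocalPlane(144, -30), np.zeros(2), np.eye(2), 10.0)
        area, _ = contour_area(ud, 0.95, build_polygon=False)
        assert area == np.ceil(0.95 * k)

    def test_level_validation(self):
        ud = gaussian_ud([0, 0], [1, 1])
        with pytest.raises(ValueError):
            contour_area(ud, 1.5)

    def test_polygon_contains_mode(self, resident_month_track):
        import shapely

        ud = akde_ud(resident_month_track.fixes, FIT, cell_km=1.0)
        area, poly = contour_area(ud, build_polygon=True)
        assert area > 0
        i, j = np.unravel_index(np.argmax(ud.mass), ud.mass.shape)
        lon, lat = ud.plane.to_lonlat(ud.x_centres[i], ud.y_centres[j])
        assert poly.covers(shapely.points(lon, lat))

    def test_grid_refinement_stability(self, resident_month_track):
        a1, _ = contour_area(akde_ud(resident_month_track.fixes, FIT, cell_km=0.5), build_polygon=False)
        a2, _ = contour_area(akde_ud(resident_month_track.fixes, FIT, cell_km=1.0), build_polygon=False)
        assert abs(a2 - a1) / a1 < 0.02


class TestBhattacharyya:
    def test_identical_uds(self):
        ud = gaussian_ud([0, 0], [1, 1])
        assert bhattacharyya(ud, ud) == pytest.approx(1.0, abs=1e-6)

    def test_unit_gaussians_two_apart(self):
        # numeric-integration value e^{-1/8 * 4} = e^{-0.5}
        assert bhattacharyya_gaussian([0, 0], np.eye(2), [2, 0], np.eye(2)) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )
        u1 = gaussian_ud([0, 0], [1, 1])
        u2 = gaussian_ud([2, 0], [1, 1])
        assert bhattacharyya(u1, u2) == pytest.approx(np.exp(-0.5), abs=1e-3)

    def test_grid_vs_closed_form_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mu1, mu2 = rng.normal(0, 1, 2), rng.normal(0, 1, 2)
            v1, v2 = rng.uniform(0.5, 2, 2), rng.uniform(0.5, 2, 2)
            bc_g = bhattacharyya(gaussian_ud(mu1, v1), gaussian_ud(mu2, v2))
            bc_c = bhattacharyya_gaussian(mu1, np.diag(v1), mu2, np.diag(v2))
            assert bc_g == pytest.approx(bc_c, abs=1e-2)

    def test_symmetry(self):
        u1 = gaussian_ud([0, 0], [1.5, 0.8])
        u2 = gaussian_ud([1, 1], [0.9, 1.2])
        assert bhattacharyya_gaussian(u1.mu_km, u1.cov_km2, u2.mu_km, u2.cov_km2) == pytest.approx(
            bhattacharyya_gaussian(u2.mu_km, u2.cov_km2, u1.mu_km, u1.cov_km2), abs=1e-12
        )

    def test_disjoint_grids_zero_with_warning(self):
        u1 = gaussian_ud([0, 0], [0.5, 0.5], half=3.0)
        u2 = gaussian_ud([100, 100], [0.5, 0.5], half=3.0)
        with pytest.warns(UserWarning):
            assert bhattacharyya(u1, u2) == 0.0


@pytest.fixture(scope="module")
def long_ud():
    tr = simulate_ouf_track(SimConfig(sigma2=100, tau_p=24, tau_v=1, fix_interval=6, duration=90, seed=3))
    return akde_ud(tr.fixes, FIT)


class TestBcConfidence:
    def test_identical_high_ci(self, long_ud):
        r = bc_confidence(long_ud, long_ud, seed=0)
        assert r.ok and r.ci_low > 0.9

    def test_far_apart_low_ci(self, long_ud):
        tr = simulate_ouf_track(
            SimConfig(sigma2=100, tau_p=24, tau_v=1, fix_interval=6, duration=90, seed=4, centre=(146.2, -30.0))
        )
        far = akde_ud(tr.fixes, FIT)
        r = bc_confidence(long_ud, far, seed=0)
        assert r.ok and r.ci_high < 0.01

    def test_seed_determinism(self, long_ud):
        r1 = bc_confidence(long_ud, long_ud, seed=5)
        r2 = bc_confidence(long_ud, long_ud, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_brackets_between_zero_and_one_ordering(self, long_ud):
        r = bc_confidence(long_ud, long_ud, seed=1)
        assert 0 <= r.ci_low <= r.ci_high <= 1 + 1e-9

    def test_small_neff_fails_closed(self, long_ud):
        small = UD(
            long_ud.x_centres, long_ud.y_centres, long_ud.mass, long_ud.cell_km,
            long_ud.plane, long_ud.mu_km, long_ud.cov_km2, n_eff=1.5,
        )
        r = bc_confidence(long_ud, small, seed=0)
        assert not r.ok


def month_records(tracks_by_month):
    """Build MonthRecords for consecutive months from one concatenated track."""
    records = []
    for (year, month), tr in tracks_by_month:
        seg = split_months(regularize(tr))[0]
        fit = fit_ouf(segment_svf(seg))
        ud = akde_ud(seg.data, fit, cell_km=1.0)
        records.append(MonthRecord(year, month, seg, fit, ud))
    return records


class TestMergeBlocks:
    @staticmethod
    def sim_month(year, month, seed, centre=(144.0, -30.0)):
        start = pd.Timestamp(year=year, month=month, day=1, tz="UTC")
        days = ((start + pd.offsets.MonthBegin(1)) - start).days - 0.25
        tr = simulate_ouf_track(
            SimConfig(sigma2=100, tau_p=12, tau_v=1, fix_interval=6, duration=days, seed=seed,
                      start=str(start), centre=centre)
        )
        return (year, month), tr

    def test_same_site_three_months_one_block(self):
        recs = month_records([self.sim_month(2021, m, 10 + m) for m in (1, 2, 3)])
        blocks = merge_blocks("b", recs, seed=0)
        assert len(blocks) == 1
        assert blocks[0].months == [(2021, 1), (2021, 2), (2021, 3)]
        assert blocks[0].area.area95_km2 > 0

    def test_distant_sites_two_blocks(self):
        recs = month_records(
            [self.sim_month(2021, 1, 1), self.sim_month(2021, 2, 2, centre=(145.1, -30.0))]
        )
        blocks = merge_blocks("b", recs, seed=0)
        assert len(blocks) == 2

    def test_non_consecutive_never_merged(self):
        recs = month_records([self.sim_month(2021, 1, 1), self.sim_month(2021, 3, 3)])
        blocks = merge_blocks("b", recs, seed=0)
        assert len(blocks) == 2

    def test_pairwise_mode_limits_block_size(self):
        recs = month_records([self.sim_month(2021, m, 20 + m) for m in (1, 2, 3, 4)])
        blocks = merge_blocks("b", recs, seed=0, chain=False)
        assert all(len(b.months) <= 2 for b in blocks)

    def test_build_blocks_pipeline(self):
        tr = simulate_ouf_track(
            SimConfig(sigma2=100, tau_p=12, tau_v=1, fix_interval=6, duration=89, seed=5,
                      start="2021-01-01T00:00:00Z", bird_id="bb")
        )
        rt = regularize(tr)
        calls = classify_all_months([rt])
        blocks = build_blocks(rt, calls, seed=1)
        assert len(blocks) >= 1
        assert sum(len(b.months) for b in blocks) == int(calls["resident"].sum())


class TestBlockSummaries:
    def test_single_block(self):
        df = pd.DataFrame({"species": ["SNI"], "age_class": ["adult"], "area95_km2": [42.0]})
        summary, tests = block_summaries(df)
        assert summary["median_km2"].iloc[0] == summary["mean_km2"].iloc[0] == 42.0
        assert tests.empty

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "species": ["A"] * 30 + ["B"] * 30,
                "age_class": "adult",
                "area95_km2": np.concatenate([rng.normal(100, 5, 30), rng.normal(400, 20, 30)]),
            }
        )
        summary, tests = block_summaries(df, by=["species"], n_perm=500, seed=1)
        med = summary.set_index("species")["median_km2"]
        assert med["B"] / med["A"] == pytest.approx(4.0, rel=0.15)
        assert tests["p_adj"].iloc[0] <= 0.01
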