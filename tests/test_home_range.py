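"""MCP, kernel UD, isopleths, core detection, summaries and density."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import ConvexHull
from shapely.geometry import box

from mangrovemove import home_range as hr
from mangrovemove.channel_crossings import ChannelFeature


def _hull_area_km2(pts):
    """Independent oracle: exact convex hull area via scipy (qhull)."""
    return ConvexHull(pts).volume / 1e6


class TestMCP:
    def test_triangle_area(self):
        res = hr.compute_mcp(np.array([[0, 0], [0, 1000], [1000, 0]]), percent=100)
        assert res.area_km2 == pytest.approx(0.5)

    def test_identical_points_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = hr.compute_mcp(np.array([[5.0, 5.0]] * 10), percent=100)
        assert res.area_km2 == 0.0
        assert res.degenerate

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="degenerate|collinear"):
            res = hr.compute_mcp(pts, percent=100)
        assert res.area_km2 == 0.0

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            hr.compute_mcp(np.array([[0, 0], [1, 1]]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_mcp_matches_hull_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 5000, size=(150, 2))
        res = hr.compute_mcp(pts, percent=100)
        assert res.area_km2 == pytest.approx(_hull_area_km2(pts), rel=1e-9)

    def test_trimmed_mcp_matches_brute_force(self):
        """95% MCP: drop the ceil(5%) farthest-from-centroid fixes, then hull."""
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 2000, size=(200, 2))
        res = hr.compute_mcp(pts, percent=95)
        d = np.hypot(*(pts - pts.mean(axis=0)).T)
        keep = np.argsort(d, kind="stable")[: 200 - math.ceil(0.05 * 200)]
        assert res.area_km2 == pytest.approx(_hull_area_km2(pts[keep]), rel=1e-9)


class TestKernelUD:
    def test_single_fix_isopleths_match_closed_form(self):
        """Superlevel sets of one Gaussian kernel: area(p) = -2 ln(1-p) pi h^2."""
        ud = hr.compute_fixed_kernel_ud(np.array([[0.0, 0.0]]), h=1000.0, cell=100.0)
        profile = hr.extract_isopleths(ud, levels=[75.0, 95.0])
        a75, a95 = profile.areas_km2
        assert a75 == pytest.approx(-2 * math.log(0.25) * math.pi, rel=0.02)  # 8.71
        assert a95 == pytest.approx(-2 * math.log(0.05) * math.pi, rel=0.02)  # 18.82

    def test_two_distant_fixes_split_mass_evenly(self):
        xy = np.array([[0.0, 0.0], [20_000.0, 0.0]])
        ud = hr.compute_fixed_kernel_ud(xy, h=1000.0)
        xs = ud.x0 + (np.arange(ud.density.shape[1]) + 0.5) * ud.cell
        left = ud.density[:, xs < 10_000.0].sum() * ud.cell_area_m2
        assert left == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("n", [1, 7, 40])
    def test_ud_normalized(self, n):
        rng = np.random.default_rng(n)
        ud = hr.compute_fixed_kernel_ud(rng.normal(0, 3000, size=(n, 2)), h=1000.0)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_cell_too_coarse_errors(self):
        with pytest.raises(ValueError, match="too coarse"):
            hr.compute_fixed_kernel_ud(np.zeros((1, 2)), h=1000.0, cell=300.0)

    def test_isopleth_areas_nondecreasing(self):
        rng = np.random.default_rng(5)
        ud = hr.compute_fixed_kernel_ud(rng.normal(0, 2000, size=(30, 2)), h=1000.0)
        profile = hr.extract_isopleths(ud)
        assert (np.diff(profile.areas_km2) >= 0).all()

    def test_uniform_ud_isopleths_are_linear(self):
        """On a uniform UD over a 10 km^2 island, area(p) ~ p/100 * 10."""
        cell = 100.0
        ny = nx = 50
        density = np.zeros((ny, nx))
        density[10:30, 15:35] = 1.0  # 400 cells = 4 km2... scale to 10 km2
        density = np.zeros((ny, nx))
        density[5:45, 20:45] = 1.0  # 40x25=1000 cells x (100 m)^2 = 10 km2
        density /= density.sum() * cell * cell
        ud = hr.UtilizationDistribution(0.0, 0.0, cell, density, h=1000.0)
        profile = hr.extract_isopleths(ud, levels=[20.0, 50.0, 80.0])
        for p, a in zip(profile.levels, profile.areas_km2):
            assert a == pytest.approx(p / 100.0 * 10.0, rel=0.02)


class TestMaskWater:
    def _result(self, geom):
        return hr.HomeRangeResult("a", "MCP", 95, geom, geom.area / 1e6)

    def test_polygon_on_land_unchanged(self):
        poly = box(0, 0, 2000, 2000)
        chan = [ChannelFeature("c", box(5000, 0, 6500, 2000), 1500.0)]
        res = hr.mask_water(self._result(poly), chan)
        assert res.area_km2 == pytest.approx(4.0)
        assert res.water_masked

    def test_wide_channel_subtracted(self):
        # polygon 2x2 km, half covered by a 1500 m channel -> area halved
        poly = box(0, 0, 2000, 2000)
        chan = [ChannelFeature("c", box(1000, -100, 2500, 2100), 1500.0)]
        res = hr.mask_water(self._result(poly), chan)
        assert res.area_km2 == pytest.approx(2.0)

    def test_narrow_channel_kept(self):
        poly = box(0, 0, 2000, 2000)
        chan = [ChannelFeature("c", box(500, -100, 1400, 2100), 900.0)]
        res = hr.mask_water(self._result(poly), chan)
        assert res.area_km2 == pytest.approx(4.0)


class TestAsymptote:
    def test_full_mcp_curve_nondecreasing(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 4000, size=(300, 2))
        curve, _ = hr.asymptote_curve(
            pts, step=50,
            estimator=lambda p: hr.compute_mcp(p, percent=100).area_km2,
        )
        areas = [a for _, a in curve]
        assert all(b >= a - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_bounded_range_reaches_asymptote(self, simulated_tiger):
        _, traj, _ = simulated_tiger
        curve, asymptote = hr.asymptote_curve(traj.xy, step=50)
        assert asymptote is not None
        assert asymptote < len(traj.xy)

    def test_short_input_makes_no_claim(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1000, size=(60, 2))
        curve, asymptote = hr.asymptote_curve(pts, step=50)
        assert len(curve) == 1
        assert asymptote is None


class TestCoreDetection:
    def _mixture_profile(self, core_mass=0.75):
        """Isopleth areas of a constructed tight-core + wide-background UD.

        core_mass sits in a compact Gaussian bump (sd 300 m); the rest is
        spread uniformly over the 20 km square, so the area-vs-level curve
        is flat-then-steep with its bend at the mass boundary.
        """
        cell = 200.0
        n = 100  # 20 km square
        xs = (np.arange(n) + 0.5) * cell - 10_000.0
        gx, gy = np.meshgrid(xs, xs)
        sigma = 300.0
        gauss = np.exp(-(gx**2 + gy**2) / (2 * sigma**2))
        gauss /= gauss.sum() * cell * cell
        uniform = np.full((n, n), 1.0 / (n * n * cell * cell))
        density = core_mass * gauss + (1 - core_mass) * uniform
        ud = hr.UtilizationDistribution(-10_000.0, -10_000.0, cell, density, h=300.0)
        return hr.extract_isopleths(ud)

    def test_detects_constructed_mass_boundary(self):
        level = hr.detect_core_isopleth(self._mixture_profile(0.75))
        assert level is not None
        assert abs(level - 75.0) <= 5.0

    def test_linear_profile_returns_none(self):
        profile = hr.IsoplethProfile(np.arange(5, 96, 5.0), np.arange(5, 96, 5.0) * 2.0)
        assert hr.detect_core_isopleth(profile) is None

    def test_invariant_to_area_rescaling(self):
        profile = self._mixture_profile()
        scaled = hr.IsoplethProfile(profile.levels, profile.areas_km2 * 37.5)
        assert hr.detect_core_isopleth(profile) == hr.detect_core_isopleth(scaled)


class TestSummaries:
    def test_single_animal_reports_blank_se(self):
        import pandas as pd

        table = pd.DataFrame(
            {"animal_id": ["a"], "sex": ["F"], "fk95": [62.17]}
        )
        out = hr.summarize_home_ranges(table, ["fk95"])
        row = out["summary"].iloc[0]
        assert row["mean"] == 62.17
        assert np.isnan(row["se"])

    def test_excluded_animals_listed(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "animal_id": ["a", "b", "c"],
                "sex": ["F", "F", "F"],
                "fk95": [62.17, 50.80, 191.31],
            }
        )
        out = hr.summarize_home_ranges(table, ["fk95"], exclude={"c": "transient"})
        assert out["summary"].iloc[0]["mean"] == pytest.approx(56.485)
        assert list(out["excluded"]["animal_id"]) == ["c"]


class TestDensity:
    def test_scale_invariance(self):
        d1 = hr.estimate_density(1645.0, (34.81, 7.26), (58.27, 25.51))
        d2 = hr.estimate_density(3290.0, (34.81, 7.26), (58.27, 25.51))
        assert d2.density_per_100km2 == pytest.approx(d1.density_per_100km2, abs=0.1)

    def test_core_equal_to_land_warns_and_counts_one(self):
        with pytest.warns(UserWarning, match="single resident"):
            d = hr.estimate_density(100.0, (100.0, 10.0), (100.0, 10.0))
        assert d.n_females == d.n_males == 1
        assert d.density_per_100km2 == pytest.approx(2.0)

    def test_se_larger_than_mean_rejected(self):
        with pytest.raises(ValueError, match="SE"):
            hr.estimate_density(1645.0, (34.0, 40.0), (58.0, 10.0))


@given(st.integers(0, 2**31 - 1))
def test_isopleth_profile_monotone_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 25))
    ud = hr.compute_fixed_kernel_ud(
        rng.normal(0, 2500, size=(n, 2)), h=1000.0, cell=250.0, pad=2500.0
    )
    profile = hr.extract_isopleths(ud, levels=[10, 30, 50, 70, 90])
    assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)
    assert (np.diff(profile.areas_km2) >= 0).all()
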