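"""Crossing detection, null paths, width binning and the barrier test."""

import numpy as np
import pytest
from shapely.geometry import box

from mangrovemove import channel_crossings as cc
from mangrovemove.raster import PHOENIX, WATER, GridRaster


def _strip(cid, lo, hi, y1=10_000.0):
    return cc.ChannelFeature(cid, box(lo, 0.0, hi, y1), hi - lo)


def _crossing_count_oracle(xy, strips):
    """Exhaustive interval-arithmetic oracle for vertical strip channels."""
    count = {}
    for i in range(len(xy) - 1):
        a, b = sorted([xy[i][0], xy[i + 1][0]])
        for ch in strips:
            lo, _, hi, _ = ch.geometry.bounds
            if a <= lo and b >= hi:
                count[ch.id] = count.get(ch.id, 0) + 1
    return count


class TestDetectCrossings:
    def test_land_segment_no_records(self):
        recs = cc.detect_crossings(
            ("p", np.array([[0.0, 1.0], [50.0, 2.0]])), [_strip("c", 100, 200)]
        )
        assert recs == []

    def test_single_span(self):
        recs = cc.detect_crossings(
            ("p", np.array([[50.0, 5.0], [250.0, 5.0]])), [_strip("c", 100, 200)]
        )
        assert len(recs) == 1
        assert recs[0].width_m == 100.0
        assert recs[0].source == "observed"

    def test_zigzag_matches_exhaustive_oracle(self):
        strips = [_strip("a", 100, 160), _strip("b", 400, 480), _strip("c", 900, 1150)]
        xy = np.array([
            [0, 0], [200, 50], [50, 100], [500, 150], [300, 200],
            [1300, 250], [700, 300], [80, 350],
        ], dtype=float)
        recs = cc.detect_crossings(("p", xy), strips)
        got = {}
        for r in recs:
            got[r.channel_id] = got.get(r.channel_id, 0) + 1
        expected = _crossing_count_oracle(xy, strips)
        assert got == expected
        assert sum(expected.values()) >= 5  # the fixture really zigzags

    def test_reentry_counts_again(self):
        xy = np.array([[0, 0], [300, 0], [0, 50], [300, 50]], dtype=float)
        recs = cc.detect_crossings(("p", xy), [_strip("c", 100, 200)])
        assert len(recs) == 3

    def test_too_short_path_errors(self):
        with pytest.raises(ValueError, match="2 fixes"):
            cc.detect_crossings(("p", np.array([[0.0, 0.0]])), [_strip("c", 1, 2)])


class TestCommonPolygon:
    def test_equals_full_mcp_for_one_animal(self):
        from mangrovemove.home_range import compute_mcp

        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 3000, size=(60, 2))
        assert cc.common_polygon(pts).equals(compute_mcp(pts, 100).geometry)

    def test_pooled_hull_contains_individual_hulls(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 2000, size=(40, 2))
        b = rng.uniform(1500, 4000, size=(40, 2))
        pooled = cc.common_polygon(np.vstack([a, b]))
        assert pooled.contains(cc.common_polygon(a).buffer(-1e-9))
        assert pooled.contains(cc.common_polygon(b).buffer(-1e-9))

    def test_degenerate_errors(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0) * 2])
        with pytest.raises(ValueError, match="degenerate"):
            cc.common_polygon(pts)


class TestNullPaths:
    @pytest.fixture()
    def all_land(self):
        return GridRaster(np.full((40, 40), PHOENIX), 0.0, 0.0, 250.0)

    def test_n_zero_gives_empty_list(self, all_land):
        xy = np.array([[5000.0, 5000.0], [5400.0, 5000.0]])
        assert cc.generate_null_paths(xy, n=0, landscape=all_land) == []

    def test_unconstrained_paths_match_step_count_and_start(self, all_land):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.uniform(-300, 300, size=(13, 2)), axis=0) + 5000.0
        paths = cc.generate_null_paths(
            xy, n=5, polygon=box(-1e7, -1e7, 1e7, 1e7), landscape=None, seed=1
        )
        lens = np.hypot(*np.diff(xy, axis=0).T)
        for p in paths:
            assert p.shape == xy.shape
            assert np.array_equal(p[0], xy[0])
            plens = np.hypot(*np.diff(p, axis=0).T)
            assert (plens >= lens.min() - 1e-9).all()
            assert (plens <= lens.max() + 1e-9).all()

    def test_constraints_respected(self, small_landscape):
        _, raster, channels = small_landscape
        from mangrovemove.raster import WATER as W

        poly = box(2000, 2000, 10_000, 10_000)
        start = np.array([6000.0, 6000.0])
        if raster.value_at([start[0]], [start[1]])[0] == W:
            start = start + 400.0
        xy = np.vstack([start, start + [350, 0], start + [100, 300], start + [0, 40]])
        paths = cc.generate_null_paths(xy, n=8, polygon=poly, landscape=raster, seed=3)
        for p in paths:
            assert (raster.value_at(p[:, 0], p[:, 1]) != W).all()
            assert (p[:, 0] >= 2000).all() and (p[:, 0] <= 10_000).all()

    def test_deterministic_under_seed(self, all_land):
        xy = np.array([[5000.0, 5000.0], [5400.0, 5100.0], [5300.0, 4800.0]])
        p1 = cc.generate_null_paths(xy, n=3, landscape=all_land, seed=9)
        p2 = cc.generate_null_paths(xy, n=3, landscape=all_land, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2))

    def test_infeasible_constraints_error(self):
        water = GridRaster(np.full((20, 20), WATER), 0.0, 0.0, 250.0)
        water.data[10, 10] = PHOENIX  # a single land cell, start island
        start = np.array([2625.0, 2625.0])
        xy = np.vstack([start, start + [2000.0, 0.0]])
        with pytest.raises(RuntimeError, match="constraints"):
            cc.generate_null_paths(xy, n=2, landscape=water, max_attempts=500)


class TestBinning:
    def test_default_edges_and_assignment(self):
        obs = [cc.CrossingRecord("p", "c", w) for w in (54.0, 1000.0)]
        avail = [cc.CrossingRecord("p", "c", w, "null") for w in (10.0, 1400.0)]
        table = cc.bin_crossings(obs, avail)
        lo = table.edges[:-1]
        # width 54 -> [50, 100); width 1000 -> the first 500 m bin [1000, 1500)
        assert table.observed[np.flatnonzero(lo == 50.0)[0]] == 1
        assert table.observed[np.flatnonzero(lo == 1000.0)[0]] == 1

    def test_counts_match_tally_oracle(self):
        rng = np.random.default_rng(4)
        widths = rng.uniform(10, 1800, size=200)
        obs = [cc.CrossingRecord("p", "c", w) for w in widths]
        avail = [cc.CrossingRecord("p", "c", w, "null") for w in widths]
        table = cc.bin_crossings(obs, avail)
        tally, _ = np.histogram(widths, bins=table.edges)
        assert np.array_equal(table.observed, tally.astype(float))
        assert table.observed.sum() == 200

    def test_record_beyond_final_edge_extends_with_warning(self):
        obs = [cc.CrossingRecord("p", "c", 2600.0)]
        avail = [cc.CrossingRecord("p", "c", 100.0, "null")]
        with pytest.warns(UserWarning, match="extending"):
            table = cc.bin_crossings(obs, avail, edges=np.array([0.0, 1000.0, 1500.0]))
        assert table.edges[-1] > 2600.0
        assert table.observed.sum() == 1

    def test_empty_availability_errors(self):
        with pytest.raises(ValueError, match="availability"):
            cc.bin_crossings([cc.CrossingRecord("p", "c", 50.0)], [])


class TestChiSquare:
    def _table(self, obs, avail, edges=None):
        edges = np.arange(0.0, 50.0 * (len(obs) + 1), 50.0) if edges is None else edges
        return cc.WidthBinTable(edges=edges, observed=np.asarray(obs, float),
                                availability=np.asarray(avail, float))

    def test_proportional_counts_give_zero(self):
        t = cc.crossing_chisq(self._table([10, 20, 30], [1, 2, 3]))
        assert t.chi_square == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        t = cc.crossing_chisq(self._table([10, 0], [1, 1]))
        assert t.merged_expected.tolist() == [5.0, 5.0]
        assert t.chi_square == pytest.approx(10.0)
        assert t.df == 1

    def test_totals_conserved_after_merging(self):
        rng = np.random.default_rng(5)
        obs = rng.integers(0, 30, size=12)
        avail = rng.integers(0, 40, size=12) + 1
        t = cc.crossing_chisq(self._table(obs, avail))
        assert t.merged_expected.sum() == pytest.approx(obs.sum())
        assert t.merged_observed.sum() == obs.sum()
        assert t.df == len(t.merged_observed) - 1

    def test_sparse_bins_merged_to_reach_min_expected(self):
        t = cc.crossing_chisq(self._table([50, 1, 0, 49], [50, 1, 1, 48]))
        assert (t.merged_expected >= 1.0).all()

    def test_too_few_availability_bins_error(self):
        with pytest.raises(ValueError, match=">= 2 bins"):
            cc.crossing_chisq(self._table([5, 5], [7, 0]))


class TestBarrierBehaviour:
    def test_reluctant_world_underuses_wide_channels(self):
        """With reluctance on, wide channels (>400 m) are crossed well below
        their availability, while narrow channels are not."""
        from mangrovemove.experiments import crossing_replicate

        obs_w = obs_tot = av_w = av_tot = 0.0
        for seed in (3, 4, 5):
            res = crossing_replicate(seed, days=40, crossing_halfwidth=150.0,
                                     width_range=(30.0, 600.0))
            t = res["table"]
            wide = t.edges[:-1] >= 300.0
            obs_w += t.observed[wide].sum()
            obs_tot += t.observed.sum()
            av_w += t.availability[wide].sum()
            av_tot += t.availability.sum()
        assert obs_tot > 150
        avail_wide = av_w / av_tot
        obs_wide = obs_w / obs_tot
        assert avail_wide > 0.005           # wide channels are genuinely available
        assert obs_wide < 0.5 * avail_wide  # ... but seldom crossed
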