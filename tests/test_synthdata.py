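"""Generator contracts: landscapes match their recipe, tigers their truth."""

import math

import numpy as np
import pytest

from mangrovemove.channel_crossings import detect_crossings
from mangrovemove.raster import ALL_CLASSES, WATER, GridRaster
from mangrovemove.synthdata import (SUNDARBAN_FRACTIONS, LandscapeSpec,
                                    TigerSimSpec, generate_landscape,
                                    random_land_point, simulate_tiger,
                                    synthetic_syzygy_table)

UNIFORM = {c: 1.0 for c in ALL_CLASSES}
FLAT = tuple([1.0] * 24)


class TestGenerateLandscape:
    def test_class_fractions_match_recipe(self, small_landscape):
        spec, raster, channels = small_landscape
        realized = raster.class_fractions()
        for name in ALL_CLASSES:
            assert realized[name] == pytest.approx(spec.fraction(name), abs=0.02)
        assert all(c.width_m > 0 for c in channels)

    def test_sundarban_default_fractions(self):
        raster, _ = generate_landscape(LandscapeSpec(seed=3))
        realized = raster.class_fractions()
        # the mangrove archipelago composition: ~41.5% water, ~36.9% Phoenix
        assert realized["Water"] == pytest.approx(SUNDARBAN_FRACTIONS["Water"], abs=0.02)
        assert realized["Phoenix"] == pytest.approx(SUNDARBAN_FRACTIONS["Phoenix"], abs=0.02)

    def test_channels_rasterized_as_water(self, small_landscape):
        _, raster, channels = small_landscape
        for c in channels:
            lo, _, hi, _ = c.geometry.bounds
            xs = np.linspace(lo + 1, hi - 1, 7)
            ys = np.full_like(xs, 6_000.0)
            assert (raster.value_at(xs, ys) == WATER).all()

    def test_all_land_when_no_channels_and_no_water(self):
        fr = {"Water": 0.0, "Phoenix": 0.6, "Ceriops": 0.2, "Barren": 0.1,
              "AvicenniaSonneratia": 0.1}
        raster, channels = generate_landscape(
            LandscapeSpec(extent=(0, 0, 6000, 6000), class_fractions=fr,
                          channel_count=0, seed=1)
        )
        assert channels == []
        assert (raster.data != WATER).all()

    def test_deterministic(self):
        spec = LandscapeSpec(extent=(0, 0, 8000, 8000), channel_count=3, seed=42)
        r1, c1 = generate_landscape(spec)
        r2, c2 = generate_landscape(spec)
        assert (r1.data == r2.data).all()
        assert [c.width_m for c in c1] == [c.width_m for c in c2]
        assert all(a.geometry.equals(b.geometry) for a, b in zip(c1, c2))

    def test_extent_too_small_raises(self):
        with pytest.raises(ValueError, match="too small|budget"):
            generate_landscape(
                LandscapeSpec(extent=(0, 0, 3000, 3000), channel_count=10,
                              width_range=(200, 400), seed=0)
            )

    @pytest.mark.parametrize(
        "bad",
        [
            dict(class_fractions={"Water": 0.5, "Phoenix": 0.6}),
            dict(cell_size=-5.0),
            dict(width_range=(10.0, 100.0)),
            dict(channel_count=-1),
        ],
    )
    def test_spec_validation(self, bad):
        with pytest.raises(ValueError):
            LandscapeSpec(**bad)


class TestSimulateTiger:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TigerSimSpec(home_center=(0, 0), fix_interval_hours=0.5)
        with pytest.raises(ValueError):
            TigerSimSpec(home_center=(0, 0), activity_profile=(1.0,) * 23)
        with pytest.raises(ValueError):
            TigerSimSpec(home_center=(0, 0), fix_success_prob=1.2)
        with pytest.raises(ValueError):
            TigerSimSpec(home_center=(0, 0),
                         habitat_weights={c: 0.0 for c in ALL_CLASSES})

    def test_home_center_in_water_rejected(self, small_landscape):
        _, raster, channels = small_landscape
        lo, _, hi, _ = channels[0].geometry.bounds
        spec = TigerSimSpec(home_center=((lo + hi) / 2, 6000.0), duration_days=2)
        with pytest.raises(ValueError, match="Water"):
            simulate_tiger(spec, (raster, channels))

    def test_fix_schedule_and_dropout(self, simulated_tiger):
        spec, traj, truth = simulated_tiger
        n_sched = int(spec.duration_days * 24 / spec.fix_interval_hours) + 1
        assert len(truth.raw_rows) == n_sched
        assert traj.n + traj.metadata["n_failed"] == n_sched
        # dropout close to 1 - fix_success_prob
        rate = traj.n / n_sched
        assert rate == pytest.approx(spec.fix_success_prob, abs=0.05)
        assert traj.times.is_monotonic_increasing

    def test_determinism(self, small_landscape):
        _, raster, channels = small_landscape
        rng = np.random.default_rng(1)
        home = random_land_point(raster, rng, margin_m=1500.0)
        spec = TigerSimSpec(home_center=home, duration_days=5, seed=9)
        t1, tr1 = simulate_tiger(spec, (raster, channels))
        t2, tr2 = simulate_tiger(spec, (raster, channels))
        assert np.array_equal(t1.xy, t2.xy)
        assert tr1.occupancy.equals(tr2.occupancy)

    def test_truth_occupancy_sums_to_one(self, simulated_tiger):
        _, _, truth = simulated_tiger
        assert truth.occupancy.sum() == pytest.approx(1.0, abs=1e-9)

    def test_near_zero_halfwidth_means_no_crossings(self, small_landscape):
        _, raster, channels = small_landscape
        rng = np.random.default_rng(2)
        home = random_land_point(raster, rng, margin_m=1500.0)
        spec = TigerSimSpec(
            home_center=home, crossing_halfwidth=1e-9, attraction_strength=0.0,
            turning_concentration=0.0, step_scale=450.0, duration_days=20,
            activity_profile=FLAT, habitat_weights=dict(UNIFORM), seed=3,
        )
        _, truth = simulate_tiger(spec, (raster, channels))
        assert truth.crossings["count"].sum() == 0

    def test_truth_crossings_match_geometry_oracle(self, small_landscape):
        """Realized crossings equal segment-channel intersections of the path."""
        _, raster, channels = small_landscape
        rng = np.random.default_rng(4)
        home = random_land_point(raster, rng, margin_m=2000.0)
        spec = TigerSimSpec(home_center=home, duration_days=15,
                            fix_success_prob=1.0, seed=8)
        traj, truth = simulate_tiger(spec, (raster, channels))
        detected = detect_crossings(("p", truth.positions), channels)
        per_channel = {c.id: 0 for c in channels}
        for r in detected:
            per_channel[r.channel_id] += 1
        truth_counts = dict(zip(truth.crossings["channel_id"], truth.crossings["count"]))
        assert per_channel == truth_counts

    def test_uniform_weights_occupancy_matches_availability(self):
        """With no preference the walk samples the landscape like a census.

        Monte-Carlo check at 400 days; the tolerance allows for the strong
        autocorrelation of a random walk (effective sample far below the
        step count).
        """
        raster, channels = generate_landscape(
            LandscapeSpec(extent=(0, 0, 10_000, 10_000), channel_count=3,
                          width_range=(30, 300), seed=21)
        )
        rng = np.random.default_rng(3)
        home = random_land_point(raster, rng, margin_m=1500.0)
        spec = TigerSimSpec(
            home_center=home, attraction_strength=0.0, turning_concentration=0.0,
            habitat_weights=dict(UNIFORM), activity_profile=FLAT,
            step_scale=600.0, crossing_halfwidth=math.inf,
            fix_interval_hours=2.0, duration_days=400, seed=17,
        )
        _, truth = simulate_tiger(spec, (raster, channels))
        avail = raster.class_fractions()
        for name in ALL_CLASSES:
            assert truth.occupancy[name] == pytest.approx(avail[name], abs=0.06)

    def test_default_world_walks_about_4p6_km_per_day(self):
        """The default parameters emulate ~4.6 km/day over 200 days."""
        from mangrovemove.experiments import default_daily_distance

        res = default_daily_distance(seed=1, days=200)
        assert res["mean_daily_km"] == pytest.approx(4.6, abs=0.4)


class TestHalfwidthDecay:
    def test_crossing_decay_recovers_halfwidth_scale(self):
        """Crossing frequency vs width decays; the fitted half-width is on
        the right scale (within a factor of two of the planted 300 m)."""
        from mangrovemove.experiments import halfwidth_recovery

        res = halfwidth_recovery(seed=1, days=400)
        est = res["estimated_halfwidth"]
        assert math.isfinite(est)
        assert 150.0 <= est <= 600.0


def test_synthetic_syzygy_table_spacing():
    t = synthetic_syzygy_table("2010-01-01", n_cycles=10)
    gaps = np.diff([d.toordinal() for d in t["date"]])
    assert set(gaps) <= {14, 15}
    assert list(t["phase"][:2]) == ["new", "full"]
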