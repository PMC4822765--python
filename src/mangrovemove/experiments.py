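"""Reproducible simulation studies on the synthetic world.

Each function builds a fully specified world (landscape + movement
parameters), runs the estimation machinery on it, and reports how well the
known truth is recovered: type-I error and power of the channel-crossing
chi-square test, recovery of the planted habitat-preference ranking by
compositional analysis, day-effect detection by the movement model, and
recovery of the crossing half-width from the fitted width decay.

All randomness flows from a single integer seed via spawned substreams, so
every study is exactly reproducible.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from . import channel_crossings as cc
from . import habitat_selection as hs
from . import home_range as hr
from . import movement_metrics as mm
from . import synthdata as sd
from . import telemetry_io as tio
from .raster import WATER

#: Planted preference order of the default habitat weights (most to least).
PLANTED_ORDER = ["AvicenniaSonneratia", "Phoenix", "Ceriops", "Barren", "Water"]

#: Near-zero weight for Water in null-model worlds: the tiger never rests in
#: open water, matching the null trajectories' land-only node constraint.
_NO_WATER = {"AvicenniaSonneratia": 1.0, "Phoenix": 1.0, "Ceriops": 1.0,
             "Barren": 1.0, "Water": 1e-9}

_FLAT = tuple([1.0] * 24)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Channel-crossing chi-square: calibration and power
# ---------------------------------------------------------------------------

def crossing_replicate(
    seed: int,
    days: int = 60,
    crossing_halfwidth: float = math.inf,
    n_null: int = 5,
    extent_m: float = 16_000.0,
    channel_count: int = 30,
    width_range: tuple[float, float] = (30.0, 500.0),
    class_fractions: dict | None = None,
    step_scale: float = 450.0,
    n_tigers: int = 3,
    observed_source: str = "tiger",
) -> dict:
    """One replicate of the barrier test on a null-consistent random walk.

    The world is an isotropic random walk on land (uniform land weights,
    no home attraction, flat activity, complete 2-h fix schedule), so the
    observed paths satisfy the availability model's assumptions except for
    the crossing reluctance set by ``crossing_halfwidth``.

    ``observed_source='tiger'`` scores the daily paths of the simulated
    tiger (the end-to-end design); ``'null'`` replaces each day's observed
    path by one extra draw from the null generator itself, making observed
    and availability exchangeable by construction — this isolates the
    chi-square machinery from movement-model/null-model mismatch.
    """
    if class_fractions is None:
        # channel-dominated waterscape, dense enough that a resident crosses
        # roughly five channels per day as mangrove tigers are observed to
        class_fractions = {"Water": 0.35, "Phoenix": 0.37, "Ceriops": 0.14,
                           "Barren": 0.07, "AvicenniaSonneratia": 0.07}
    s1, s2, *s_t = _sub_seeds(seed, 2 + n_tigers)
    land_spec = sd.LandscapeSpec(
        extent=(0, 0, extent_m, extent_m),
        channel_count=channel_count,
        width_range=width_range,
        class_fractions=class_fractions,
        min_gap_m=100.0,
        seed=int(s1),
    )
    raster, channels = sd.generate_landscape(land_spec)
    rng = np.random.default_rng(int(s2))
    days_list: list[tio.DailyPath] = []
    for i, st in enumerate(s_t):
        home = sd.random_land_point(raster, rng, margin_m=2_000.0)
        spec = sd.TigerSimSpec(
            home_center=home,
            attraction_strength=0.0,
            step_scale=step_scale,
            turning_concentration=0.0,
            habitat_weights=dict(_NO_WATER),
            crossing_halfwidth=crossing_halfwidth,
            activity_profile=_FLAT,
            fix_interval_hours=2.0,
            fix_success_prob=1.0,
            duration_days=days,
            animal_id=f"T{i:02d}",
            seed=int(st),
        )
        traj, _ = sd.simulate_tiger(spec, (raster, channels))
        days_list.extend(d for d in tio.assemble_daily_paths(traj) if d.usable)
    # study-area polygon = the full landscape: the simulated walks are
    # bounded by the extent (not by their own fix hull), and the nulls must
    # share their constraints for the availability sample to be unbiased
    from shapely.geometry import box as _box

    polygon = _box(*raster.extent)
    obs: list[cc.CrossingRecord] = []
    avail: list[cc.CrossingRecord] = []
    null_rng = np.random.default_rng(int(s2) + 1)
    n_extra = 1 if observed_source == "null" else 0
    for dp in days_list:
        paths = cc.generate_null_paths(
            dp, n=n_null + n_extra, polygon=polygon, landscape=raster,
            seed=null_rng, max_attempts=400_000, on_exhaust="skip",
        )
        if len(paths) < n_null + n_extra:
            continue  # drop the day entirely: availability must stay matched
        if observed_source == "null":
            obs.extend(cc.detect_crossings((dp.path_id, paths[0]), channels))
            paths = paths[1:]
        else:
            obs.extend(cc.detect_crossings(dp, channels))
        for j, p in enumerate(paths):
            avail.extend(
                cc.detect_crossings((f"{dp.path_id}#null{j}", p), channels, source="null")
            )
    table = cc.crossing_chisq(cc.bin_crossings(obs, avail))
    return {
        "chi_square": table.chi_square,
        "df": table.df,
        "p_value": table.p_value,
        "n_observed": len(obs),
        "n_available": len(avail),
        "n_days": len(days_list),
        "table": table,
    }


def crossing_calibration(
    n_reps: int = 100,
    seed: int = 0,
    crossing_halfwidth: float = math.inf,
    days: int = 60,
    alpha: float = 0.05,
    observed_source: str = "tiger",
    **replicate_kwargs,
) -> dict:
    """Rejection rate of the barrier chi-square over simulated replicates.

    With ``crossing_halfwidth=inf`` (no reluctance) this measures the test's
    type-I error; with a finite half-width it measures power.
    """
    seeds = _sub_seeds(seed, n_reps)
    pvals = []
    for s in seeds:
        res = crossing_replicate(int(s), days=days,
                                 crossing_halfwidth=crossing_halfwidth,
                                 observed_source=observed_source,
                                 **replicate_kwargs)
        pvals.append(res["p_value"])
    pvals = np.asarray(pvals)
    return {
        "n_reps": n_reps,
        "rejection_rate": float(np.mean(pvals < alpha)),
        "p_values": pvals,
    }


# ---------------------------------------------------------------------------
# Compositional-analysis preference recovery
# ---------------------------------------------------------------------------

def preference_replicate(
    seed: int,
    n_animals: int = 6,
    days: int = 30,
    hr_level: float = 95.0,
    h: float = 1000.0,
    extent_m: float = 16_000.0,
) -> dict:
    """Simulate ranked-preference tigers and rank habitats compositionally."""
    s_land, *s_tigers = _sub_seeds(seed, n_animals + 1)
    land_spec = sd.LandscapeSpec(
        extent=(0, 0, extent_m, extent_m), channel_count=4, seed=int(s_land)
    )
    raster, channels = sd.generate_landscape(land_spec)
    samples = []
    for i, s in enumerate(s_tigers):
        rng = np.random.default_rng(int(s))
        home = sd.random_land_point(raster, rng, margin_m=3_000.0)
        spec = sd.TigerSimSpec(
            home_center=home,
            attraction_strength=0.6,
            habitat_weights=dict(sd.DEFAULT_HABITAT_WEIGHTS),
            duration_days=days,
            fix_interval_hours=1.0,
            animal_id=f"T{i:02d}",
            seed=int(s) + 1,
        )
        traj, _ = sd.simulate_tiger(spec, (raster, channels))
        ud = hr.compute_fixed_kernel_ud(traj.xy, h=h, grid_like=raster)
        mask = hr.isopleth_mask(ud, hr_level)
        use = hs.habitat_use(traj.xy, raster)
        avail = hs.habitat_availability(mask, raster)
        samples.append(hs.HabitatUseAvail(spec.animal_id, use, avail))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = hs.compositional_analysis(samples)
    return {
        "ranking": result.ranking,
        "recovered": result.ranking == PLANTED_ORDER,
        "chi_square": result.chi_square,
        "df": result.df,
        "p_value": result.p_value,
    }


def preference_recovery(n_reps: int = 100, seed: int = 0, **kwargs) -> dict:
    """Fraction of replicates whose compositional ranking equals the truth."""
    seeds = _sub_seeds(seed, n_reps)
    hits = 0
    dfs = []
    for s in seeds:
        res = preference_replicate(int(s), **kwargs)
        hits += bool(res["recovered"])
        dfs.append(res["df"])
    return {"n_reps": n_reps, "n_recovered": hits, "recovery_rate": hits / n_reps,
            "dfs": dfs}


# ---------------------------------------------------------------------------
# Movement-model calibration and power
# ---------------------------------------------------------------------------

def movement_model_replicate(
    seed: int,
    day_multiplier: float = 1.0,
    n_animals: int = 3,
    days: int = 40,
    extent_m: float = 16_000.0,
) -> dict:
    """Fit the day/tide mixed model to tigers with a known day effect.

    ``day_multiplier`` scales step lengths in local hours [6, 18); 1 means
    no day/night difference (and the world has no tide effect either).
    """
    s_land, *s_tigers = _sub_seeds(seed, n_animals + 1)
    land_spec = sd.LandscapeSpec(
        extent=(0, 0, extent_m, extent_m), channel_count=4, seed=int(s_land)
    )
    raster, channels = sd.generate_landscape(land_spec)
    profile = np.ones(24)
    profile[6:18] *= day_multiplier
    trajs = []
    for i, s in enumerate(s_tigers):
        rng = np.random.default_rng(int(s))
        home = sd.random_land_point(raster, rng, margin_m=2_000.0)
        spec = sd.TigerSimSpec(
            home_center=home,
            attraction_strength=0.5,
            habitat_weights=dict(_NO_WATER),
            activity_profile=tuple(profile),
            fix_interval_hours=2.0,
            fix_success_prob=1.0,
            duration_days=days,
            animal_id=f"T{i:02d}",
            seed=int(s) + 1,
        )
        traj, _ = sd.simulate_tiger(spec, (raster, channels))
        trajs.append(traj)
    start = trajs[0].times[0] - pd.Timedelta(days=20)
    syz = sd.synthetic_syzygy_table(start.date().isoformat(), n_cycles=2 + int(days // 14) + 3)
    table = mm.movement_table(trajs, syz)
    res = mm.fit_movement_model(table)
    return {
        "t_day": res.tvalues.get("is_day", float("nan")),
        "t_tide": res.tvalues.get("is_spring", float("nan")),
        "n_rows": res.n_rows,
    }


def movement_model_calibration(
    n_reps: int = 20, seed: int = 0, day_multiplier: float = 1.0
) -> dict:
    """|t| > 2 rates for the day and tide effects over replicates."""
    seeds = _sub_seeds(seed, n_reps)
    t_day, t_tide = [], []
    for s in seeds:
        res = movement_model_replicate(int(s), day_multiplier=day_multiplier)
        t_day.append(res["t_day"])
        t_tide.append(res["t_tide"])
    t_day, t_tide = np.asarray(t_day), np.asarray(t_tide)
    return {
        "n_reps": n_reps,
        "reject_day": float(np.mean(np.abs(t_day) > 2)),
        "reject_tide": float(np.mean(np.abs(t_tide) > 2)),
        "detect_day_positive": float(np.mean(t_day > 2)),
        "t_day": t_day,
        "t_tide": t_tide,
    }


# ---------------------------------------------------------------------------
# Crossing half-width recovery
# ---------------------------------------------------------------------------

def halfwidth_recovery(
    seed: int = 0,
    days: int = 500,
    true_halfwidth: float = 300.0,
    n_tigers: int = 3,
    extent_m: float = 16_000.0,
) -> dict:
    """Recover the crossing half-width from the observed/available decay.

    The crossing acceptance model is 2**(-w/halfwidth); regressing
    ln(observed_i / available_i) on bin-center width therefore has slope
    -ln(2)/halfwidth.  ``days`` simulated tracking days are split across
    ``n_tigers`` animals in the dense-channel world of
    :func:`crossing_replicate`; the fit weights bins by the inverse
    variance of the log count ratio (1/obs + 1/avail).
    """
    class_fractions = {"Water": 0.30, "Phoenix": 0.40, "Ceriops": 0.15,
                       "Barren": 0.08, "AvicenniaSonneratia": 0.07}
    s1, s2, *s_t = _sub_seeds(seed, 2 + n_tigers)
    land_spec = sd.LandscapeSpec(
        extent=(0, 0, extent_m, extent_m),
        class_fractions=class_fractions,
        channel_count=22,
        width_range=(30.0, 500.0),
        seed=int(s1),
    )
    raster, channels = sd.generate_landscape(land_spec)
    rng = np.random.default_rng(int(s2))
    days_list: list[tio.DailyPath] = []
    for i, st in enumerate(s_t):
        home = sd.random_land_point(raster, rng, margin_m=2_000.0)
        spec = sd.TigerSimSpec(
            home_center=home,
            attraction_strength=0.0,
            step_scale=450.0,
            turning_concentration=0.0,
            habitat_weights=dict(_NO_WATER),
            crossing_halfwidth=true_halfwidth,
            activity_profile=_FLAT,
            fix_interval_hours=2.0,
            fix_success_prob=1.0,
            duration_days=days // n_tigers,
            animal_id=f"T{i:02d}",
            seed=int(st),
        )
        traj, _ = sd.simulate_tiger(spec, (raster, channels))
        days_list.extend(d for d in tio.assemble_daily_paths(traj) if d.usable)
    from shapely.geometry import box as _box

    polygon = _box(*raster.extent)
    obs: list[cc.CrossingRecord] = []
    avail: list[cc.CrossingRecord] = []
    null_rng = np.random.default_rng(int(s2) + 1)
    for dp in days_list:
        obs.extend(cc.detect_crossings(dp, channels))
        for j, p in enumerate(
            cc.generate_null_paths(dp, n=5, polygon=polygon, landscape=raster,
                                   seed=null_rng, max_attempts=400_000,
                                   on_exhaust="skip")
        ):
            avail.extend(
                cc.detect_crossings((f"{dp.path_id}#null{j}", p), channels, source="null")
            )
    table = cc.bin_crossings(obs, avail)
    centers = 0.5 * (table.edges[:-1] + table.edges[1:])
    ok = (table.availability >= 5) & (table.observed > 0)
    if ok.sum() < 3:
        raise RuntimeError("halfwidth_recovery: too few populated width bins to fit")
    y = np.log(table.observed[ok] / table.availability[ok])
    w = 1.0 / (1.0 / table.observed[ok] + 1.0 / table.availability[ok])
    slope, _ = np.polyfit(centers[ok], y, 1, w=np.sqrt(w))
    est = -math.log(2.0) / slope if slope < 0 else math.inf
    return {
        "true_halfwidth": true_halfwidth,
        "estimated_halfwidth": float(est),
        "n_bins_fit": int(ok.sum()),
        "n_observed": len(obs),
        "n_available": len(avail),
    }


# ---------------------------------------------------------------------------
# Default-world daily distance
# ---------------------------------------------------------------------------

def default_daily_distance(seed: int = 0, days: int = 200) -> dict:
    """Mean realized daily travel distance of the default tiger world (km)."""
    s1, s2, s3 = _sub_seeds(seed, 3)
    raster, channels = sd.generate_landscape(sd.LandscapeSpec(seed=int(s1)))
    rng = np.random.default_rng(int(s2))
    home = sd.random_land_point(raster, rng, margin_m=3_000.0)
    spec = sd.TigerSimSpec(home_center=home, duration_days=days, seed=int(s3))
    _, truth = sd.simulate_tiger(spec, (raster, channels))
    # drop edge days (partial local days at the simulation boundaries)
    full = truth.daily_distance_km.iloc[1:-1] if len(truth.daily_distance_km) > 2 \
        else truth.daily_distance_km
    return {
        "mean_daily_km": float(full.mean()),
        "sd_daily_km": float(full.std(ddof=1)),
        "n_days": int(len(full)),
    }
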