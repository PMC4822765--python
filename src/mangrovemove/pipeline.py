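"""End-to-end orchestration: simulate -> validate -> home range -> movement
-> crossings -> habitat -> density, as one configured, seeded, logged run.

The configuration is a plain mapping (YAML-loadable) with one block per
stage; a single global seed spawns an independent substream for every
stochastic stage, so stages are individually reproducible.  Each stage
writes its outputs before the next starts; a stage failure halts the run
with the stage name and cause, retaining partial outputs.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import channel_crossings as cc
from . import habitat_selection as hs
from . import home_range as hr
from . import movement_metrics as mm
from . import synthdata as sd
from . import telemetry_io as tio
from .raster import ALL_CLASSES

log = logging.getLogger("mangrovemove")

REQUIRED_BLOCKS = ["landscape", "simulate", "homerange", "movement",
                   "crossings", "habitat", "output"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "landscape": {
        "extent_m": 20_000.0,
        "cell_size": 50.0,
        "channel_count": 6,
        "width_min": 30.0,
        "width_max": 2500.0,
    },
    "simulate": {
        "n_females": 3,
        "n_males": 3,
        "duration_days": 60,
        "fix_interval_hours": 1.0,
        "fix_success_prob": 0.666,
        "female_attraction": 0.8,
        "male_attraction": 0.45,
    },
    "homerange": {
        "h": 1000.0,
        "mcp_percent": 95.0,
        "fk_level": 95.0,
        "mask_water_gt_m": 1000.0,
        "fallback_core_level": 75.0,
    },
    "movement": {"min_fixes": 12, "utc_offset_hours": tio.DEFAULT_UTC_OFFSET_HOURS},
    "crossings": {"null_per_path": 5, "max_attempts": 60_000, "min_expected": 1.0},
    "habitat": {"hr_level": 95.0, "zero_sub": 0.01, "reference": "Water"},
    "output": {"dir": "mangrovemove_out"},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        import yaml

        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = copy.deepcopy(path_or_dict)
    missing = [b for b in REQUIRED_BLOCKS if b not in cfg]
    if missing:
        raise ValueError(f"config missing required block(s): {missing}")
    if "seed" not in cfg:
        raise ValueError("config missing required key 'seed'")
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config) -> dict:
    """Run all stages and return (and write) the aggregated report."""
    cfg = load_config(config)
    out = Path(cfg["output"]["dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    streams = np.random.SeedSequence(seed).generate_state(8) % (2**31 - 1)
    report: dict = {"config": _jsonable(cfg), "seed": seed}

    stage = "simulate"
    try:
        lc = cfg["landscape"]
        land_spec = sd.LandscapeSpec(
            extent=(0.0, 0.0, float(lc["extent_m"]), float(lc["extent_m"])),
            cell_size=float(lc["cell_size"]),
            channel_count=int(lc["channel_count"]),
            width_range=(float(lc["width_min"]), float(lc["width_max"])),
            seed=int(streams[0]),
        )
        raster, channels = sd.generate_landscape(land_spec)
        raster.write_ascii(out / "habitat.asc")
        cc.write_channels_geojson(channels, out / "channels.geojson")

        sim = cfg["simulate"]
        rng = np.random.default_rng(int(streams[1]))
        sexes = (["F"] * int(sim["n_females"])) + (["M"] * int(sim["n_males"]))
        trajs, truths, sex_of = [], [], {}
        raw_frames = []
        for i, sex in enumerate(sexes):
            home = sd.random_land_point(raster, rng, margin_m=2_500.0)
            spec = sd.TigerSimSpec(
                home_center=home,
                attraction_strength=float(
                    sim["female_attraction"] if sex == "F" else sim["male_attraction"]
                ),
                duration_days=int(sim["duration_days"]),
                fix_interval_hours=float(sim["fix_interval_hours"]),
                fix_success_prob=float(sim["fix_success_prob"]),
                animal_id=f"{sex}{i:02d}",
                seed=int(rng.integers(2**31 - 1)),
            )
            traj, truth = sd.simulate_tiger(spec, (raster, channels))
            trajs.append(traj)
            truths.append(truth)
            sex_of[traj.animal_id] = sex
            raw_frames.append(truth.raw_rows)
        raw = pd.concat(raw_frames, ignore_index=True)
        tio.write_fixes(raw, out / "fixes.csv")
        truth_summary = {
            t.spec.animal_id: {
                "mean_daily_km": float(t.daily_distance_km.mean()),
                "occupancy": _jsonable(t.occupancy),
                "total_crossings": int(t.crossings["count"].sum()),
            }
            for t in truths
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(truth_summary), fh, indent=1)
        report["simulate"] = {
            "n_animals": len(trajs),
            "landscape_fractions": raster.class_fractions(),
        }
        log.info("simulate: %d animals on a %.0f m landscape", len(trajs), lc["extent_m"])

        stage = "validate"
        trajs = tio.read_fixes(out / "fixes.csv")
        acq = tio.acquisition_rate(tio.read_fix_rows(out / "fixes.csv"))
        report["validate"] = {
            "n_animals": len(trajs),
            "acquisition_success": acq.success_rate,
            "mean_fixes_per_day": acq.mean_fixes_per_day,
        }

        stage = "homerange"
        hrc = cfg["homerange"]
        h = float(hrc["h"])
        rows = []
        profiles = []
        geoms = {}
        for traj in trajs:
            ud = hr.compute_fixed_kernel_ud(traj.xy, h=h, grid_like=raster)
            profile = hr.extract_isopleths(ud)
            profiles.append(profile.areas_km2)
            mcp = hr.compute_mcp(traj.xy, percent=float(hrc["mcp_percent"]))
            fk = hr.kernel_home_range(
                traj.xy, level=float(hrc["fk_level"]), h=h, grid_like=raster,
                animal_id=traj.animal_id,
            )
            mcp = hr.mask_water(mcp, channels, float(hrc["mask_water_gt_m"]))
            fk = hr.mask_water(fk, channels, float(hrc["mask_water_gt_m"]))
            geoms[traj.animal_id] = fk.geometry
            rows.append({
                "animal_id": traj.animal_id,
                "sex": sex_of[traj.animal_id],
                "mcp95_km2": mcp.area_km2,
                "fk95_km2": fk.area_km2,
                "profile": profile,
                "ud": ud,
            })
        mean_profile = hr.IsoplethProfile(
            levels=np.arange(5.0, 96.0, 5.0),
            areas_km2=np.mean(np.vstack(profiles), axis=0),
        )
        core_level = hr.detect_core_isopleth(mean_profile)
        if core_level is None:
            core_level = float(hrc["fallback_core_level"])
        for row in rows:
            mask = hr.isopleth_mask(row["ud"], core_level)
            core = hr.HomeRangeResult(
                row["animal_id"], "FK", core_level,
                hr._mask_polygon(row["ud"], mask),
                float(mask.sum()) * row["ud"].cell_area_m2 / hr.M2_PER_KM2,
            )
            core = hr.mask_water(core, channels, float(hrc["mask_water_gt_m"]))
            row["core_km2"] = core.area_km2
        table = pd.DataFrame(
            [{k: r[k] for k in ("animal_id", "sex", "mcp95_km2", "fk95_km2", "core_km2")}
             for r in rows]
        )
        table.to_csv(out / "home_ranges.csv", index=False)
        summ = hr.summarize_home_ranges(
            table, ["mcp95_km2", "fk95_km2", "core_km2"], exclude={}
        )
        summ["summary"].to_csv(out / "home_range_summary.csv", index=False)
        land_km2 = (
            (1.0 - raster.class_fractions()["Water"])
            * (float(lc["extent_m"]) / 1000.0) ** 2
        )

        def _core(sex):
            s = summ["summary"]
            row = s[(s["sex"] == sex) & (s["measure"] == "core_km2")].iloc[0]
            return float(row["mean"]), float(row["se"])

        try:
            dens = hr.estimate_density(land_km2, _core("F"), _core("M"))
            density_block = {
                "land_area_km2": land_km2,
                "n_females": dens.n_females,
                "n_females_range": dens.n_females_range,
                "n_males": dens.n_males,
                "n_males_range": dens.n_males_range,
                "density_per_100km2": dens.density_per_100km2,
                "density_range": dens.density_range,
            }
        except ValueError as err:
            density_block = {"error": str(err)}
        report["homerange"] = {
            "core_isopleth_level": core_level,
            "per_animal": _jsonable(table),
            "summary": _jsonable(summ["summary"]),
            "mean_isopleth_profile": _jsonable(
                dict(zip(mean_profile.levels, mean_profile.areas_km2))
            ),
            "density": _jsonable(density_block),
        }

        stage = "movement"
        mv = cfg["movement"]
        daily = []
        for traj in trajs:
            for dp in tio.assemble_daily_paths(
                traj, int(mv["min_fixes"]), float(mv["utc_offset_hours"])
            ):
                if dp.usable and dp.fix_count >= 2:
                    daily.append(mm.daily_distance(dp))
        daily_df = pd.DataFrame(
            [{"animal_id": d.animal_id, "date": d.date, "distance_km": d.distance_km}
             for d in daily]
        )
        daily_df.to_csv(out / "daily_distance.csv", index=False)
        activity = mm.hourly_activity(trajs, float(mv["utc_offset_hours"]))
        pd.DataFrame({
            "hour": np.arange(24),
            "mean_kmh": activity.mean_kmh,
            "se_kmh": activity.se_kmh,
            "n_steps": activity.n_steps,
        }).to_csv(out / "hourly_activity.csv", index=False)
        _plot_activity(activity, out / "hourly_activity.png")
        t0 = min(t.times[0] for t in trajs) - pd.Timedelta(days=20)
        n_cycles = int(cfg["simulate"]["duration_days"] // 14) + 5
        syz = sd.synthetic_syzygy_table(t0.date().isoformat(), n_cycles=n_cycles)
        mtable = mm.movement_table(
            trajs, syz, int(mv["min_fixes"]), float(mv["utc_offset_hours"])
        )
        model = mm.fit_movement_model(mtable)
        report["movement"] = {
            "n_usable_days": len(daily_df),
            "mean_daily_km_per_day": float(daily_df["distance_km"].mean()),
            "mean_daily_km_per_animal": float(
                daily_df.groupby("animal_id")["distance_km"].mean().mean()
            ),
            "peak_activity_hours": [int(h) for h in activity.peak_hours[:3]],
            "model": {
                "params": model.params,
                "t": model.tvalues,
                "p": model.pvalues,
                "random_intercept_var": model.random_intercept_var,
                "n_rows": model.n_rows,
                "kind": model.model,
            },
        }

        stage = "crossings"
        cr = cfg["crossings"]
        pooled = np.vstack([t.xy for t in trajs])
        polygon = cc.common_polygon(pooled)
        obs_records, null_records = [], []
        n_requested = n_accepted = 0
        null_rng = np.random.default_rng(int(streams[2]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for traj in trajs:
                for dp in tio.assemble_daily_paths(
                    traj, int(mv["min_fixes"]), float(mv["utc_offset_hours"])
                ):
                    if not dp.usable:
                        continue
                    obs_records.extend(cc.detect_crossings(dp, channels))
                    paths = cc.generate_null_paths(
                        dp, n=int(cr["null_per_path"]), polygon=polygon,
                        landscape=raster, seed=null_rng,
                        max_attempts=int(cr["max_attempts"]),
                        on_exhaust="skip",
                    )
                    n_requested += int(cr["null_per_path"])
                    n_accepted += len(paths)
                    for j, p in enumerate(paths):
                        null_records.extend(
                            cc.detect_crossings(
                                (f"{dp.path_id}#null{j}", p), channels, source="null"
                            )
                        )
        chisq_note = None
        try:
            ctable = cc.crossing_chisq(
                cc.bin_crossings(obs_records, null_records),
                min_expected=float(cr["min_expected"]),
            )
        except ValueError as err:
            # too few crossings to test: report the counts, not a statistic
            chisq_note = str(err)
            ctable = cc.WidthBinTable(
                edges=np.array([0.0, 500.0]),
                observed=np.array([float(len(obs_records))]),
                availability=np.array([float(len(null_records))]),
            ) if null_records else None
        if ctable is not None:
            ctable.to_frame().to_csv(out / "crossing_bins.csv", index=False)
        n_days_crossed = len({r.path_id for r in obs_records})
        n_usable = report["movement"]["n_usable_days"]
        report["crossings"] = {
            "chi_square": ctable.chi_square if ctable is not None else None,
            "df": ctable.df if ctable is not None else None,
            "p_value": ctable.p_value if ctable is not None else None,
            "note": chisq_note,
            "n_observed_crossings": len(obs_records),
            "mean_crossings_per_day": (len(obs_records) / n_usable) if n_usable else None,
            "mean_crossed_width_m": float(np.mean([r.width_m for r in obs_records]))
            if obs_records else None,
            "null_paths_requested": n_requested,
            "null_paths_accepted": n_accepted,
        }

        stage = "habitat"
        hb = cfg["habitat"]
        samples = []
        for traj in trajs:
            ud = next(r["ud"] for r in rows if r["animal_id"] == traj.animal_id)
            mask = hr.isopleth_mask(ud, float(hb["hr_level"]))
            samples.append(
                hs.HabitatUseAvail(
                    traj.animal_id,
                    hs.habitat_use(traj.xy, raster),
                    hs.habitat_availability(mask, raster),
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = hs.compositional_analysis(
                samples, zero_sub=float(hb["zero_sub"]), reference=str(hb["reference"])
            )
        ivlev = {s.animal_id: hs.ivlev_index(s).electivity for s in samples}
        ivlev_df = pd.DataFrame(ivlev).T
        ivlev_df.to_csv(out / "ivlev.csv")
        _plot_ivlev(ivlev_df, out / "ivlev.png")
        pd.DataFrame(
            {
                "animal_id": [s.animal_id for s in samples],
                **{f"use_{c}": [s.use[c] for s in samples] for c in ALL_CLASSES},
                **{f"avail_{c}": [s.availability[c] for s in samples] for c in ALL_CLASSES},
            }
        ).to_csv(out / "use_availability.csv", index=False)
        comp.pairwise_t.to_csv(out / "ranking_matrix.csv")
        report["habitat"] = {
            "wilks_lambda": comp.wilks_lambda,
            "chi_square": comp.chi_square,
            "df": comp.df,
            "p_value": comp.p_value,
            "ranking": comp.ranking,
            "ivlev": _jsonable(ivlev_df),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    _write_markdown(report, out / "report.md")
    return report


def _plot_activity(activity, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(np.arange(24), activity.mean_kmh, yerr=activity.se_kmh, color="#33668c")
    ax.set_xlabel("local hour")
    ax.set_ylabel("mean speed (km/h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_ivlev(ivlev_df, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ivlev_df.plot.bar(ax=ax)
    ax.set_ylabel("Ivlev electivity")
    ax.axhline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_markdown(report: dict, path) -> None:
    lines = ["# mangrovemove run report", ""]
    hrb = report.get("homerange", {})
    mv = report.get("movement", {})
    crs = report.get("crossings", {})
    hb = report.get("habitat", {})
    lines += [
        f"- seed: {report['seed']}",
        f"- animals: {report.get('simulate', {}).get('n_animals')}",
        f"- fix acquisition success: {report.get('validate', {}).get('acquisition_success'):.3f}",
        f"- core isopleth level: {hrb.get('core_isopleth_level')}%",
        f"- density per 100 km2: {hrb.get('density', {}).get('density_per_100km2')}",
        f"- mean daily distance (per day): {mv.get('mean_daily_km_per_day'):.2f} km",
        (
            f"- crossing test: chi2={crs['chi_square']:.2f}, df={crs['df']}, "
            f"p={crs['p_value']:.2g}"
            if crs.get("chi_square") is not None
            else f"- crossing test: not computable ({crs.get('note')})"
        ),
        f"- habitat ranking: {' > '.join(hb.get('ranking', []))}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
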