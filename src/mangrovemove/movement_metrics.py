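"""Daily travel distance, hourly activity, and the day/tide movement model.

Daily travel distance is the summed Euclidean length of consecutive-fix
steps within a usable (>= 12-fix) local calendar day.  The activity clock
assigns each step's speed (km/h) to the local hour of the step start.  Days
are split day/night at 06:00/18:00 local, and dates are classed spring/neap
from a syzygy (new/full moon) calendar: the 8-day window [syzygy-3,
syzygy+4] is spring tide, the remainder neap.  The movement model regresses
log half-day distance on daytime and tide phase with a random intercept per
animal.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .telemetry_io import DEFAULT_UTC_OFFSET_HOURS, DailyPath, Trajectory

#: Steps faster than this are flagged (never dropped); collared tigers were
#: recorded in bursts above 5 km/h, so the default flag sits well above that.
DEFAULT_MAX_SPEED_KMH = 10.0


@dataclass
class MovementDay:
    animal_id: str
    date: _dt.date
    distance_km: float
    tide_phase: str | None = None      # 'spring' | 'neap'
    usable: bool = True

    def __post_init__(self) -> None:
        if self.distance_km < 0:
            raise ValueError("distance_km must be >= 0")


@dataclass
class ActivityProfile:
    """Mean speed (km/h) by local hour with SEs and step counts."""

    mean_kmh: np.ndarray
    se_kmh: np.ndarray
    n_steps: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.mean_kmh, self.se_kmh, self.n_steps):
            if len(arr) != 24:
                raise ValueError("activity profile arrays must have 24 entries")

    @property
    def peak_hours(self) -> np.ndarray:
        return np.argsort(self.mean_kmh)[::-1]


@dataclass
class MovementModelResult:
    params: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float | None
    n_rows: int
    model: str                        # 'mixed' or 'ols'


# ---------------------------------------------------------------------------
# Distances and activity
# ---------------------------------------------------------------------------

def daily_distance(day: DailyPath) -> MovementDay:
    """Total distance travelled in one day: summed consecutive-fix steps, km."""
    if day.fix_count < 2:
        raise ValueError(f"daily_distance: day {day.path_id} has fewer than 2 fixes")
    d = float(np.hypot(*np.diff(day.xy, axis=0).T).sum()) / 1000.0
    return MovementDay(
        animal_id=day.animal_id,
        date=day.date,
        distance_km=d,
        usable=day.usable,
    )


def steps_frame(
    traj: Trajectory,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
    max_speed_kmh: float = DEFAULT_MAX_SPEED_KMH,
) -> pd.DataFrame:
    """Per-step table: distance, duration, speed, local clock fields.

    Steps exceeding ``max_speed_kmh`` are flagged in ``speed_flag`` but kept.
    """
    if traj.n < 2:
        return pd.DataFrame(
            columns=["animal_id", "t0", "dt_h", "dist_km", "speed_kmh",
                     "hour_local", "date_local", "daytime", "speed_flag"]
        )
    xy = traj.xy
    dist = np.hypot(*np.diff(xy, axis=0).T) / 1000.0
    dt_h = np.diff(traj.times.asi8) / 3.6e12
    local = traj.local_times(utc_offset_hours)[:-1]
    speed = dist / dt_h
    df = pd.DataFrame(
        {
            "animal_id": traj.animal_id,
            "t0": traj.times[:-1],
            "dt_h": dt_h,
            "dist_km": dist,
            "speed_kmh": speed,
            "hour_local": local.hour,
            "date_local": local.date,
            "daytime": np.where((local.hour >= 6) & (local.hour < 18), "day", "night"),
            "speed_flag": speed > max_speed_kmh,
        }
    )
    return df


def hourly_activity(
    trajectories: list[Trajectory],
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> ActivityProfile:
    """Mean movement speed per local hour pooled over all steps."""
    frames = [steps_frame(t, utc_offset_hours) for t in trajectories]
    steps = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    mean = np.zeros(24)
    se = np.zeros(24)
    n = np.zeros(24, dtype=int)
    if len(steps):
        for hr, grp in steps.groupby("hour_local"):
            v = grp["speed_kmh"].to_numpy()
            n[hr] = len(v)
            mean[hr] = v.mean()
            se[hr] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return ActivityProfile(mean_kmh=mean, se_kmh=se, n_steps=n)


# ---------------------------------------------------------------------------
# Clock and calendar classification
# ---------------------------------------------------------------------------

def classify_daynight(
    timestamp,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> str:
    """'day' for local [06:00, 18:00), else 'night'."""
    t = pd.Timestamp(timestamp)
    if t.tz is None:
        t = t.tz_localize("UTC")
    hour = (t + pd.Timedelta(hours=utc_offset_hours)).hour
    return "day" if 6 <= hour < 18 else "night"


def classify_tide(date, syzygy_table: pd.DataFrame) -> str:
    """'spring' within the 8-day window [syzygy-3, syzygy+4], else 'neap'.

    ``syzygy_table`` needs a ``date`` column of new/full-moon dates.  A date
    farther than half a synodic month (15 days) from every listed syzygy is
    outside the table's coverage and raises.
    """
    d = pd.Timestamp(date).date()
    syz = pd.to_datetime(syzygy_table["date"]).dt.date
    deltas = np.array([(d - s).days for s in syz])
    if np.abs(deltas).min() > 15:
        raise ValueError(f"classify_tide: date {d} not covered by the syzygy table")
    return "spring" if np.any((deltas >= -3) & (deltas <= 4)) else "neap"


# ---------------------------------------------------------------------------
# The mixed movement model
# ---------------------------------------------------------------------------

def movement_table(
    trajectories: list[Trajectory],
    syzygy_table: pd.DataFrame,
    min_fixes: int = 12,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> pd.DataFrame:
    """Half-day movement rows for the mixed model.

    Only local days with >= ``min_fixes`` fixes contribute.  Each usable day
    yields one 'day' and one 'night' row with the summed step distance of
    steps starting in that half, plus the date's tide phase.
    """
    from .telemetry_io import assemble_daily_paths

    rows = []
    for traj in trajectories:
        steps = steps_frame(traj, utc_offset_hours)
        usable_dates = {
            dp.date for dp in assemble_daily_paths(traj, min_fixes, utc_offset_hours)
            if dp.usable
        }
        if not len(steps):
            continue
        for (date, half), grp in steps.groupby(["date_local", "daytime"]):
            if date not in usable_dates:
                continue
            rows.append(
                {
                    "animal_id": traj.animal_id,
                    "date": date,
                    "daytime": half,
                    "tide": classify_tide(date, syzygy_table),
                    "distance_km": float(grp["dist_km"].sum()),
                }
            )
    return pd.DataFrame(rows)


def fit_movement_model(table: pd.DataFrame) -> MovementModelResult:
    """Mixed model: log distance ~ daytime + tide, random intercept per animal.

    Zero distances are replaced by half the minimum positive distance before
    the log transform.  With a single animal the random intercept is
    unidentifiable and the fit falls back to ordinary least squares with a
    warning.
    """
    import statsmodels.api as sm

    required = {"animal_id", "distance_km", "daytime", "tide"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fit_movement_model: missing columns {sorted(missing)}")
    df = table.copy()
    if len(df) < 10:
        raise ValueError("fit_movement_model: need >= 10 usable rows")
    pos = df["distance_km"] > 0
    if not pos.any():
        raise ValueError("fit_movement_model: all distances are zero")
    floor = df.loc[pos, "distance_km"].min() / 2.0
    df.loc[~pos, "distance_km"] = floor
    df["log_dist"] = np.log(df["distance_km"])
    df["is_day"] = (df["daytime"] == "day").astype(float)
    df["is_spring"] = (df["tide"] == "spring").astype(float)
    exog = sm.add_constant(df[["is_day", "is_spring"]])
    # drop constant columns (e.g. all-spring fixture) to keep the fit sane
    keep = [c for c in exog.columns if c == "const" or exog[c].nunique() > 1]
    exog = exog[keep]

    n_animals = df["animal_id"].nunique()
    if n_animals < 2:
        warnings.warn("fit_movement_model: single animal; falling back to OLS")
        res = sm.OLS(df["log_dist"], exog).fit()
        return MovementModelResult(
            params=dict(res.params),
            tvalues=dict(res.tvalues),
            pvalues=dict(res.pvalues),
            random_intercept_var=None,
            n_rows=len(df),
            model="ols",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(df["log_dist"], exog, groups=df["animal_id"])
        res = md.fit(reml=True)
    fe = list(exog.columns)
    return MovementModelResult(
        params={k: float(res.params[k]) for k in fe},
        tvalues={k: float(res.tvalues[k]) for k in fe},
        pvalues={k: float(res.pvalues[k]) for k in fe},
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        n_rows=len(df),
        model="mixed",
    )
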