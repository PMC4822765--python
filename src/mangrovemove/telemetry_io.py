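"""Reading, writing and validating GPS telemetry fix tables.

Fix CSV layout (one row per *scheduled* fix attempt)::

    animal_id, timestamp, x_m, y_m, status

``timestamp`` is ISO-8601 (UTC); ``x_m``/``y_m`` are projected coordinates in
meters; ``status`` is ``valid`` or ``failed``.  Failed attempts carry empty
coordinates and are excluded from trajectories but counted in acquisition
statistics.

Local civil time (used for day boundaries, the day/night split and the hourly
activity clock) is UTC plus a configurable offset, +05:30 by default.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default local-time offset from UTC in hours (+05:30).
DEFAULT_UTC_OFFSET_HOURS = 5.5

REQUIRED_COLUMNS = ["animal_id", "timestamp", "x_m", "y_m", "status"]
VALID_STATUS = {"valid", "failed"}


@dataclass
class Fix:
    """A single valid GPS location."""

    animal_id: str
    timestamp: pd.Timestamp
    x: float
    y: float
    status: str = "valid"


@dataclass
class Trajectory:
    """Time-ordered valid fixes for one animal.

    ``times`` is a tz-aware (UTC) DatetimeIndex, strictly increasing;
    ``xy`` is the matching ``(n, 2)`` coordinate array in meters.
    ``metadata`` carries free-form keys (sex, n_attempted, n_failed,
    transient / short_deployment flags, ...).
    """

    animal_id: str
    times: pd.DatetimeIndex
    xy: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.times = pd.DatetimeIndex(self.times)
        if self.times.tz is None:
            self.times = self.times.tz_localize("UTC")
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times.asi8)
            if (dt <= 0).any():
                raise ValueError(
                    f"trajectory {self.animal_id}: timestamps not strictly increasing"
                )
        if not np.all(np.isfinite(self.xy)):
            raise ValueError(f"trajectory {self.animal_id}: non-finite coordinate")

    @property
    def n(self) -> int:
        return len(self.times)

    def local_times(self, utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS) -> pd.DatetimeIndex:
        return self.times + pd.Timedelta(hours=utc_offset_hours)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": self.times,
                "x_m": self.xy[:, 0],
                "y_m": self.xy[:, 1],
                "status": "valid",
            }
        )


@dataclass
class DailyPath:
    """Valid fixes of one animal within one local calendar day."""

    animal_id: str
    date: _dt.date
    times: pd.DatetimeIndex
    xy: np.ndarray
    min_fixes: int = 12

    @property
    def fix_count(self) -> int:
        return len(self.times)

    @property
    def usable(self) -> bool:
        return self.fix_count >= self.min_fixes

    @property
    def path_id(self) -> str:
        return f"{self.animal_id}:{self.date.isoformat()}"


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _parse_fix_frame(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    df = df.copy()
    if pd.api.types.is_datetime64_any_dtype(df["timestamp"]):
        ts = pd.to_datetime(df["timestamp"], utc=True)
    else:
        ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(f"{source}: unparseable timestamp at row {row}: "
                         f"{df['timestamp'].iloc[row]!r}")
    df["timestamp"] = ts
    bad_status = ~df["status"].isin(VALID_STATUS)
    if bad_status.any():
        row = int(np.flatnonzero(bad_status.to_numpy())[0])
        raise ValueError(f"{source}: unknown status at row {row}: {df['status'].iloc[row]!r}")
    valid = df["status"] == "valid"
    coords = df.loc[valid, ["x_m", "y_m"]].apply(pd.to_numeric, errors="coerce")
    nonfinite = ~np.isfinite(coords.to_numpy(dtype=float)).all(axis=1)
    if nonfinite.any():
        row = int(coords.index[np.flatnonzero(nonfinite)[0]])
        raise ValueError(f"{source}: non-finite coordinate for valid fix at row {row}")
    df.loc[valid, ["x_m", "y_m"]] = coords
    return df


def trajectories_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[Trajectory]:
    """Build one time-sorted :class:`Trajectory` per animal from raw rows."""
    df = _parse_fix_frame(df, source)
    out: list[Trajectory] = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        valid = grp[grp["status"] == "valid"].sort_values("timestamp", kind="stable")
        dup = valid["timestamp"].duplicated()
        if dup.any():
            t = valid["timestamp"][dup].iloc[0]
            raise ValueError(
                f"{source}: duplicate timestamp {t} for animal {animal_id}"
            )
        out.append(
            Trajectory(
                animal_id=str(animal_id),
                times=pd.DatetimeIndex(valid["timestamp"]),
                xy=valid[["x_m", "y_m"]].to_numpy(dtype=float),
                metadata={
                    "n_attempted": int(len(grp)),
                    "n_failed": int((grp["status"] == "failed").sum()),
                },
            )
        )
    return out


def read_fixes(path, format: str = "csv") -> list[Trajectory]:
    """Read a fix table and return one Trajectory per animal.

    Rows are sorted by time; duplicate timestamps within an animal are an
    error; ``failed`` rows are excluded from trajectories but counted in
    ``metadata['n_failed']``.
    """
    if format != "csv":
        raise ValueError(f"unsupported fix format: {format!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    return trajectories_from_frame(df, source=str(path))


def read_fix_rows(path) -> pd.DataFrame:
    """Read the raw fix table (all attempts, including failed) validated."""
    return _parse_fix_frame(pd.read_csv(path, float_precision="round_trip"),
                            source=str(path))


def write_fixes(rows, path) -> None:
    """Write fixes to CSV.

    ``rows`` may be a DataFrame of raw rows or a list of Trajectory.
    Round-trips losslessly through :func:`read_fixes` (full float repr,
    ISO-8601 timestamps).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.concat([t.to_frame() for t in rows], ignore_index=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).map(
        lambda t: t.isoformat()
    )
    df.to_csv(path, index=False, columns=REQUIRED_COLUMNS)


# ---------------------------------------------------------------------------
# Acquisition statistics and daily paths
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionStats:
    success_rate: float
    mean_fixes_per_day: float
    n_attempted: int
    n_valid: int
    n_days: int


def acquisition_rate(
    rows: pd.DataFrame,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> AcquisitionStats:
    """Fix acquisition success and mean valid fixes per tracking day.

    ``rows`` must include failed attempts (the raw schedule), e.g. from
    :func:`read_fix_rows`.
    """
    rows = _parse_fix_frame(rows)
    n_attempted = len(rows)
    if n_attempted == 0:
        raise ValueError("acquisition_rate: zero fix attempts")
    n_valid = int((rows["status"] == "valid").sum())
    local = rows["timestamp"] + pd.Timedelta(hours=utc_offset_hours)
    n_days = int(local.dt.date.nunique())
    return AcquisitionStats(
        success_rate=n_valid / n_attempted,
        mean_fixes_per_day=n_valid / n_days,
        n_attempted=n_attempted,
        n_valid=n_valid,
        n_days=n_days,
    )


def assemble_daily_paths(
    traj: Trajectory,
    min_fixes: int = 12,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> list[DailyPath]:
    """Partition a trajectory into local calendar days.

    Every valid fix belongs to exactly one day (local civil midnight
    boundaries).  Days with at least ``min_fixes`` fixes are flagged usable;
    the default threshold of 12 follows the convention of analysing only
    24-h periods with a minimum of 12 GPS fixes.
    """
    if traj.n == 0:
        raise ValueError("assemble_daily_paths: empty trajectory")
    local = traj.local_times(utc_offset_hours)
    dates = np.asarray(local.date)
    out: list[DailyPath] = []
    # stable order: fixes are already time-sorted, group by consecutive date
    uniq, starts = np.unique(dates, return_index=True)
    order = np.argsort(starts)
    for d in uniq[order]:
        sel = dates == d
        out.append(
            DailyPath(
                animal_id=traj.animal_id,
                date=d,
                times=traj.times[sel],
                xy=traj.xy[sel],
                min_fixes=min_fixes,
            )
        )
    return out
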