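"""Synthetic mangrove landscapes and tiger trajectories with known truth.

The generator emulates a mangrove archipelago: a smoothed random elevation
field thresholded into five habitat classes at the class-fraction targets,
with water channels laid as straight corridors of constant width spanning
the study area.  Tigers move as biased correlated random walks: headings are
wrapped-normal around the previous heading with a pull toward a home center,
step lengths scale with an hourly activity profile, proposed steps are
accepted in proportion to the habitat weight of the end cell, and a step
that swims across a channel of width ``w`` is additionally accepted with
probability ``2**(-w / crossing_halfwidth)``.  Scheduled fixes drop out
independently at ``1 - fix_success_prob``.

Every stochastic choice flows from the recipe's integer seed, so identical
specs give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .channel_crossings import ChannelFeature
from .raster import (ALL_CLASSES, AVIC_SONN, BARREN, CERIOPS, CLASS_CODES,
                     CLASS_NAMES, PHOENIX, WATER, GridRaster)
from .telemetry_io import DEFAULT_UTC_OFFSET_HOURS, Trajectory

# Habitat class fractions of the Sundarban Tiger Reserve map (printed
# percentages sum to 100.03; normalized here so proportions sum to 1).
_RAW = {
    "Water": 0.4148,
    "Phoenix": 0.3692,
    "Ceriops": 0.1191,
    "Barren": 0.052,
    "AvicenniaSonneratia": 0.0452,
}
SUNDARBAN_FRACTIONS: dict[str, float] = {k: v / sum(_RAW.values()) for k, v in _RAW.items()}

#: Hourly activity multipliers (local hour 0-23) with a dawn peak around
#: 07:00 and a midday lull, normalized to mean 1.
_DAWN_RAW = np.array(
    [0.8, 0.8, 0.8, 0.9, 1.5, 2.2, 2.8, 3.2, 2.8, 2.2, 1.2, 0.5,
     0.35, 0.35, 0.35, 0.35, 0.5, 0.7, 1.0, 1.0, 1.0, 0.9, 0.8, 0.8]
)
DAWN_PEAK_ACTIVITY: tuple[float, ...] = tuple(_DAWN_RAW / _DAWN_RAW.mean())

#: Default habitat weights: clearly ranked preference, prey-rich silt banks
#: first, open water strongly avoided.
DEFAULT_HABITAT_WEIGHTS: dict[str, float] = {
    "AvicenniaSonneratia": 8.0,
    "Phoenix": 4.0,
    "Ceriops": 2.0,
    "Barren": 1.0,
    "Water": 0.5,
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a synthetic habitat raster plus channel network."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 24_000.0, 24_000.0)
    cell_size: float = 50.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(SUNDARBAN_FRACTIONS)
    )
    channel_count: int = 8
    width_range: tuple[float, float] = (30.0, 2500.0)
    patch_scale_m: float = 300.0
    min_gap_m: float = 200.0  # minimum land strip flanking each channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        unknown = set(self.class_fractions) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown habitat classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total!r})")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class fractions must be nonnegative")
        if self.channel_count < 0:
            raise ValueError("channel_count must be >= 0")
        if self.width_range[0] < 20:
            raise ValueError("minimum channel width must be >= 20 m")
        if self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must be (min, max) with min <= max")

    def fraction(self, name: str) -> float:
        return self.class_fractions.get(name, 0.0)


def _place_channels(spec: LandscapeSpec, rng: np.random.Generator) -> list[ChannelFeature]:
    """Lay straight north-south channel corridors of constant width."""
    x0, y0, x1, y1 = spec.extent
    lx = x1 - x0
    gap = max(spec.min_gap_m, 2.0 * spec.cell_size)
    wmin, wmax = spec.width_range
    water_budget = spec.fraction("Water") * lx

    for _ in range(200):  # redraw widths until they fit the water budget
        widths = np.exp(rng.uniform(np.log(wmin), np.log(wmax), size=spec.channel_count))
        if spec.channel_count == 0:
            return []
        if widths.sum() + (spec.channel_count + 1) * gap > lx:
            continue
        if water_budget > 0 and widths.sum() > water_budget:
            continue
        intervals: list[tuple[float, float]] = []
        ok = True
        for w in widths:
            placed = False
            for _ in range(500):
                c = rng.uniform(x0 + w / 2 + gap, x1 - w / 2 - gap)
                lo, hi = c - w / 2 - gap, c + w / 2 + gap
                if all(hi <= a or lo >= b for a, b in intervals):
                    intervals.append((lo, hi))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            chans = []
            cell = spec.cell_size
            for i, ((lo, hi), w) in enumerate(zip(intervals, widths)):
                # snap edges to the raster grid so the vector channel and its
                # rasterized Water cells coincide exactly (no sliver overlaps)
                a = round((lo + gap - x0) / cell) * cell + x0
                b = round((hi - gap - x0) / cell) * cell + x0
                b = max(b, a + cell)
                chans.append(
                    ChannelFeature(
                        id=f"ch{i:02d}", geometry=box(a, y0, b, y1), width_m=float(b - a)
                    )
                )
            return sorted(chans, key=lambda c: c.geometry.bounds[0])
    raise ValueError(
        f"extent too small to place {spec.channel_count} channels of width "
        f"{spec.width_range} m within the Water budget "
        f"({spec.fraction('Water'):.0%} of a {lx:.0f} m extent)"
    )


def generate_landscape(spec: LandscapeSpec) -> tuple[GridRaster, list[ChannelFeature]]:
    """Generate a habitat raster and its channel feature set.

    The class field is a Gaussian-smoothed random surface thresholded by
    'elevation': residual open water in the lowest cells, then
    Avicennia-Sonneratia silt banks, barren flats, Ceriops shrub, and
    Phoenix thicket on the highest ground.  Channels are rasterized as
    Water.  Realized class fractions match the recipe within +/-2 percentage
    points (exact up to cell quantization unless channels overflow the
    Water budget).
    """
    x0, y0, x1, y1 = spec.extent
    nx = int(round((x1 - x0) / spec.cell_size))
    ny = int(round((y1 - y0) / spec.cell_size))
    if nx < 4 or ny < 4:
        raise ValueError("extent too small for the requested cell size")
    rng = np.random.default_rng(spec.seed)

    channels = _place_channels(spec, rng)

    elev = gaussian_filter(
        rng.standard_normal((ny, nx)), sigma=spec.patch_scale_m / spec.cell_size,
        mode="reflect",
    )

    xs = x0 + (np.arange(nx) + 0.5) * spec.cell_size
    chan_cols = np.zeros(nx, dtype=bool)
    for c in channels:
        lo, _, hi, _ = c.geometry.bounds
        chan_cols |= (xs >= lo) & (xs < hi)
    chan_mask = np.broadcast_to(chan_cols, (ny, nx))

    n_total = nx * ny
    n_chan = int(chan_mask.sum())
    # fill order: ascending elevation
    order_classes = [WATER, AVIC_SONN, BARREN, CERIOPS, PHOENIX]
    targets = np.array([spec.fraction(CLASS_NAMES[c]) for c in order_classes]) * n_total
    targets[0] = max(0.0, targets[0] - n_chan)  # water already supplied by channels
    n_free = n_total - n_chan
    if targets.sum() > 0:
        targets *= n_free / targets.sum()
    bounds = np.round(np.cumsum(targets)).astype(int)
    bounds[-1] = n_free

    data = np.empty((ny, nx), dtype=int)
    free = ~chan_mask
    free_idx = np.flatnonzero(free.ravel())
    order = free_idx[np.argsort(elev.ravel()[free_idx], kind="stable")]
    flat = data.ravel()
    flat[chan_mask.ravel()] = WATER
    start = 0
    for cls, stop in zip(order_classes, bounds):
        flat[order[start:stop]] = cls
        start = stop

    raster = GridRaster(data=data, x0=x0, y0=y0, cell_size=spec.cell_size)
    realized = raster.class_fractions()
    for name in ALL_CLASSES:
        if abs(realized[name] - spec.fraction(name)) > 0.02:
            raise ValueError(
                f"realized {name} fraction {realized[name]:.3f} deviates more than "
                f"2 percentage points from target {spec.fraction(name):.3f} "
                "(channel widths exceed the Water budget; reduce channel_count or widths)"
            )
    return raster, channels


# ---------------------------------------------------------------------------
# Tiger movement simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TigerSimSpec:
    """Parameters of one simulated tiger's movement and fix schedule."""

    home_center: tuple[float, float]
    attraction_strength: float = 0.5
    step_scale: float = 193.0  # tuned so the default world walks ~4.6 km/day
    turning_concentration: float = 1.0
    habitat_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_WEIGHTS)
    )
    crossing_halfwidth: float = 150.0
    activity_profile: tuple[float, ...] = DAWN_PEAK_ACTIVITY
    fix_interval_hours: float = 1.0
    fix_success_prob: float = 0.666
    duration_days: int = 90
    start_time: str = "2009-12-31T18:30:00+00:00"  # local midnight at UTC+05:30
    animal_id: str = "T01"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 <= self.fix_interval_hours <= 3.0:
            raise ValueError("fix_interval_hours must lie in [1, 3]")
        if not 0.0 <= self.fix_success_prob <= 1.0:
            raise ValueError("fix_success_prob must lie in [0, 1]")
        if len(self.activity_profile) != 24:
            raise ValueError("activity_profile must have exactly 24 entries")
        if any(a < 0 for a in self.activity_profile):
            raise ValueError("activity_profile entries must be nonnegative")
        if any(w <= 0 for w in self.habitat_weights.values()):
            raise ValueError("habitat weights must be positive")
        if set(self.habitat_weights) - set(ALL_CLASSES):
            raise ValueError("habitat_weights contains unknown classes")
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        if self.turning_concentration < 0:
            raise ValueError("turning_concentration must be >= 0")
        if self.crossing_halfwidth <= 0:
            raise ValueError("crossing_halfwidth must be > 0 (may be inf)")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth realized by one simulation run."""

    spec: TigerSimSpec
    daily_distance_km: pd.Series          # local date -> km travelled
    crossings: pd.DataFrame               # channel_id, width_m, count
    occupancy: pd.Series                  # class name -> fraction of true positions
    positions: np.ndarray                 # (n+1, 2) true path, all scheduled times
    raw_rows: pd.DataFrame                # the full fix-attempt table

    def __post_init__(self) -> None:
        s = float(self.occupancy.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"occupancy fractions must sum to 1 (got {s})")


def _strip_intervals(channels: list[ChannelFeature]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = np.array([c.geometry.bounds[0] for c in channels])
    hi = np.array([c.geometry.bounds[2] for c in channels])
    wid = np.array([c.width_m for c in channels])
    return lo, hi, wid


def simulate_tiger(
    spec: TigerSimSpec,
    landscape: tuple[GridRaster, list[ChannelFeature]],
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
    max_step_attempts: int = 50,
) -> tuple[Trajectory, SyntheticTruth]:
    """Simulate one tiger and return its observed trajectory plus the truth.

    The movement kernel is Metropolis-like: a proposed endpoint in class
    ``c`` is accepted with probability ``weight[c]/max(weight)`` times the
    channel-crossing penalty, so long-run occupancy is proportional to
    habitat weight times availability.  If every proposal in a step is
    rejected the tiger stays put for that interval.
    """
    raster, channels = landscape
    x0e, y0e, x1e, y1e = raster.extent
    hx, hy = spec.home_center
    if raster.value_at([hx], [hy])[0] == WATER:
        raise ValueError("home_center lies in Water; it must be on land")

    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_days * 24.0 / spec.fix_interval_hours))
    t0 = pd.Timestamp(spec.start_time)
    if t0.tz is None:
        t0 = t0.tz_localize("UTC")
    times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * spec.fix_interval_hours, unit="h")
    local_hours = ((times.asi8 / 3.6e12 + utc_offset_hours) % 24).astype(int)

    act = np.asarray(spec.activity_profile, dtype=float)
    codes = sorted(CLASS_NAMES)
    wvec = np.array([spec.habitat_weights[CLASS_NAMES[c]] for c in codes])
    wnorm = wvec / wvec.max()
    slo, shi, swid = _strip_intervals(channels)
    have_strips = len(channels) > 0
    hw = spec.crossing_halfwidth
    kappa = spec.turning_concentration
    sigma_turn = 1.0 / math.sqrt(kappa) if kappa > 0 else None
    attract = spec.attraction_strength

    data = raster.data
    rx0, ry0, cell = raster.x0, raster.y0, raster.cell_size
    ny, nx = data.shape

    pos = np.empty((n_steps + 1, 2))
    pos[0] = (hx, hy)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    n_cross = np.zeros(len(channels), dtype=int)

    x, y = float(hx), float(hy)
    for k in range(1, n_steps + 1):
        m = act[local_hours[k - 1]]
        if m > 0:
            for _ in range(max_step_attempts):
                L = m * spec.step_scale * (0.5 + rng.random())
                turn = (rng.normal(0.0, sigma_turn) if sigma_turn is not None
                        else rng.uniform(-math.pi, math.pi))
                if attract > 0:
                    dx, dy = hx - x, hy - y
                    d = math.hypot(dx, dy)
                    if d > 0:
                        mu = math.atan2(math.sin(heading) + attract * dy / d,
                                        math.cos(heading) + attract * dx / d)
                    else:
                        mu = heading
                else:
                    mu = heading
                th = mu + turn
                cx, cy = x + L * math.cos(th), y + L * math.sin(th)
                if not (x0e <= cx < x1e and y0e <= cy < y1e):
                    continue
                code = data[int((cy - ry0) // cell), int((cx - rx0) // cell)]
                p = wnorm[code]
                spans = None
                if have_strips:
                    a, b = (x, cx) if x <= cx else (cx, x)
                    spans = (slo >= a) & (shi <= b)
                    if spans.any() and math.isfinite(hw):
                        p *= 2.0 ** (-swid[spans].sum() / hw)
                if rng.random() < p:
                    x, y, heading = cx, cy, th
                    if spans is not None and spans.any():
                        n_cross[spans] += 1
                    break
        pos[k] = (x, y)

    valid = rng.random(n_steps + 1) < spec.fix_success_prob

    raw = pd.DataFrame(
        {
            "animal_id": spec.animal_id,
            "timestamp": times,
            "x_m": np.where(valid, pos[:, 0], np.nan),
            "y_m": np.where(valid, pos[:, 1], np.nan),
            "status": np.where(valid, "valid", "failed"),
        }
    )
    traj = Trajectory(
        animal_id=spec.animal_id,
        times=times[valid],
        xy=pos[valid],
        metadata={
            "n_attempted": int(n_steps + 1),
            "n_failed": int((~valid).sum()),
            "sim_spec": spec,
        },
    )

    # truth bookkeeping from the realized (true) path
    step_len = np.hypot(*np.diff(pos, axis=0).T) / 1000.0
    local_dates = (times + pd.Timedelta(hours=utc_offset_hours)).date
    daily = pd.Series(step_len).groupby(pd.Series(local_dates[:-1])).sum()
    daily.index.name = "date"
    occ_codes = raster.value_at(pos[:, 0], pos[:, 1])
    occupancy = pd.Series(
        {CLASS_NAMES[c]: float(np.mean(occ_codes == c)) for c in codes}
    )
    occupancy /= occupancy.sum()
    crossings = pd.DataFrame(
        {
            "channel_id": [c.id for c in channels],
            "width_m": [c.width_m for c in channels],
            "count": n_cross,
        }
    )
    truth = SyntheticTruth(
        spec=spec,
        daily_distance_km=daily,
        crossings=crossings,
        occupancy=occupancy,
        positions=pos,
        raw_rows=raw,
    )
    return traj, truth


def random_land_point(
    raster: GridRaster,
    rng: np.random.Generator,
    margin_m: float = 0.0,
) -> tuple[float, float]:
    """A uniformly chosen land-cell center, optionally away from the border."""
    x0, y0, x1, y1 = raster.extent
    xs, ys = raster.cell_centers()
    land_iy, land_ix = np.nonzero(raster.data != WATER)
    ok = (
        (xs[land_ix] >= x0 + margin_m) & (xs[land_ix] < x1 - margin_m)
        & (ys[land_iy] >= y0 + margin_m) & (ys[land_iy] < y1 - margin_m)
    )
    land_iy, land_ix = land_iy[ok], land_ix[ok]
    if len(land_ix) == 0:
        raise ValueError("no land cells available for a start point")
    j = rng.integers(len(land_ix))
    return float(xs[land_ix[j]]), float(ys[land_iy[j]])


def synthetic_syzygy_table(start: str, n_cycles: int = 30) -> pd.DataFrame:
    """New/full-moon dates at the mean half-synodic interval of 14.765 days."""
    t0 = pd.Timestamp(start)
    offsets = np.round(np.arange(n_cycles) * 14.765).astype(int)
    dates = [t0 + pd.Timedelta(days=int(d)) for d in offsets]
    phase = ["new" if i % 2 == 0 else "full" for i in range(n_cycles)]
    return pd.DataFrame({"date": [d.date() for d in dates], "phase": phase})
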