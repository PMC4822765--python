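"""Home-range estimation: MCP, fixed-kernel UD, isopleths, cores, density.

Two classic estimators are provided.  The minimum convex polygon (MCP) at
``percent`` < 100 removes the fixes farthest from the arithmetic centroid
before hull construction.  The fixed-kernel utilization distribution (UD)
places a circular bivariate Gaussian of standard deviation ``h`` (the
smoothing parameter, meters; default 1000) on every fix and renormalizes on
a regular grid.  Isopleths are smallest-area superlevel sets of the UD
containing the stated probability mass, computed exactly on the grid by
accumulating cells in decreasing density order.  The core area is the
isopleth level at which the area-versus-level curve bends most sharply
upward (maximum second forward difference).  Mean territorial core areas,
treated as exclusive, extrapolate to the number of residents a land area can
accommodate and hence a crude density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

from .channel_crossings import ChannelFeature
from .raster import GridRaster

M2_PER_KM2 = 1e6


@dataclass
class UtilizationDistribution:
    """Normalized kernel density on a regular grid (row 0 = south)."""

    x0: float
    y0: float
    cell: float
    density: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if (self.density < 0).any():
            raise ValueError("UD density must be nonnegative")

    @property
    def cell_area_m2(self) -> float:
        return self.cell * self.cell

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area_m2)


@dataclass
class HomeRangeResult:
    animal_id: str
    estimator: str               # 'MCP' or 'FK'
    level: float                 # percent in (0, 100]
    geometry: Polygon
    area_km2: float
    water_masked: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.level <= 100:
            raise ValueError("level must lie in (0, 100]")
        if self.area_km2 < 0:
            raise ValueError("area_km2 must be >= 0")


@dataclass
class IsoplethProfile:
    levels: np.ndarray
    areas_km2: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.areas_km2 = np.asarray(self.areas_km2, dtype=float)
        if np.any(np.diff(self.areas_km2) < -1e-12):
            raise ValueError("isopleth areas must be nondecreasing in level")


@dataclass
class DensityEstimate:
    land_area_km2: float
    core_female_km2: tuple[float, float]   # (mean, SE)
    core_male_km2: tuple[float, float]
    n_females: int
    n_females_range: tuple[int, int]
    n_males: int
    n_males_range: tuple[int, int]
    density_per_100km2: float
    density_range: tuple[float, float]


# ---------------------------------------------------------------------------
# Minimum convex polygon
# ---------------------------------------------------------------------------

def compute_mcp(xy: np.ndarray, percent: float = 95.0, animal_id: str = "") -> HomeRangeResult:
    """MCP home range at ``percent`` (100 or the customary 95).

    For ``percent`` < 100 the ``ceil((1 - percent/100) * n)`` fixes farthest
    from the arithmetic centroid are removed before hull construction.
    Degenerate inputs (all identical or collinear) yield a flagged
    zero-area result with a warning.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    n = len(xy)
    if n < 3:
        raise ValueError(f"compute_mcp: need >= 3 fixes, got {n}")
    if percent < 100:
        # epsilon guards the ceil against float artifacts (1 - 95/100 != 0.05)
        k = math.ceil((100.0 - percent) / 100.0 * n - 1e-9)
        if k > 0:
            centroid = xy.mean(axis=0)
            d = np.hypot(*(xy - centroid).T)
            keep = np.argsort(d, kind="stable")[: n - k]
            xy = xy[np.sort(keep)]
    if len(np.unique(xy, axis=0)) < 3:
        warnings.warn("compute_mcp: fewer than 3 distinct fixes; degenerate zero-area hull")
        return HomeRangeResult(animal_id, "MCP", percent, MultiPoint(xy).convex_hull.buffer(0),
                               0.0, degenerate=True)
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn("compute_mcp: collinear fixes; degenerate zero-area hull")
        return HomeRangeResult(animal_id, "MCP", percent, hull.buffer(0), 0.0, degenerate=True)
    return HomeRangeResult(animal_id, "MCP", percent, hull, hull.area / M2_PER_KM2)


# ---------------------------------------------------------------------------
# Fixed-kernel UD
# ---------------------------------------------------------------------------

def compute_fixed_kernel_ud(
    xy: np.ndarray,
    h: float = 1000.0,
    cell: float | None = None,
    pad: float | None = None,
    grid_like: GridRaster | None = None,
) -> UtilizationDistribution:
    """Fixed-kernel UD: mean of circular Gaussian kernels (sd = ``h`` m).

    Fixes are binned to the grid and smoothed with a Gaussian filter of
    sigma ``h``; the result is renormalized to integrate to 1 on the grid.
    The default grid uses cell = h/10 and pads 4h beyond the fix extent;
    pass ``grid_like`` to evaluate on an existing raster's grid instead.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        raise ValueError("compute_fixed_kernel_ud: need at least one fix")
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    if grid_like is not None:
        cell = grid_like.cell_size
        x0, y0, x1, y1 = grid_like.extent
        ny, nx = grid_like.shape
    else:
        cell = h / 10.0 if cell is None else float(cell)
        pad = 4.0 * h if pad is None else float(pad)
        x0 = xy[:, 0].min() - pad
        y0 = xy[:, 1].min() - pad
        nx = int(math.ceil((xy[:, 0].max() + pad - x0) / cell))
        ny = int(math.ceil((xy[:, 1].max() + pad - y0) / cell))
        x1, y1 = x0 + nx * cell, y0 + ny * cell
    if cell > h / 4.0:
        raise ValueError(f"grid cell {cell} m too coarse for h={h} m (need cell <= h/4)")
    counts, _, _ = np.histogram2d(
        xy[:, 1], xy[:, 0], bins=[ny, nx], range=[[y0, y1], [x0, x1]]
    )
    if counts.sum() != len(xy):
        raise ValueError("compute_fixed_kernel_ud: fixes fall outside the grid extent")
    dens = gaussian_filter(counts, sigma=h / cell, mode="constant", truncate=6.0)
    mass = dens.sum() * cell * cell
    if mass <= 0:
        raise ValueError("compute_fixed_kernel_ud: empty density")
    return UtilizationDistribution(x0=x0, y0=y0, cell=cell, density=dens / mass, h=h)


def isopleth_mask(ud: UtilizationDistribution, level: float) -> np.ndarray:
    """Boolean mask of the smallest-area superlevel set holding level% mass."""
    if not 0 < level <= 100:
        raise ValueError("isopleth level must lie in (0, 100]")
    flat = ud.density.ravel()
    if flat.sum() == 0:
        raise ValueError("isopleth_mask: empty UD")
    order = np.argsort(flat, kind="stable")[::-1]
    cum = np.cumsum(flat[order]) * ud.cell_area_m2
    k = int(np.searchsorted(cum, level / 100.0 * cum[-1] - 1e-12)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape)


def _mask_polygon(ud: UtilizationDistribution, mask: np.ndarray) -> Polygon:
    """Union of cell rectangles of a mask, merged row-wise into run boxes."""
    boxes = []
    for iy in range(mask.shape[0]):
        row = mask[iy]
        if not row.any():
            continue
        d = np.diff(np.concatenate([[0], row.view(np.int8), [0]]))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        yl = ud.y0 + iy * ud.cell
        for a, b in zip(starts, stops):
            boxes.append(box(ud.x0 + a * ud.cell, yl, ud.x0 + b * ud.cell, yl + ud.cell))
    return unary_union(boxes)


def extract_isopleths(
    ud: UtilizationDistribution,
    levels=None,
    with_polygons: bool = False,
):
    """Isopleth area profile (and optionally polygons) for a UD.

    Default levels are 5, 10, ..., 95 percent.  Areas are nondecreasing in
    level by construction.
    """
    if levels is None:
        levels = np.arange(5.0, 96.0, 5.0)
    levels = np.asarray(levels, dtype=float)
    flat = ud.density.ravel()
    if flat.sum() == 0:
        raise ValueError("extract_isopleths: empty UD")
    order = np.argsort(flat, kind="stable")[::-1]
    cum = np.cumsum(flat[order]) * ud.cell_area_m2
    ks = np.searchsorted(cum, levels / 100.0 * cum[-1] - 1e-12) + 1
    areas = ks * ud.cell_area_m2 / M2_PER_KM2
    profile = IsoplethProfile(levels=levels, areas_km2=areas)
    if not with_polygons:
        return profile
    polys = {float(lv): _mask_polygon(ud, isopleth_mask(ud, lv)) for lv in levels}
    return profile, polys


def kernel_home_range(
    xy: np.ndarray,
    level: float = 95.0,
    h: float = 1000.0,
    animal_id: str = "",
    with_polygon: bool = True,
    **ud_kwargs,
) -> HomeRangeResult:
    """Convenience: fixed-kernel home range polygon/area at one isopleth."""
    ud = compute_fixed_kernel_ud(xy, h=h, **ud_kwargs)
    mask = isopleth_mask(ud, level)
    area = mask.sum() * ud.cell_area_m2 / M2_PER_KM2
    geom = _mask_polygon(ud, mask) if with_polygon else Polygon()
    return HomeRangeResult(animal_id, "FK", level, geom, area)


# ---------------------------------------------------------------------------
# Water masking, asymptote, core detection
# ---------------------------------------------------------------------------

def mask_water(
    result: HomeRangeResult,
    channels: list[ChannelFeature],
    min_width_m: float = 1000.0,
) -> HomeRangeResult:
    """Exclude wide water channels (width > 1 km by default) as non-habitat.

    Channels at or below the threshold are habitat matrix and are kept.
    """
    wide = [c.geometry for c in channels if c.width_m > min_width_m]
    geom = result.geometry
    if wide:
        geom = geom.difference(unary_union(wide))
    return replace(result, geometry=geom, area_km2=geom.area / M2_PER_KM2, water_masked=True)


def asymptote_curve(
    xy: np.ndarray,
    step: int = 50,
    percent: float = 95.0,
    gain_fraction: float = 0.05,
    estimator=None,
) -> tuple[list[tuple[int, float]], int | None]:
    """Home-range area versus number of chronological fixes.

    Areas are computed on the first ``step``, ``2*step``, ... fixes.  The
    asymptote is the first sample size whose area gain over the next
    increment is below ``gain_fraction`` of the current area; ``None`` if
    the curve is too short or never flattens.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) < step:
        raise ValueError(f"asymptote_curve: need at least {step} fixes")
    if estimator is None:
        estimator = lambda pts: compute_mcp(pts, percent=percent).area_km2  # noqa: E731
    ns = list(range(step, len(xy) + 1, step))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = [(n, float(estimator(xy[:n]))) for n in ns]
    asymptote = None
    for (n0, a0), (_, a1) in zip(curve, curve[1:]):
        if a0 > 0 and (a1 - a0) < gain_fraction * a0:
            asymptote = n0
            break
    return curve, asymptote


def detect_core_isopleth(profile: IsoplethProfile, rel_tol: float = 1e-9) -> float | None:
    """Isopleth level at the inflection of the area-vs-level curve.

    Returns the level maximizing the second forward difference of area
    (sharpest upward bend), ties broken toward the higher level; ``None``
    for a strictly linear profile.  Invariant to uniform rescaling of areas.
    """
    lv = profile.levels
    ar = profile.areas_km2
    if len(lv) < 5:
        raise ValueError("detect_core_isopleth: need >= 5 levels")
    d2 = ar[2:] - 2.0 * ar[1:-1] + ar[:-2]
    scale = float(np.max(np.abs(ar))) or 1.0
    if np.all(np.abs(d2) <= rel_tol * scale):
        return None
    best = d2.max()
    idx = np.flatnonzero(d2 >= best - rel_tol * scale)[-1]
    return float(lv[idx + 1])


# ---------------------------------------------------------------------------
# Cross-animal summaries and density extrapolation
# ---------------------------------------------------------------------------

def summarize_home_ranges(
    table: pd.DataFrame,
    value_cols: list[str],
    sex_col: str = "sex",
    exclude: dict[str, str] | None = None,
) -> dict:
    """Mean and SE (sd/sqrt(n), n = animals) of home-range areas by sex.

    ``table`` has one row per animal (indexed or keyed by ``animal_id``);
    animals in ``exclude`` (id -> reason) are left out of the means and
    listed separately.  A sex class with a single animal reports its mean
    with a blank (NaN) SE; an empty class warns and reports blanks.
    """
    exclude = exclude or {}
    if "animal_id" in table.columns:
        table = table.set_index("animal_id")
    included = table.loc[[i for i in table.index if i not in exclude]]
    rows = []
    for sex, grp in included.groupby(sex_col):
        for col in value_cols:
            vals = grp[col].astype(float)
            n = len(vals)
            se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append({"sex": sex, "measure": col, "mean": float(vals.mean()),
                         "se": se, "n": n})
    for sex in table[sex_col].unique():
        if sex not in included[sex_col].unique():
            warnings.warn(f"summarize_home_ranges: no includable animals of sex {sex!r}")
            for col in value_cols:
                rows.append({"sex": sex, "measure": col, "mean": float("nan"),
                             "se": float("nan"), "n": 0})
    summary = pd.DataFrame(rows)
    excluded = pd.DataFrame(
        [{"animal_id": k, "reason": v} for k, v in exclude.items()]
    )
    return {"summary": summary, "excluded": excluded}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_density(
    land_area_km2: float,
    core_female_km2: tuple[float, float],
    core_male_km2: tuple[float, float],
) -> DensityEstimate:
    """Exclusive-core extrapolation of resident numbers and density.

    The number of residents per sex is land area divided by that sex's mean
    core area, rounded to the nearest integer; the SE range divides by
    (mean +/- SE).  Density per 100 km2 = 100 * (n_f + n_m) / land, to one
    decimal, with its range from the summed count bounds.
    """
    if land_area_km2 <= 0:
        raise ValueError("land_area_km2 must be positive")

    def counts(core: tuple[float, float]) -> tuple[int, tuple[int, int]]:
        mean, se = core
        if mean <= 0:
            raise ValueError("core area must be positive")
        if se >= mean:
            raise ValueError("core-area SE must be smaller than the mean")
        if mean >= land_area_km2:
            warnings.warn("core area >= land area; reporting a single resident")
            return 1, (1, 1)
        n = _round_half_up(land_area_km2 / mean)
        lo = _round_half_up(land_area_km2 / (mean + se))
        hi = _round_half_up(land_area_km2 / (mean - se))
        return n, (lo, hi)

    n_f, r_f = counts(core_female_km2)
    n_m, r_m = counts(core_male_km2)
    dens = round(100.0 * (n_f + n_m) / land_area_km2, 1)
    d_lo = round(100.0 * (r_f[0] + r_m[0]) / land_area_km2, 1)
    d_hi = round(100.0 * (r_f[1] + r_m[1]) / land_area_km2, 1)
    return DensityEstimate(
        land_area_km2=land_area_km2,
        core_female_km2=core_female_km2,
        core_male_km2=core_male_km2,
        n_females=n_f,
        n_females_range=r_f,
        n_males=n_m,
        n_males_range=r_m,
        density_per_100km2=dens,
        density_range=(d_lo, d_hi),
    )
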