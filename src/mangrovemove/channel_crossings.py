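"""Water-channel crossings, the random-walk null model and the barrier test.

A tiger moving through an island mosaic must swim to change islands.  For
each daily movement path we count intersections of consecutive-fix segments
with width-attributed channel features.  Availability of channels of each
width is estimated from random null trajectories matched to each observed
daily path (same step count, step lengths within the observed min/max,
unconstrained headings) and constrained to the pooled-fix convex polygon and
to land endpoints.  Observed versus available crossing counts per width bin
are then compared with a chi-square goodness-of-fit test: a deficit of
crossings in wide bins indicates width-dependent barrier avoidance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import LineString, MultiPoint, Polygon, mapping, shape

from .raster import WATER, GridRaster
from .telemetry_io import DailyPath


@dataclass
class ChannelFeature:
    """A water channel: polygon (or buffered centerline) with a width in meters."""

    id: str
    geometry: Polygon
    width_m: float

    def __post_init__(self) -> None:
        if self.width_m <= 0:
            raise ValueError(f"channel {self.id}: width_m must be positive")


@dataclass
class CrossingRecord:
    path_id: str
    channel_id: str
    width_m: float
    source: str = "observed"  # 'observed' or 'null'


@dataclass
class WidthBinTable:
    """Crossing counts by channel-width bin, plus the chi-square test."""

    edges: np.ndarray                 # len k+1, half-open [lo, hi)
    observed: np.ndarray              # len k
    availability: np.ndarray          # len k
    expected: np.ndarray | None = None
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None
    merged_edges: np.ndarray | None = None
    merged_observed: np.ndarray | None = None
    merged_expected: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "width_lo_m": self.edges[:-1],
                "width_hi_m": self.edges[1:],
                "observed": self.observed,
                "availability": self.availability,
            }
        )


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_channels_geojson(channels: list[ChannelFeature], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(c.geometry),
                "properties": {"id": c.id, "width_m": c.width_m},
            }
            for c in channels
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_channels_geojson(path) -> list[ChannelFeature]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for i, feat in enumerate(fc["features"]):
        props = feat.get("properties", {})
        if "width_m" not in props:
            raise ValueError(f"{path}: feature {i} lacks a 'width_m' property")
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            geom = geom.buffer(props["width_m"] / 2.0, cap_style="flat")
        out.append(
            ChannelFeature(
                id=str(props.get("id", f"ch{i:02d}")),
                geometry=geom,
                width_m=float(props["width_m"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Crossing detection
# ---------------------------------------------------------------------------

def _path_segments(xy: np.ndarray) -> list[LineString]:
    xy = np.asarray(xy, dtype=float)
    return [LineString(xy[i : i + 2]) for i in range(len(xy) - 1)]


def detect_crossings(
    path: DailyPath | tuple[str, np.ndarray],
    channels: list[ChannelFeature],
    source: str = "observed",
) -> list[CrossingRecord]:
    """Crossing records along a daily path.

    One record per maximal (positive-length) intersection of a
    consecutive-fix segment with a channel geometry; a path re-entering the
    same channel later in the day is counted again.  Grazing point contacts
    are not crossings.
    """
    if isinstance(path, DailyPath):
        path_id, xy = path.path_id, path.xy
    else:
        path_id, xy = path
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError(f"path {path_id}: need at least 2 fixes")
    if not channels:
        return []
    segs = _path_segments(xy)
    tree = shapely.STRtree([c.geometry for c in channels])
    seg_idx, chan_idx = tree.query(np.array(segs, dtype=object), predicate="intersects")
    records: list[CrossingRecord] = []
    for si, ci in zip(seg_idx, chan_idx):
        inter = segs[si].intersection(channels[ci].geometry)
        parts = getattr(inter, "geoms", [inter])
        n = sum(1 for g in parts if g.geom_type == "LineString" and g.length > 0)
        records.extend(
            CrossingRecord(path_id, channels[ci].id, channels[ci].width_m, source)
            for _ in range(n)
        )
    return records


def common_polygon(xy: np.ndarray) -> Polygon:
    """Convex hull of the pooled fixes of all animals (the study polygon)."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("common_polygon: fixes are degenerate (collinear or <3 distinct)")
    return hull


# ---------------------------------------------------------------------------
# Null-path generation
# ---------------------------------------------------------------------------

def generate_null_paths(
    observed: DailyPath | np.ndarray,
    n: int = 5,
    polygon: Polygon | None = None,
    landscape: GridRaster | None = None,
    seed=None,
    max_attempts: int = 10_000,
    on_exhaust: str = "error",
) -> list[np.ndarray]:
    """Random null trajectories matched to an observed daily path.

    Each null path starts at the observed start point, has the same step
    count as the observed path, step lengths drawn uniformly within the
    observed [min, max] step length, and unconstrained (uniform) headings.
    Every node is rejection-resampled until it lies inside ``polygon`` and
    outside the Water cells of ``landscape``, so no accepted node violates
    either constraint.  Per-node resampling keeps the null walk's law
    identical to an unconstrained walk conditioned step by step on land —
    discarding whole trajectories instead would down-weight bank-adjacent
    paths in proportion to their water exposure and bias the availability
    sample away from wide channels.

    ``max_attempts`` bounds the total proposals per call; on exhaustion the
    default is an error naming the constraints, while ``on_exhaust='skip'``
    returns however many complete paths were built, with a warning.
    """
    xy = observed.xy if isinstance(observed, DailyPath) else np.asarray(observed, float)
    xy = xy.reshape(-1, 2)
    if len(xy) < 2:
        raise ValueError("generate_null_paths: observed path needs >= 2 fixes")
    if n == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = np.diff(xy, axis=0)
    lens = np.hypot(steps[:, 0], steps[:, 1])
    smin, smax = float(lens.min()), float(lens.max())
    n_steps = len(lens)
    start = xy[0]
    if polygon is not None:
        shapely.prepare(polygon)

    def _valid(pts: np.ndarray) -> np.ndarray:
        ok = np.ones(len(pts), dtype=bool)
        if polygon is not None:
            ok &= shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
        if landscape is not None:
            cls = landscape.value_at(pts[:, 0], pts[:, 1], outside="nodata")
            ok &= landscape.contains(pts[:, 0], pts[:, 1]) & (cls != WATER)
        return ok

    nodes = np.empty((n, n_steps + 1, 2))
    nodes[:, 0] = start
    pos = np.broadcast_to(start, (n, 2)).copy()
    attempts = 0
    for k in range(1, n_steps + 1):
        todo = np.arange(n)
        while todo.size:
            if attempts >= max_attempts:
                msg = (
                    f"generate_null_paths: exceeded {max_attempts} proposals at "
                    f"step {k}/{n_steps}; constraints (study polygon, land-only "
                    "nodes) may be infeasible for this path"
                )
                if on_exhaust == "skip":
                    warnings.warn(msg)
                    return []
                raise RuntimeError(msg)
            m = todo.size
            attempts += m
            L = rng.uniform(smin, smax, size=m)
            theta = rng.uniform(0.0, 2.0 * np.pi, size=m)
            cand = pos[todo] + np.column_stack([L * np.cos(theta), L * np.sin(theta)])
            ok = _valid(cand)
            pos[todo[ok]] = cand[ok]
            todo = todo[~ok]
        nodes[:, k] = pos
    return [nodes[i] for i in range(n)]


# ---------------------------------------------------------------------------
# Width binning and the chi-square test
# ---------------------------------------------------------------------------

def default_width_edges(max_width: float) -> np.ndarray:
    """50 m bins to 1000 m, then 500 m bins up to at least ``max_width``."""
    edges = list(np.arange(0.0, 1000.0 + 1e-9, 50.0))
    hi = 1000.0
    while hi < max_width or hi == 1000.0:
        hi += 500.0
        edges.append(hi)
        if hi >= max_width:
            break
    return np.asarray(edges)


def bin_crossings(
    observed: list[CrossingRecord],
    availability: list[CrossingRecord],
    edges: np.ndarray | None = None,
) -> WidthBinTable:
    """Tally observed and available crossings into channel-width bins.

    Bins are half-open ``[lo, hi)``.  A record wider than the final edge
    extends the table with additional 500 m bins, with a warning.
    """
    if not availability:
        raise ValueError("bin_crossings: availability records are empty")
    w_obs = np.array([r.width_m for r in observed], dtype=float)
    w_avl = np.array([r.width_m for r in availability], dtype=float)
    w_all = np.concatenate([w_obs, w_avl]) if len(w_obs) else w_avl
    if edges is None:
        edges = default_width_edges(float(w_all.max()))
    else:
        edges = np.asarray(edges, dtype=float)
        if w_all.max() >= edges[-1]:
            warnings.warn(
                "bin_crossings: record wider than final edge; extending table",
                stacklevel=2,
            )
            while w_all.max() >= edges[-1]:
                edges = np.append(edges, edges[-1] + 500.0)
    obs, _ = np.histogram(w_obs, bins=edges)
    avl, _ = np.histogram(w_avl, bins=edges)
    return WidthBinTable(edges=edges, observed=obs.astype(float), availability=avl.astype(float))


def _merge_bins(edges, obs, exp, avl, min_expected):
    """Merge adjacent bins until every expected count >= min_expected."""
    edges, obs, exp, avl = (list(edges), list(obs), list(exp), list(avl))
    while len(obs) > 1 and min(exp) < min_expected:
        i = int(np.argmin(exp))
        # merge with the adjacent neighbor having the smaller expected count
        if i == 0:
            j = 1
        elif i == len(obs) - 1:
            j = i - 1
        else:
            j = i - 1 if exp[i - 1] <= exp[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        obs[lo] += obs.pop(hi)
        exp[lo] += exp.pop(hi)
        avl[lo] += avl.pop(hi)
        edges.pop(hi)
    return np.asarray(edges), np.asarray(obs), np.asarray(exp), np.asarray(avl)


def crossing_chisq(table: WidthBinTable, min_expected: float = 1.0) -> WidthBinTable:
    """Complete a width-bin table with the barrier chi-square test.

    Expected counts are availability proportions scaled to the observed
    total; empty bins (both counts zero) are dropped; adjacent bins are
    merged until every expected count reaches ``min_expected``;
    chi2 = sum (obs-exp)^2/exp with df = merged bins - 1.
    """
    keep = (table.observed > 0) | (table.availability > 0)
    if int((table.availability > 0).sum()) < 2:
        raise ValueError("crossing_chisq: need availability counts in >= 2 bins")
    # bin edges of kept bins: keep left edges of kept bins plus closing edge
    obs = table.observed[keep]
    avl = table.availability[keep]
    edges = np.append(table.edges[:-1][keep], table.edges[-1])
    total_obs = obs.sum()
    expected_full = total_obs * table.availability / table.availability.sum()
    exp = total_obs * avl / avl.sum()
    m_edges, m_obs, m_exp, _ = _merge_bins(edges, obs, exp, avl, min_expected)
    if len(m_obs) < 2:
        raise ValueError("crossing_chisq: fewer than 2 bins remain after merging")
    chi2 = float(np.sum((m_obs - m_exp) ** 2 / m_exp))
    df = len(m_obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return replace(
        table,
        expected=expected_full,
        chi_square=chi2,
        df=df,
        p_value=p,
        merged_edges=m_edges,
        merged_observed=m_obs,
        merged_expected=m_exp,
    )
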