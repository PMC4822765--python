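"""Habitat use versus availability: compositional analysis and Ivlev's index.

Use is the proportion of an animal's fixes in each habitat class;
availability is the class composition of its 95% fixed-kernel home range.
Compositional analysis log-ratio transforms both (against a reference
class), forms per-animal differences d = ln(u/u_ref) - ln(a/a_ref), and
tests the multivariate mean of d against zero with Wilks' lambda;
chi2 = -N ln(lambda) on D-1 degrees of freedom.  A pairwise t-matrix of
mean log-ratio differences orders the classes into a preference ranking.
Ivlev's electivity E = (u - a)/(u + a) in [-1, 1] gives a per-animal,
per-class picture for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from .raster import ALL_CLASSES, CLASS_CODES, GridRaster


@dataclass
class HabitatUseAvail:
    """Per-animal use and availability proportions over the habitat classes."""

    animal_id: str
    use: pd.Series
    availability: pd.Series

    def __post_init__(self) -> None:
        self.use = self.use.astype(float)
        self.availability = self.availability.reindex(self.use.index).astype(float)
        for name, s in (("use", self.use), ("availability", self.availability)):
            if abs(float(s.sum()) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.animal_id}: {name} proportions must sum to 1 "
                    f"(got {float(s.sum())!r})"
                )


@dataclass
class CompositionalResult:
    wilks_lambda: float | None
    chi_square: float | None
    df: int
    p_value: float | None
    pairwise_t: pd.DataFrame
    ranking: list[str]
    rank_scores: pd.Series
    p_permutation: float | None = None
    warning: str | None = None


@dataclass
class IvlevResult:
    animal_id: str
    electivity: pd.Series   # E_i in [-1, 1], NaN where u_i = a_i = 0


# ---------------------------------------------------------------------------
# Use and availability
# ---------------------------------------------------------------------------

def habitat_use(xy: np.ndarray, raster: GridRaster) -> pd.Series:
    """Proportion of fixes per habitat class; errors on out-of-extent fixes."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        raise ValueError("habitat_use: no fixes")
    codes = raster.value_at(xy[:, 0], xy[:, 1])  # raises naming the fix index
    props = {
        name: float(np.mean(codes == code)) for name, code in CLASS_CODES.items()
    }
    return pd.Series(props).reindex(list(ALL_CLASSES))


def habitat_availability(region, raster: GridRaster) -> pd.Series:
    """Class composition of a home-range region on the habitat raster.

    ``region`` is a shapely polygon (cells counted by center containment) or
    a boolean mask aligned to the raster grid.
    """
    if isinstance(region, np.ndarray):
        mask = region.astype(bool)
        if mask.shape != raster.shape:
            raise ValueError("availability mask does not match the raster shape")
    elif isinstance(region, Polygon) or hasattr(region, "geom_type"):
        import shapely

        xs, ys = raster.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        shapely.prepare(region)
        mask = shapely.contains_xy(region, gx.ravel(), gy.ravel()).reshape(raster.shape)
    else:
        raise TypeError("region must be a shapely polygon or a boolean mask")
    total = int(mask.sum())
    if total == 0:
        raise ValueError("habitat_availability: region does not overlap the raster")
    vals = raster.data[mask]
    props = {
        name: float(np.count_nonzero(vals == code)) / total
        for name, code in CLASS_CODES.items()
    }
    return pd.Series(props).reindex(list(ALL_CLASSES))


# ---------------------------------------------------------------------------
# Compositional analysis
# ---------------------------------------------------------------------------

def _prepare_matrix(samples: list[HabitatUseAvail], zero_sub: float):
    classes = list(samples[0].use.index)
    U = np.vstack([s.use.reindex(classes).to_numpy() for s in samples])
    A = np.vstack([s.availability.reindex(classes).to_numpy() for s in samples])
    if (U == 0).any():
        U = np.where(U == 0, zero_sub, U)
        U = U / U.sum(axis=1, keepdims=True)
    if (A <= 0).any():
        warnings.warn(
            "compositional_analysis: zero availability substituted by zero_sub"
        )
        A = np.where(A <= 0, zero_sub, A)
        A = A / A.sum(axis=1, keepdims=True)
    return classes, U, A


def compositional_analysis(
    samples: list[HabitatUseAvail],
    zero_sub: float = 0.01,
    reference: str = "Water",
    n_permutations: int = 0,
    seed=None,
) -> CompositionalResult:
    """Compositional analysis of habitat selection across animals.

    Each animal is one sample.  Zero use proportions are replaced by
    ``zero_sub`` and rows renormalized before the log-ratio transform.
    Wilks' lambda is the ratio det(W)/det(T) of the mean-centered to the
    raw cross-product matrix of the per-animal log-ratio differences; the
    statistic and ranking are invariant to the choice of reference class.
    If the cross-products are singular (too few animals for the number of
    classes) only the ranking is returned, with a warning.
    """
    if len(samples) < 2:
        raise ValueError("compositional_analysis: need >= 2 animals")
    classes, U, A = _prepare_matrix(samples, zero_sub)
    if len(classes) < 2:
        raise ValueError("compositional_analysis: need >= 2 habitat classes")
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} not among {classes}")
    N, D = U.shape
    Y = np.log(U) - np.log(A)          # per-animal log(use/avail), all classes
    ref = classes.index(reference)
    others = [j for j in range(D) if j != ref]
    d = Y[:, others] - Y[:, [ref]]     # (N, D-1) log-ratio differences

    # pairwise preference matrix: t of mean[ln(u_i/u_j) - ln(a_i/a_j)]
    tmat = pd.DataFrame(np.zeros((D, D)), index=classes, columns=classes)
    for i in range(D):
        for j in range(D):
            if i == j:
                continue
            diff = Y[:, i] - Y[:, j]
            sd = diff.std(ddof=1)
            mean = diff.mean()
            if sd == 0:
                t = 0.0 if mean == 0 else np.sign(mean) * np.inf
            else:
                t = mean / (sd / np.sqrt(N))
            tmat.iloc[i, j] = t
    wins = (tmat.to_numpy() > 0).sum(axis=1)
    mean_lr = Y.mean(axis=0)
    score = pd.Series(wins + 1e-9 * (mean_lr - mean_lr.min()), index=classes)
    ranking = list(score.sort_values(ascending=False).index)

    df_stat = D - 1
    warn_msg = None
    if np.allclose(d, 0.0):
        lam, chi2, p = 1.0, 0.0, 1.0
    else:
        T = d.T @ d
        W = (d - d.mean(axis=0)).T @ (d - d.mean(axis=0))
        detT = np.linalg.det(T)
        detW = np.linalg.det(W)
        if N - 1 < df_stat or detT <= 0 or detW < 0:
            warn_msg = (
                "singular cross-products (need more animals than habitat "
                "classes minus one); reporting rank-only output"
            )
            warnings.warn(f"compositional_analysis: {warn_msg}")
            lam = chi2 = p = None
        else:
            lam = float(detW / detT)
            lam = min(max(lam, np.finfo(float).tiny), 1.0)
            chi2 = float(-N * np.log(lam))
            p = float(stats.chi2.sf(chi2, df_stat))

    p_perm = None
    if n_permutations > 0 and lam is not None:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=(N, 1))
            dp = d * signs
            Tp = dp.T @ dp
            Wp = (dp - dp.mean(axis=0)).T @ (dp - dp.mean(axis=0))
            lp = np.linalg.det(Wp) / np.linalg.det(Tp)
            if lp <= lam:
                count += 1
        p_perm = (count + 1) / (n_permutations + 1)

    return CompositionalResult(
        wilks_lambda=lam,
        chi_square=chi2,
        df=df_stat,
        p_value=p,
        pairwise_t=tmat,
        ranking=ranking,
        rank_scores=pd.Series(wins, index=classes),
        p_permutation=p_perm,
        warning=warn_msg,
    )


# ---------------------------------------------------------------------------
# Ivlev's electivity
# ---------------------------------------------------------------------------

def ivlev_index(sample: HabitatUseAvail) -> IvlevResult:
    """Ivlev's electivity E = (u - a)/(u + a); NaN where u + a = 0."""
    u = sample.use
    a = sample.availability
    denom = u + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (u - a) / denom
    e = e.where(denom > 0, np.nan)
    return IvlevResult(animal_id=sample.animal_id, electivity=e)
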