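"""Temporal levels and age calibration of a composite sequence.

Adjacent events whose order the data cannot resolve (swapping them is
feasible and changes the total penalty by exactly zero) are merged into
discrete temporal levels; each level is a cluster of imputed contemporaneous
datums and the unit of the imputed temporal resolution.

Level ranks are then mapped to numeric ages (Ma) with a cubic smoothing
spline fitted through marker datums — events with externally assigned ages
(index-species appearances, magnetochron boundaries).  The smoothing penalty
is chosen by leave-one-out cross-validation on a log-spaced grid, the fit is
projected to monotone non-increasing ages (younger upward) by isotonic
regression, and ages beyond the first/last marker extrapolate linearly from
the boundary slope.  Uncertainty comes from resampling markers with
replacement and refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import isotonic_regression

from . import penalty as P
from .dataset import FAD, LAD
from .penalty import AdjacentSwap, CompositeSequence, Problem

logger = logging.getLogger("stratseq")

# smoothing penalties live on the scale of (rank span)^3; the dimensionless
# grid runs from near-interpolation to the straight-line limit
DEFAULT_CV_GRID_RELATIVE = np.logspace(-8.0, 2.0, 17)


def default_cv_grid(rank_span: float) -> np.ndarray:
    return DEFAULT_CV_GRID_RELATIVE * max(rank_span, 1.0) ** 3


# ---------------------------------------------------------------------------
# Level clustering
# ---------------------------------------------------------------------------

def cluster_levels(seq: CompositeSequence, problem: Problem,
                   merge: bool = True) -> list[list[int]]:
    """Group adjacent events into temporal levels, oldest first.

    Two adjacent events merge when swapping them is feasible and leaves the
    total penalty unchanged; merging is transitive along runs of such pairs.
    With ``merge=False`` every event is its own level.
    """
    if seq.section_penalties is None:
        P.total_penalty(seq, problem)
    order = seq.order
    if not merge:
        return [[int(e)] for e in order]
    levels: list[list[int]] = [[int(order[0])]]
    for i in range(order.size - 1):
        res = P.delta_penalty(seq, AdjacentSwap(i), problem)
        mergeable = res is not None and abs(res[0]) <= 1e-9
        if mergeable:
            levels[-1].append(int(order[i + 1]))
        else:
            levels.append([int(order[i + 1])])
    return levels


def level_of_event(levels: list[list[int]], n_events: int) -> np.ndarray:
    """Map event id -> level rank (0 = oldest)."""
    out = np.full(n_events, -1, dtype=np.int64)
    for k, lev in enumerate(levels):
        for e in lev:
            out[e] = k
    return out


def imputed_resolution(span_myr: float, n_levels: int) -> float:
    """Imputed temporal resolution in Kyr per level: span*1000/levels."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if span_myr <= 0:
        raise ValueError("span must be positive")
    return span_myr * 1000.0 / n_levels


# ---------------------------------------------------------------------------
# Markers and the age model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    """A dated event: ``kind`` is FAD, LAD or ``chron``; chron boundaries are
    carried as pseudo-taxa whose FAD and LAD sit at the boundary level."""

    kind: str
    name: str   # taxon_id, or chron boundary id
    age_ma: float

    def event(self, problem: Problem) -> int:
        kind = FAD if self.kind in (FAD, "chron") else LAD
        return problem.event_of(self.name, kind)


@dataclass
class MarkerSet:
    entries: list[Marker]

    def __post_init__(self) -> None:
        if any(m.age_ma <= 0 for m in self.entries):
            raise ValueError("marker ages must be positive (Ma)")

    def __len__(self) -> int:
        return len(self.entries)

    def ranks_and_ages(self, levels: list[list[int]], problem: Problem):
        lev = level_of_event(levels, problem.n_events)
        ranks = np.array([lev[m.event(problem)] for m in self.entries], dtype=float)
        ages = np.array([m.age_ma for m in self.entries], dtype=float)
        return ranks, ages


def read_markers(path) -> MarkerSet:
    df = pd.read_csv(path)
    need = {"kind", "name", "age_ma"}
    if need - set(df.columns):
        raise ValueError(f"marker file must have columns {sorted(need)}")
    return MarkerSet([Marker(str(r.kind), str(r.name), float(r.age_ma))
                      for r in df.itertuples()])


def write_markers(ms: MarkerSet, path) -> None:
    pd.DataFrame([m.__dict__ for m in ms.entries]).to_csv(path, index=False)


@dataclass
class AgeModel:
    """Ages (Ma) per composite level; non-increasing with level rank."""

    level_ages: np.ndarray
    lam: float
    marker_ranks: np.ndarray
    marker_ages: np.ndarray
    extrapolated: np.ndarray = None       # bool mask of levels outside marker span
    envelope_lo: np.ndarray | None = None  # 2.5th percentile ages
    envelope_hi: np.ndarray | None = None  # 97.5th
    boot_level_ages: np.ndarray | None = None  # (n_boot, n_levels) replicates

    @property
    def n_levels(self) -> int:
        return int(self.level_ages.size)

    @property
    def span_myr(self) -> float:
        return float(self.level_ages[0] - self.level_ages[-1])

    def event_age(self, level_rank: int) -> tuple[float, float]:
        """(midpoint, half-width) from the bootstrap envelope at one level."""
        if self.envelope_lo is None:
            return float(self.level_ages[level_rank]), 0.0
        lo = float(self.envelope_lo[level_rank])
        hi = float(self.envelope_hi[level_rank])
        return (lo + hi) / 2.0, (hi - lo) / 2.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"level": np.arange(self.n_levels),
                           "age_ma": self.level_ages})
        if self.envelope_lo is not None:
            df["age_lo"] = self.envelope_lo
            df["age_hi"] = self.envelope_hi
        if self.extrapolated is not None:
            df["extrapolated"] = self.extrapolated
        return df


def _curvature_penalty(x: np.ndarray) -> np.ndarray:
    """Green--Silverman penalty matrix K with f'Kf = integral of f''^2 for
    the natural cubic interpolant through (x, f)."""
    h = np.diff(x)
    n = x.size
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    C = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        C[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            C[i, i + 1] = C[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(C, D)


def _smoother(x: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Hat matrix of the weighted cubic smoothing spline at the knots.

    Minimises sum w_i (y_i - f_i)^2 + lam * integral f''^2, the same
    objective as scipy's ``make_smoothing_spline``; solved densely, which at
    marker-set sizes is faster than the banded route and exposes the hat
    diagonal needed for exact leave-one-out errors.
    """
    K = _curvature_penalty(x)
    W = np.diag(w)
    return np.linalg.solve(W + lam * K, W)


def _spline_predict(x: np.ndarray, y: np.ndarray, lam: float,
                    xq: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Smoothing-spline fit with linear extrapolation beyond the data span."""
    if w is None:
        w = np.ones_like(x)
    if x.size >= 3:
        f = _smoother(x, w, lam) @ y
        fn = CubicSpline(x, f, bc_type="natural")
        dfn = fn.derivative()
    else:
        coef = np.polyfit(x, y, deg=min(1, x.size - 1), w=np.sqrt(w))
        fn = np.poly1d(coef)
        dfn = np.polyder(np.poly1d(coef))
    out = np.asarray(fn(np.clip(xq, x[0], x[-1])), dtype=float)
    left = xq < x[0]
    right = xq > x[-1]
    if left.any():
        out[left] = float(fn(x[0])) + float(dfn(x[0])) * (xq[left] - x[0])
    if right.any():
        out[right] = float(fn(x[-1])) + float(dfn(x[-1])) * (xq[right] - x[-1])
    return out


def _dedupe(ranks: np.ndarray, ages: np.ndarray):
    """Collapse markers sharing a level to their mean age, keeping the
    multiplicity as a least-squares weight; sorted by rank."""
    df = (pd.DataFrame({"r": ranks, "a": ages})
          .groupby("r", sort=True)["a"].agg(["mean", "count"]))
    return (df.index.to_numpy(dtype=float), df["mean"].to_numpy(dtype=float),
            df["count"].to_numpy(dtype=float))


def _loo_errors(x: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Exact leave-one-out squared errors via the hat diagonal."""
    S = _smoother(x, w, lam)
    f = S @ y
    denom = np.clip(1.0 - np.diag(S), 1e-10, None)
    return ((y - f) / denom) ** 2


def _select_lambda(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   grid: np.ndarray) -> tuple[float, np.ndarray]:
    """Leave-one-out CV with the one-standard-error rule.

    Plain argmin over a lambda grid is noisy at marker-set sizes; the 1-SE
    rule (largest lambda whose CV error is within one standard error of the
    minimum) is the standard stabiliser and errs toward smoother age models.
    """
    errs = [_loo_errors(x, y, w, lam) for lam in grid]
    means = np.array([e.mean() for e in errs])
    k_min = int(np.argmin(means))
    se = errs[k_min].std(ddof=1) / np.sqrt(errs[k_min].size)
    ok = means <= means[k_min] + se
    return float(grid[np.nonzero(ok)[0].max()]), means


def _monotone_fit(x: np.ndarray, y: np.ndarray, lam: float,
                  xq: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Spline prediction projected to non-increasing ages (younger upward)."""
    pred = _spline_predict(x, y, lam, xq, w=w)
    iso = isotonic_regression(-pred, increasing=True)
    return -np.asarray(iso.x, dtype=float)


def fit_age_curve(ranks: np.ndarray, ages: np.ndarray, n_levels: int,
                  cv_grid: np.ndarray | None = None,
                  monotone_tol: float = 1e-9) -> AgeModel:
    """Fit age ~ rank through dated points; LOO-CV smoothing; isotonic ages."""
    x, y, w = _dedupe(np.asarray(ranks, dtype=float), np.asarray(ages, dtype=float))
    if x.size < 4:
        raise ValueError(
            f"need markers in >=4 distinct levels to fit an age model, got {x.size}"
        )
    inversions = [(float(x[i]), float(y[i])) for i in range(1, x.size)
                  if y[i] > y[i - 1] + monotone_tol]
    if inversions:
        logger.warning("markers violate monotone age order at ranks: %s",
                       [r for r, _ in inversions])
    grid = (default_cv_grid(float(x[-1] - x[0])) if cv_grid is None
            else np.asarray(cv_grid, dtype=float))
    lam, _ = _select_lambda(x, y, w, grid)
    xq = np.arange(n_levels, dtype=float)
    level_ages = _monotone_fit(x, y, lam, xq, w=w)
    extrap = (xq < x[0]) | (xq > x[-1])
    return AgeModel(level_ages=level_ages, lam=lam, marker_ranks=x,
                    marker_ages=y, extrapolated=extrap)


def fit_age_model(levels: list[list[int]], markers: MarkerSet, problem: Problem,
                  cv_grid: np.ndarray | None = None,
                  monotone_tol: float = 1e-9) -> AgeModel:
    """Fit the age model through a composite's marker datums."""
    ranks, ages = markers.ranks_and_ages(levels, problem)
    return fit_age_curve(ranks, ages, len(levels), cv_grid=cv_grid,
                         monotone_tol=monotone_tol)


def bootstrap_age_curve(ranks: np.ndarray, ages: np.ndarray, n_levels: int,
                        n_boot: int = 1000, seed: int = 0,
                        cv_grid: np.ndarray | None = None,
                        max_redraws: int = 100) -> AgeModel:
    """Marker-resampling bootstrap envelope around the fitted age model.

    Each replicate resamples dated points with replacement (duplicates enter
    the refit as least-squares weights) and re-runs the cross-validated
    smoothing-parameter selection, so the envelope reflects both sampling and
    smoothing-selection uncertainty; degenerate draws (<4 distinct levels)
    are redrawn and counted.  The 2.5/97.5 percentile envelope is widened,
    if needed, to bracket the point estimate.
    """
    ranks = np.asarray(ranks, dtype=float)
    ages = np.asarray(ages, dtype=float)
    model = fit_age_curve(ranks, ages, n_levels, cv_grid=cv_grid)
    rng = np.random.default_rng(seed)
    xq = np.arange(n_levels, dtype=float)
    reps = np.empty((n_boot, xq.size))
    n_redraw = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, ranks.size, ranks.size)
            x, y, w = _dedupe(ranks[idx], ages[idx])
            if x.size >= 4:
                break
            n_redraw += 1
        else:
            raise RuntimeError("bootstrap: could not draw >=4 distinct marker levels")
        grid_b = (default_cv_grid(float(x[-1] - x[0])) if cv_grid is None
                  else np.asarray(cv_grid, dtype=float))
        lam_b, _ = _select_lambda(x, y, w, grid_b)
        reps[b] = _monotone_fit(x, y, lam_b, xq, w=w)
    if n_redraw:
        logger.info("bootstrap_age_curve: %d degenerate resamples redrawn", n_redraw)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    model.envelope_lo = np.minimum(lo, model.level_ages)
    model.envelope_hi = np.maximum(hi, model.level_ages)
    model.boot_level_ages = reps
    return model


def bootstrap_age_model(levels: list[list[int]], markers: MarkerSet,
                        problem: Problem, n_boot: int = 1000,
                        seed: int = 0, cv_grid: np.ndarray | None = None,
                        max_redraws: int = 100) -> AgeModel:
    """Bootstrap envelope for a composite's marker-calibrated age model."""
    ranks, ages = markers.ranks_and_ages(levels, problem)
    return bootstrap_age_curve(ranks, ages, len(levels), n_boot=n_boot,
                               seed=seed, cv_grid=cv_grid, max_redraws=max_redraws)
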