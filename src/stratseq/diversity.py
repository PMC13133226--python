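"""Richness and turnover statistics from a calibrated composite.

Richness is counted without binning: at every composite level, standing
richness is the number of taxa whose composite range (FAD level .. LAD level,
inclusive) spans that level, equivalently the running sum of FADs at or below
the level minus LADs strictly below it.  Genus richness collapses congeneric
ranges (earliest FAD to latest LAD).  Proportional origination/extinction
rates use a binned approach: events per standing lineage per Myr inside bins
of fixed width (0.2 Myr by default), where the denominator counts every taxon
whose age range intersects the bin.  Rarefaction draws occurrences without
replacement to control for sampling effort, and bootstrap envelopes propagate
age-model uncertainty by recomputing each series under every bootstrap
replicate of the age model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import AgeModel, level_of_event
from .dataset import StratDataset
from .penalty import Problem, event_id
from .dataset import FAD, LAD

logger = logging.getLogger("stratseq")


# ---------------------------------------------------------------------------
# Composite ranges on levels
# ---------------------------------------------------------------------------

def taxon_level_ranges(levels: list[list[int]], problem: Problem,
                       group: str | None = None) -> pd.DataFrame:
    """Per-taxon (FAD level, LAD level) plus genus/group metadata.

    ``group`` filters to one ecological group (PF/LBF/SBF); None keeps all.
    """
    lev = level_of_event(levels, problem.n_events)
    rows = []
    for t, tid in enumerate(problem.taxon_ids):
        taxon = problem.ds.taxa[tid]
        if group is not None and taxon.group != group:
            continue
        rows.append({
            "taxon": tid,
            "genus": taxon.genus,
            "group": taxon.group,
            "fad_level": int(lev[event_id(t, FAD)]),
            "lad_level": int(lev[event_id(t, LAD)]),
        })
    return pd.DataFrame(rows)


def _running_richness(fad_levels: np.ndarray, lad_levels: np.ndarray,
                      n_levels: int) -> np.ndarray:
    """richness_k = #(FAD <= k) - #(LAD < k), vectorised as a running sum."""
    delta = np.zeros(n_levels + 1, dtype=np.int64)
    np.add.at(delta, fad_levels, 1)
    np.add.at(delta, lad_levels + 1, -1)
    return np.cumsum(delta)[:n_levels]


def unbinned_richness(levels: list[list[int]], problem: Problem,
                      group: str | None = None,
                      age_model: AgeModel | None = None) -> pd.DataFrame:
    """Species and genus richness (plus their ratio) at every level."""
    n_levels = len(levels)
    rng_df = taxon_level_ranges(levels, problem, group=group)
    if rng_df.empty:
        raise ValueError(f"no taxa in group {group!r}")
    sp = _running_richness(rng_df["fad_level"].to_numpy(),
                           rng_df["lad_level"].to_numpy(), n_levels)
    named = rng_df[rng_df["genus"] != ""]
    n_unnamed = len(rng_df) - len(named)
    if n_unnamed:
        logger.info("genus richness: %d taxa without genus excluded", n_unnamed)
    out = pd.DataFrame({"level": np.arange(n_levels), "richness": sp})
    if not named.empty:
        gen = named.groupby("genus").agg(fad_level=("fad_level", "min"),
                                         lad_level=("lad_level", "max"))
        ge = _running_richness(gen["fad_level"].to_numpy(),
                               gen["lad_level"].to_numpy(), n_levels)
        out["genus_richness"] = ge
        out["species_genus_ratio"] = np.where(ge > 0, sp / np.maximum(ge, 1), np.nan)
    if age_model is not None:
        out["age_ma"] = age_model.level_ages
    return out


# ---------------------------------------------------------------------------
# Binned proportional rates
# ---------------------------------------------------------------------------

def binned_rates(fad_ages: np.ndarray, lad_ages: np.ndarray,
                 bin_width: float = 0.2,
                 denominator: str = "range-through") -> pd.DataFrame:
    """Proportional origination/extinction/turnover/net rates per age bin.

    Ages are in Ma (decreasing toward the present; FAD age >= LAD age).  For
    a bin b of width dt: D_b counts taxa whose [LAD age, FAD age] interval
    intersects b ("range-through" denominator) or only those crossing a bin
    boundary ("crossers"); O_b and E_b count FADs and LADs dated inside b.
    origination = O_b/(D_b*dt), extinction = E_b/(D_b*dt) (per lineage-Myr);
    turnover is their sum and net diversification their difference.  Bins
    with D_b = 0 are emitted as missing.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    fad_ages = np.asarray(fad_ages, dtype=float)
    lad_ages = np.asarray(lad_ages, dtype=float)
    if np.any(fad_ages < lad_ages):
        raise ValueError("FAD ages must be >= LAD ages (Ma decrease upward)")
    old = float(fad_ages.max())
    young = float(lad_ages.min())
    n_bins = max(int(np.ceil((old - young) / bin_width - 1e-9)), 1)
    edges = old - bin_width * np.arange(n_bins + 1)  # descending, edges[0]=oldest
    rows = []
    for b in range(n_bins):
        hi, lo = edges[b], edges[b + 1]  # hi = older edge
        in_bin_fad = (fad_ages <= hi + 1e-12) & (fad_ages > lo + 1e-12) if b < n_bins - 1 \
            else (fad_ages <= hi + 1e-12) & (fad_ages >= lo - 1e-12)
        in_bin_lad = (lad_ages <= hi + 1e-12) & (lad_ages > lo + 1e-12) if b < n_bins - 1 \
            else (lad_ages <= hi + 1e-12) & (lad_ages >= lo - 1e-12)
        intersects = (fad_ages > lo + 1e-12) & (lad_ages <= hi + 1e-12) if b < n_bins - 1 \
            else (fad_ages >= lo - 1e-12) & (lad_ages <= hi + 1e-12)
        if denominator == "range-through":
            D = int(intersects.sum())
        elif denominator == "crossers":
            D = int(((fad_ages > hi) & (lad_ages <= hi)).sum())
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        O = int(in_bin_fad.sum())
        E = int(in_bin_lad.sum())
        if D == 0:
            rows.append({"bin_old": hi, "bin_young": lo, "bin_mid": (hi + lo) / 2,
                         "n_lineages": 0, "n_orig": O, "n_ext": E,
                         "origination": np.nan, "extinction": np.nan,
                         "turnover": np.nan, "net_diversification": np.nan})
            continue
        orig = O / (D * bin_width)
        ext = E / (D * bin_width)
        rows.append({"bin_old": hi, "bin_young": lo, "bin_mid": (hi + lo) / 2,
                     "n_lineages": D, "n_orig": O, "n_ext": E,
                     "origination": orig, "extinction": ext,
                     "turnover": orig + ext, "net_diversification": orig - ext})
    return pd.DataFrame(rows)


def rates_from_model(levels: list[list[int]], problem: Problem,
                     age_model: AgeModel, bin_width: float = 0.2,
                     group: str | None = None,
                     denominator: str = "range-through") -> pd.DataFrame:
    rng_df = taxon_level_ranges(levels, problem, group=group)
    fad_ages = age_model.level_ages[rng_df["fad_level"].to_numpy()]
    lad_ages = age_model.level_ages[rng_df["lad_level"].to_numpy()]
    return binned_rates(fad_ages, lad_ages, bin_width=bin_width,
                        denominator=denominator)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(counts, n: int, iters: int = 1000, seed: int = 0):
    """Rarefied richness: mean and 95% CI over ``iters`` subsamples of size n.

    ``counts`` are occurrence counts per taxon within one analysis bin.
    Returns ``(mean, lo, hi)``; all NaN (with a warning) when n exceeds the
    pooled occurrence total.
    """
    counts = np.asarray(list(counts), dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if n > N:
        logger.warning("rarefy: n=%d exceeds pooled occurrences N=%d", n, N)
        return float("nan"), float("nan"), float("nan")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(counts.size), counts)
    s = np.empty(iters, dtype=np.int64)
    for i in range(iters):
        draw = rng.choice(pool, size=n, replace=False)
        s[i] = np.unique(draw).size
    return float(s.mean()), float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5))


def rarefied_series(ds: StratDataset, levels: list[list[int]], problem: Problem,
                    age_model: AgeModel, sample_size: int,
                    bin_width: float = 0.2, iters: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Rarefied richness per age bin, pooling occurrences by occurrence-level age.

    Each occurrence is dated by interpolating its section level between the
    taxon's composite FAD/LAD ages — a crude but monotone dating sufficient
    for pooling into rarefaction bins.
    """
    rng_df = taxon_level_ranges(levels, problem).set_index("taxon")
    fad_age = age_model.level_ages[rng_df["fad_level"]]
    lad_age = age_model.level_ages[rng_df["lad_level"]]
    ages_of = dict(zip(rng_df.index, zip(fad_age, lad_age)))
    occ_taxon, occ_age = [], []
    for s in ds.sections:
        ranges = s.local_ranges()
        for tid, lvl in s.occurrences:
            lo, hi = ranges[tid]
            f, l = ages_of[tid]
            frac = 0.5 if hi == lo else (lvl - lo) / (hi - lo)
            occ_taxon.append(tid)
            occ_age.append(f + (l - f) * frac)
    occ = pd.DataFrame({"taxon": occ_taxon, "age": occ_age})
    old, young = occ["age"].max(), occ["age"].min()
    n_bins = max(int(np.ceil((old - young) / bin_width - 1e-9)), 1)
    edges = old - bin_width * np.arange(n_bins + 1)
    rows = []
    for b in range(n_bins):
        hi, lo = edges[b], edges[b + 1]
        sel = (occ["age"] <= hi + 1e-12) & ((occ["age"] > lo) if b < n_bins - 1
                                            else (occ["age"] >= lo - 1e-12))
        counts = occ.loc[sel, "taxon"].value_counts().to_numpy()
        mean, ci_lo, ci_hi = rarefy(counts, sample_size, iters=iters,
                                    seed=seed + b) if counts.size else (np.nan,) * 3
        rows.append({"bin_mid": (hi + lo) / 2, "n_occurrences": int(counts.sum()) if counts.size else 0,
                     "raw_richness": int(counts.size),
                     "rarefied_mean": mean, "lo": ci_lo, "hi": ci_hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap envelopes via the age model
# ---------------------------------------------------------------------------

def bootstrap_richness(levels: list[list[int]], problem: Problem,
                       age_model: AgeModel, age_grid: np.ndarray,
                       group: str | None = None) -> pd.DataFrame:
    """Richness on a common age grid with an age-model bootstrap envelope.

    Level-wise richness is fixed by the composite; only the level->age map
    varies across bootstrap replicates, so each replicate re-dates the same
    step curve and the pointwise 2.5/97.5 percentiles form the envelope.
    """
    if age_model.boot_level_ages is None:
        raise ValueError("age model carries no bootstrap replicates")
    rich = unbinned_richness(levels, problem, group=group)["richness"].to_numpy()
    grid = np.asarray(age_grid, dtype=float)

    def on_grid(level_ages: np.ndarray) -> np.ndarray:
        # step-function lookup: richness of the youngest level at least as
        # old; the 1e-6 Myr (~1 yr) tolerance keeps knife-edge ties stable
        # across bootstrap replicates
        asc_age = level_ages[::-1]
        asc_rich = rich[::-1]
        idx = np.searchsorted(asc_age, grid - 1e-6, side="left")
        idx = np.clip(idx, 0, rich.size - 1)
        return asc_rich[idx]

    point = on_grid(age_model.level_ages)
    reps = np.vstack([on_grid(r) for r in age_model.boot_level_ages])
    lo = np.minimum(np.percentile(reps, 2.5, axis=0), point)
    hi = np.maximum(np.percentile(reps, 97.5, axis=0), point)
    return pd.DataFrame({"age_ma": grid, "richness": point, "lo": lo, "hi": hi})


def bootstrap_rates(levels: list[list[int]], problem: Problem,
                    age_model: AgeModel, bin_width: float = 0.2,
                    group: str | None = None,
                    denominator: str = "range-through") -> pd.DataFrame:
    """Rate series with envelopes from the age-model bootstrap replicates."""
    if age_model.boot_level_ages is None:
        raise ValueError("age model carries no bootstrap replicates")
    point = rates_from_model(levels, problem, age_model, bin_width=bin_width,
                             group=group, denominator=denominator)
    rng_df = taxon_level_ranges(levels, problem, group=group)
    fl = rng_df["fad_level"].to_numpy()
    ll = rng_df["lad_level"].to_numpy()
    cols = ["origination", "extinction", "turnover", "net_diversification"]
    acc = {c: [] for c in cols}
    for rep in age_model.boot_level_ages:
        df = binned_rates(rep[fl], rep[ll], bin_width=bin_width,
                          denominator=denominator)
        # align replicate bins to the point-estimate bins by midpoint lookup
        interp = {c: np.interp(point["bin_mid"], df["bin_mid"][::-1],
                               df[c].to_numpy()[::-1]) for c in cols}
        for c in cols:
            acc[c].append(interp[c])
    for c in cols:
        reps = np.vstack(acc[c])
        point[f"{c}_lo"] = np.nanpercentile(reps, 2.5, axis=0)
        point[f"{c}_hi"] = np.nanpercentile(reps, 97.5, axis=0)
    return point


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def minmax_normalize(series) -> np.ndarray:
    """Rescale to [0, 1]; errors on constant input."""
    x = np.asarray(series, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if not hi > lo:
        raise ValueError("cannot min-max normalise a constant series")
    return (x - lo) / (hi - lo)
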