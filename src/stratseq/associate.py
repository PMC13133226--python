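"""Association between richness series and environmental proxy series.

Series are linearly interpolated onto a shared age grid over their overlap,
compared with Spearman's rank correlation (two-tailed p via the t
approximation; percentile bootstrap CI from resampling index pairs), with
optional linear detrending against age, and screened for multicollinearity
with variance inflation factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("stratseq")

P_FLOOR = 2.2e-308  # smallest honestly reportable two-tailed p


@dataclass
class ProxySeries:
    """An environmental proxy sampled along age (Ma)."""

    name: str
    ages: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.size < 3:
            raise ValueError(f"proxy {self.name!r}: needs >=3 points")
        d = np.diff(self.ages)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(f"proxy {self.name!r}: ages must be strictly monotone")
        if np.any(d < 0):  # store ascending
            self.ages = self.ages[::-1].copy()
            self.values = self.values[::-1].copy()

    @classmethod
    def read(cls, path, name: str | None = None, units: str = "") -> "ProxySeries":
        df = pd.read_csv(path)
        if {"age_ma", "value"} - set(df.columns):
            raise ValueError("proxy file must have columns age_ma,value")
        return cls(name or str(path), df["age_ma"].to_numpy(), df["value"].to_numpy(),
                   units=units)

    def write(self, path) -> None:
        pd.DataFrame({"age_ma": self.ages, "value": self.values}).to_csv(path, index=False)


@dataclass
class CorrelationResult:
    rho: float
    p: float
    ci: tuple[float, float]
    n: int
    detrended: bool = False
    p_floored: bool = False

    def as_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "ci_lo": self.ci[0],
                "ci_hi": self.ci[1], "n": self.n, "detrended": self.detrended,
                "p_floored": self.p_floored}


def align(ages_a, values_a, ages_b, values_b, grid_step: float = 0.2):
    """Interpolate two series onto a shared grid over their age overlap.

    Returns ``(grid_ages, x, y)``; pairs where either side is missing are
    dropped.  Errors when the overlap is shorter than two grid steps.
    """
    a_age = np.asarray(ages_a, dtype=float)
    b_age = np.asarray(ages_b, dtype=float)
    av = np.asarray(values_a, dtype=float)
    bv = np.asarray(values_b, dtype=float)
    for arr_age in (a_age, b_age):
        if np.any(np.diff(arr_age) < 0):
            raise ValueError("ages must be ascending; use ProxySeries for auto-sorting")
    lo = max(a_age.min(), b_age.min())
    hi = min(a_age.max(), b_age.max())
    if hi - lo < 2 * grid_step:
        raise ValueError(f"age overlap [{lo:.3f}, {hi:.3f}] shorter than two grid steps")
    grid = lo + grid_step * np.arange(int(np.floor((hi - lo) / grid_step + 1e-9)) + 1)
    x = np.interp(grid, a_age, av)
    y = np.interp(grid, b_age, bv)
    keep = np.isfinite(x) & np.isfinite(y)
    return grid[keep], x[keep], y[keep]


def _rank_rho_rows(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """Pearson correlation of pre-ranked rows (vectorised over axis 0)."""
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def spearman(x, y, n_boot: int = 10000, seed: int = 0) -> CorrelationResult:
    """Spearman rho with two-tailed p and a paired percentile bootstrap CI.

    Ties receive average ranks.  The CI resamples index pairs i.i.d. with
    replacement, ``n_boot`` times, and takes the 2.5th/97.5th percentiles.
    P-values below the reportable floor are clamped and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p = float(res.pvalue)
    floored = p < P_FLOOR
    p = max(p, P_FLOOR)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xr = stats.rankdata(x[idx], axis=1)
    yr = stats.rankdata(y[idx], axis=1)
    rhos = _rank_rho_rows(xr, yr)
    rhos = rhos[np.isfinite(rhos)]
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return CorrelationResult(rho=rho, p=p, ci=(float(lo), float(hi)), n=n,
                             p_floored=floored)


def detrend_linear(ages, values) -> np.ndarray:
    """Residuals of the least-squares line of value on age (zero mean/slope)."""
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    if a.size < 3:
        raise ValueError("need >=3 points to detrend")
    coef = np.polyfit(a, v, 1)
    return v - np.polyval(coef, a)


def vif_screen(proxies: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor of each proxy regressed on the others.

    VIF_j = 1/(1-R²_j); proxies above ``threshold`` are flagged excluded;
    perfect collinearity reports an infinite VIF.
    """
    cols = list(proxies.columns)
    if len(cols) < 2:
        raise ValueError("need >=2 aligned proxies")
    X = proxies.to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(X.shape[0]), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"proxy": name, "r_squared": r2, "vif": vif,
                     "excluded": bool(vif > threshold)})
    return pd.DataFrame(rows)


def correlation_table(richness_age, richness_val, proxies: list[ProxySeries],
                      grid_step: float = 0.2, n_boot: int = 10000,
                      seed: int = 0, detrend: bool = False) -> pd.DataFrame:
    """Richness-vs-proxy correlations in a one-row-per-proxy table."""
    rows = []
    ra = np.asarray(richness_age, dtype=float)
    rv = np.asarray(richness_val, dtype=float)
    if np.any(np.diff(ra) < 0):
        rv = rv[np.argsort(ra)]
        ra = np.sort(ra)
    for k, pr in enumerate(proxies):
        grid, x, y = align(ra, rv, pr.ages, pr.values, grid_step=grid_step)
        if detrend:
            x = detrend_linear(grid, x)
            y = detrend_linear(grid, y)
        res = spearman(x, y, n_boot=n_boot, seed=seed + k)
        row = {"proxy": pr.name, **res.as_dict(), "detrended": detrend}
        rows.append(row)
    return pd.DataFrame(rows)
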