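"""Synthetic worlds with known truth for closed-loop testing.

The generator emulates the structure of the real problem: taxa with true
ranges on an absolute age axis (constant-rate birth--death: origination ages
uniform over the study span, durations exponential), sections that sample
random time windows with incomplete per-level preservation (so every local
observed range is contained in the true range), marker datums that carry true
ages for the best-sampled taxa, and an environmental proxy coupled to true
richness plus AR(1) noise.  It deliberately omits facies control, geographic
endemism and taphonomic gradients; what passing recovery tests show is that
the inference machinery is correct under honest incomplete sampling, not that
real data meet these assumptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associate import ProxySeries
from .calibrate import Marker, MarkerSet
from .dataset import FAD, LAD, GROUPS, Section, StratDataset, Taxon
from .diversity import minmax_normalize

logger = logging.getLogger("stratseq")


@dataclass
class SyntheticWorld:
    """True ranges plus everything derived from them."""

    orig_age: np.ndarray          # Ma, per taxon (older = larger)
    ext_age: np.ndarray           # Ma, per taxon; orig_age > ext_age
    taxon_ids: list[str]
    genera: list[str]
    groups: list[str]
    span: tuple[float, float]     # (old edge, young edge) in Ma
    seed: int
    dataset: StratDataset | None = None
    markers: MarkerSet | None = None
    proxy: ProxySeries | None = None
    section_level_ages: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_taxa(self) -> int:
        return int(self.orig_age.size)

    def true_event_ages(self) -> dict[tuple[str, str], float]:
        out = {}
        for i, tid in enumerate(self.taxon_ids):
            out[(tid, FAD)] = float(self.orig_age[i])
            out[(tid, LAD)] = float(self.ext_age[i])
        return out

    def true_event_order(self) -> list[tuple[str, str]]:
        """All FAD/LAD events sorted oldest to youngest by true age."""
        ev = list(self.true_event_ages().items())
        ev.sort(key=lambda kv: (-kv[1], kv[0]))
        return [k for k, _ in ev]

    def true_richness(self, ages) -> np.ndarray:
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        return ((self.orig_age[None, :] >= a[:, None]) &
                (self.ext_age[None, :] <= a[:, None])).sum(axis=1)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon": self.taxon_ids, "genus": self.genera, "group": self.groups,
            "orig_age_ma": self.orig_age, "ext_age_ma": self.ext_age,
        })


def simulate_ranges(n_taxa: int, span: tuple[float, float] = (48.0, 20.0),
                    orig_rate: float = 1.0, ext_rate: float = 0.25,
                    seed: int = 0, taxa_per_genus: int = 3,
                    max_regen: int = 50) -> SyntheticWorld:
    """Draw true taxon ranges from a constant-rate birth--death process.

    Conditioned on ``n_taxa``, constant-rate origination makes origination
    ages uniform over the span (``orig_rate`` is kept for API symmetry and
    future inhomogeneous variants); durations are exponential with mean
    ``1/ext_rate`` Myr, clipped at the young edge of the span.
    """
    if orig_rate <= 0 or ext_rate <= 0:
        raise ValueError("rates must be > 0")
    old, young = span
    if old <= young:
        raise ValueError("span must be (older, younger) in Ma")
    rng = np.random.default_rng(seed)
    for attempt in range(max_regen):
        orig = old - rng.uniform(0.0, old - young, size=n_taxa)
        dur = rng.exponential(1.0 / ext_rate, size=n_taxa)
        ext = np.maximum(orig - dur, young)
        ok = (orig - ext) > 1e-9
        if ok.all():
            break
        logger.warning("simulate_ranges: %d degenerate ranges, regenerating",
                       int((~ok).sum()))
    else:
        raise RuntimeError("could not generate positive-duration ranges")
    order = np.argsort(-orig, kind="stable")
    orig, ext = orig[order], ext[order]
    ids = [f"t{i:03d}" for i in range(n_taxa)]
    genera = [f"G{i // taxa_per_genus:02d}" for i in range(n_taxa)]
    groups = [GROUPS[i % 3] for i in range(n_taxa)]  # PF/LBF/SBF round-robin
    return SyntheticWorld(orig_age=orig, ext_age=ext, taxon_ids=ids,
                          genera=genera, groups=groups, span=span, seed=seed)


def simulate_sections(world: SyntheticWorld, n_sections: int = 8,
                      levels_per_section: int = 20,
                      sampling_prob: float = 0.5, seed: int = 0,
                      min_window_frac: float = 0.35) -> StratDataset:
    """Sample sections: random time windows, stratified level ages, and
    per-(taxon, level) Bernoulli preservation.

    Heights grow upward with youth (1 height unit = 1 Myr below the window's
    old edge), so local observed event order always honours the true age
    order and every local range is contained in the true range.
    """
    if not (0 < sampling_prob <= 1):
        raise ValueError("sampling_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    old, young = world.span
    span_len = old - young
    sections = []
    for s in range(n_sections):
        w_len = rng.uniform(min_window_frac * span_len, span_len)
        w_old = rng.uniform(young + w_len, old)
        # stratified-uniform level ages inside the window, oldest first
        edges = np.linspace(w_old, w_old - w_len, levels_per_section + 1)
        level_ages = np.array([rng.uniform(edges[i + 1], edges[i])
                               for i in range(levels_per_section)])
        heights = w_old - level_ages  # ascending = younger upward
        world.section_level_ages[f"S{s:02d}"] = level_ages
        occ = set()
        for i, tid in enumerate(world.taxon_ids):
            extant = (world.orig_age[i] >= level_ages) & (level_ages >= world.ext_age[i])
            hit = extant & (rng.random(levels_per_section) < sampling_prob)
            for lvl in np.nonzero(hit)[0]:
                occ.add((tid, int(lvl) + 1))
        if not occ:
            logger.info("section S%02d sampled no taxa; dropped", s)
            continue
        sections.append(Section(f"S{s:02d}", heights, occ))
    if not sections:
        raise ValueError("no section sampled any taxon; increase sampling_prob")
    observed = set().union(*(s.taxa for s in sections))
    taxa = {tid: Taxon(tid, name=tid, genus=world.genera[i], group=world.groups[i])
            for i, tid in enumerate(world.taxon_ids) if tid in observed}
    ds = StratDataset(taxa=taxa, sections=sections)
    world.dataset = ds
    return ds


def make_markers(world: SyntheticWorld, k: int = 5) -> MarkerSet:
    """True-age markers for the k most-occurring taxa (the best constrained),
    analogous to picking index species."""
    if world.dataset is None:
        raise ValueError("simulate sections first")
    counts: dict[str, int] = {}
    for s in world.dataset.sections:
        for tid, _ in s.occurrences:
            counts[tid] = counts.get(tid, 0) + 1
    top = sorted(counts, key=lambda t: (-counts[t], t))[:k]
    entries = []
    for tid in top:
        i = world.taxon_ids.index(tid)
        entries.append(Marker(FAD, tid, float(world.orig_age[i])))
        entries.append(Marker(LAD, tid, float(world.ext_age[i])))
    return MarkerSet(entries)


def simulate_proxy(world: SyntheticWorld, coupling: float = 2.0,
                   ar_coefficient: float = 0.6, noise_sd: float = 0.3,
                   seed: int = 0, grid_step: float = 0.2) -> ProxySeries:
    """Proxy = coupling * minmax(true richness) + stationary AR(1) noise."""
    if not abs(ar_coefficient) < 1:
        raise ValueError("|ar_coefficient| must be < 1")
    rng = np.random.default_rng(seed)
    old, young = world.span
    ages = np.arange(young, old + 1e-9, grid_step)
    rich = world.true_richness(ages).astype(float)
    signal = coupling * minmax_normalize(rich) if np.ptp(rich) > 0 else np.zeros_like(rich)
    n = ages.size
    noise = np.empty(n)
    stat_sd = noise_sd / np.sqrt(1.0 - ar_coefficient ** 2)
    noise[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, noise_sd, size=n)
    for i in range(1, n):
        noise[i] = ar_coefficient * noise[i - 1] + eps[i]
    pr = ProxySeries("synthetic_proxy", ages, signal + noise)
    world.proxy = pr
    return pr


def simulate_world(n_taxa: int = 20, span: tuple[float, float] = (48.0, 20.0),
                   ext_rate: float = 0.25, n_sections: int = 8,
                   levels_per_section: int = 20, sampling_prob: float = 0.5,
                   n_markers: int = 5, coupling: float = 2.0,
                   ar_coefficient: float = 0.6, noise_sd: float = 0.3,
                   seed: int = 0) -> SyntheticWorld:
    """One-call world: ranges, sections, markers and proxy (sub-seeded)."""
    world = simulate_ranges(n_taxa, span=span, ext_rate=ext_rate, seed=seed)
    simulate_sections(world, n_sections=n_sections,
                      levels_per_section=levels_per_section,
                      sampling_prob=sampling_prob, seed=seed + 1)
    world.markers = make_markers(world, k=n_markers)
    simulate_proxy(world, coupling=coupling, ar_coefficient=ar_coefficient,
                   noise_sd=noise_sd, seed=seed + 2)
    return world
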