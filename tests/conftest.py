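"""Shared fixtures: hand-built datasets, synthetic worlds, and oracles."""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
import pytest

import stratseq as ss
from stratseq import penalty as P
from stratseq.dataset import Section, StratDataset, Taxon


def make_dataset(sections_spec, genera=None, groups=None, weights=None) -> StratDataset:
    """Build a dataset from {section_id: {taxon: [levels]}} plus heights=levels."""
    taxa = {}
    sections = []
    for sid, occs in sections_spec.items():
        n_levels = max(l for lvls in occs.values() for l in lvls)
        occ = set()
        for t, lvls in occs.items():
            if t not in taxa:
                taxa[t] = Taxon(t, name=t,
                                genus=(genera or {}).get(t, ""),
                                group=(groups or {}).get(t, "other"))
            for l in lvls:
                occ.add((t, l))
        sections.append(Section(sid, np.arange(1, n_levels + 1, dtype=float), occ,
                                weight=(weights or {}).get(sid, 1.0)))
    return StratDataset(taxa=taxa, sections=sections)


def random_small_instance(rng):
    """One random section with <=3 taxa (<=6 events) and <=6 levels."""
    n_taxa = int(rng.integers(1, 4))
    n_levels = int(rng.integers(2, 7))
    heights = np.sort(rng.uniform(0, 10, n_levels))
    heights += np.arange(n_levels) * 1e-3  # guarantee strictly increasing
    occ = set()
    for t in range(n_taxa):
        lo = int(rng.integers(1, n_levels + 1))
        hi = int(rng.integers(lo, n_levels + 1))
        occ.add((f"t{t}", lo))
        occ.add((f"t{t}", hi))
    taxa = {f"t{t}": Taxon(f"t{t}") for t in range(n_taxa)}
    return StratDataset(taxa=taxa, sections=[Section("S", heights, occ)])


def random_feasible_order(problem: P.Problem, rng) -> np.ndarray:
    """Uniform-ish random topological order of the FAD-before-LAD constraint DAG."""
    indeg = np.zeros(problem.n_events, dtype=int)
    succ = defaultdict(list)
    for f, l in zip(problem.c_fad, problem.c_lad):
        succ[int(f)].append(int(l))
        indeg[int(l)] += 1
    avail = sorted(np.nonzero(indeg == 0)[0].tolist())
    order = []
    while avail:
        e = avail.pop(int(rng.integers(len(avail))))
        order.append(e)
        for t in succ[e]:
            indeg[t] -= 1
            if indeg[t] == 0:
                avail.append(t)
    return np.array(order, dtype=np.int64)


def brute_force_section_penalty(view: P.SectionView, order: np.ndarray) -> float:
    """Exhaustive minimum over all monotone grid placements (oracle)."""
    pos = np.full(order.size, -1, dtype=np.int64)
    pos[order] = np.arange(order.size)
    sub = view.events[np.argsort(pos[view.events], kind="stable")]
    idx = view.index_of[sub]
    obs = view.obs_height[idx]
    fadness = view.ev_is_fad[idx]
    h = view.heights
    k, m = obs.size, h.size
    best = np.inf
    for comb in itertools.combinations_with_replacement(range(m), k):
        cost = 0.0
        ok = True
        for i, j in enumerate(comb):
            if fadness[i]:
                if h[j] > obs[i] + 1e-9:
                    ok = False
                    break
            else:
                if h[j] < obs[i] - 1e-9:
                    ok = False
                    break
            cost += abs(h[j] - obs[i])
        if ok and cost < best:
            best = cost
    return best * view.weight


def consistent_dataset(n_taxa=8, n_sections=3, seed=0) -> tuple[StratDataset, np.ndarray]:
    """Sections that all agree with one global event order (zero conflict).

    Each section covers a contiguous window of a common event succession and
    records every taxon at every in-range position, so an extension-free
    monotone placement exists everywhere.  Returns (dataset, global order of
    event positions per taxon as (fad_pos, lad_pos) array).
    """
    rng = np.random.default_rng(seed)
    n_pos = 2 * n_taxa
    # random global order: taxon ranges [fad_pos, lad_pos] tiling 0..n_pos-1
    perm = random_global_ranges(n_taxa, rng)
    taxa = {f"t{t:02d}": Taxon(f"t{t:02d}") for t in range(n_taxa)}
    sections = []
    win = n_pos // 2 + 1
    for s in range(n_sections):
        a = int(round(s * (n_pos - win) / max(n_sections - 1, 1)))
        b = a + win - 1
        occ = set()
        for t in range(n_taxa):
            f, l = perm[t]
            lo, hi = max(f, a), min(l, b)
            for p in range(lo, hi + 1):
                occ.add((f"t{t:02d}", p - a + 1))
        heights = np.arange(1, win + 1, dtype=float)
        sections.append(Section(f"S{s}", heights, occ))
    return StratDataset(taxa=taxa, sections=sections), perm


def random_global_ranges(n_taxa, rng) -> np.ndarray:
    """Random (fad_pos, lad_pos) pairs forming a permutation of 0..2n-1."""
    while True:
        events = []
        open_t = []
        pending = list(range(n_taxa))
        rng.shuffle(pending)
        out = np.zeros((n_taxa, 2), dtype=int)
        pos = 0
        closed = set()
        while pos < 2 * n_taxa:
            can_open = bool(pending)
            can_close = bool(open_t)
            if can_open and (not can_close or rng.random() < 0.5):
                t = pending.pop()
                out[t, 0] = pos
                open_t.append(t)
            else:
                t = open_t.pop(int(rng.integers(len(open_t))))
                out[t, 1] = pos
                closed.add(t)
            pos += 1
        if len(closed) == n_taxa:
            return out


@pytest.fixture(scope="session")
def fixture20():
    """The standard recovery fixture: 20 taxa, 8 sections, 50% sampling."""
    return ss.simulate_world(n_taxa=20, n_sections=8, levels_per_section=20,
                             sampling_prob=0.5, seed=1)


@pytest.fixture(scope="session")
def problem20(fixture20):
    return ss.compile_problem(fixture20.dataset)


@pytest.fixture(scope="session")
def conflict_world():
    """Conflict-rich fixture for search-quality comparisons."""
    return ss.simulate_world(n_taxa=30, n_sections=10, levels_per_section=15,
                             sampling_prob=0.35, seed=7)


@pytest.fixture(scope="session")
def optimized20(fixture20, problem20):
    """One optimisation run on the standard fixture, shared across tests."""
    cfg = ss.EAConfig(population_size=8, start_temperature=3.0, steps=60,
                      trials=12000, seed=1, recombination_rate=0.2,
                      memory_replay_rate=0.1)
    best, history = ss.evolve_run(problem20, cfg)
    return best, history
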