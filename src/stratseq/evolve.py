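"""Evolutionary search over feasible composite sequences.

The optimiser keeps a fixed-size population of feasible composites and runs a
steady-state loop: a rank-biased parent proposes an offspring by a small
mutation (adjacent swap), a large mutation (block move), recombination with a
second parent (order-based window crossover), or by replaying a previously
improving move from a bounded memory.  Offspring violating the hard
stratigraphic constraints are rejected outright.  Acceptance relative to the
parent follows a Metropolis rule with a temperature annealed linearly from
``start_temperature`` to zero across ``steps`` equal stages of
``trials/steps`` proposals; at zero temperature only strict improvements are
accepted.  An accepted offspring enters the population by replacing the
current worst member whenever it beats it, so the population always consists
of the best sequences found so far.

All trial evaluations go through the incremental penalty
(:func:`stratseq.penalty.delta_penalty`), which recomputes only the sections
whose restricted event order the move can change.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import penalty as P
from .dataset import FAD, LAD, StratDataset
from .penalty import (AdjacentSwap, BlockMove, CompositeSequence, Problem,
                      WindowReorder, compile_problem, event_id, is_fad,
                      taxon_of, total_penalty)

logger = logging.getLogger("stratseq")


@dataclass
class EAConfig:
    """Search parameters.

    ``trials`` is the total proposal budget, split into ``steps`` equal
    annealing stages; the temperature decays linearly from
    ``start_temperature`` in the first stage to exactly zero in the last.
    """

    population_size: int = 24
    start_temperature: float = 500.0
    steps: int = 700
    trials: int = 40000
    recombination_rate: float = 0.2
    memory_replay_rate: float = 0.1
    seed: int = 0
    convergence_patience: int | None = None
    large_mutation_rate: float = 0.5   # share of plain mutations that are block moves
    memory_size: int = 1024

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.trials < self.steps:
            raise ValueError("trials must be >= steps")
        if not (0 <= self.recombination_rate <= 1 and 0 <= self.memory_replay_rate <= 1):
            raise ValueError("rates must be probabilities")


@dataclass
class Population:
    members: list[CompositeSequence]
    best_order: np.ndarray = None
    best_penalty: float = math.inf
    memory: deque = field(default_factory=lambda: deque(maxlen=1024))

    def __post_init__(self) -> None:
        if self.best_order is None and self.members:
            k = int(np.argmin([m.cached_penalty for m in self.members]))
            self.best_order = self.members[k].order.copy()
            self.best_penalty = float(self.members[k].cached_penalty)

    @property
    def penalties(self) -> np.ndarray:
        return np.array([m.cached_penalty for m in self.members])


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _insertion_bounds(order: list[int], event: int, problem: Problem,
                      pos_of: dict[int, int]) -> tuple[int, int]:
    """Feasible insertion-index window [lo, hi] for ``event`` into ``order``."""
    n_ev = problem.n_events
    lo, hi = 0, len(order)
    if is_fad(event):
        # must precede every present LAD l with (event, l) constrained
        for k, e in enumerate(order):
            if not is_fad(e) and (event * n_ev + e) in problem.pair_set:
                hi = min(hi, k)
                break
    else:
        # must follow every present FAD f with (f, event) constrained
        for k in range(len(order) - 1, -1, -1):
            e = order[k]
            if is_fad(e) and (e * n_ev + event) in problem.pair_set:
                lo = max(lo, k + 1)
                break
    _ = pos_of
    return lo, hi


def _greedy_insert_taxon(order: list[int], taxon: int, problem: Problem,
                         rng: np.random.Generator) -> None:
    """Insert taxon's FAD then LAD at feasible, penalty-greedy positions.

    Penalty is evaluated only over the sections observing the taxon (other
    sections' restricted orders are untouched by an insertion).  Ties are
    broken at random via ``rng`` to diversify the population.
    """
    views = [problem.sections[s] for s in problem.sections_of_taxon[taxon]]
    fad, lad = event_id(taxon, FAD), event_id(taxon, LAD)

    def local_pen(o: list[int]) -> float:
        arr = np.array(o, dtype=np.int64)
        return sum(_partial_section_penalty(v, arr) for v in views)

    lo, hi = _insertion_bounds(order, fad, problem, {})
    best: list[tuple[float, int]] = []
    for i in range(lo, hi + 1):
        cand = order[:i] + [fad, lad] + order[i:]
        best.append((local_pen(cand), i))
    m = min(b[0] for b in best)
    choices = [i for p, i in best if p <= m + 1e-12]
    i = int(choices[rng.integers(len(choices))])
    order.insert(i, fad)

    lo2, hi2 = _insertion_bounds(order, lad, problem, {})
    lo2 = max(lo2, i + 1)
    best = []
    for j in range(lo2, hi2 + 1):
        cand = order[:j] + [lad] + order[j:]
        best.append((local_pen(cand), j))
    m = min(b[0] for b in best)
    choices = [j for p, j in best if p <= m + 1e-12]
    j = int(choices[rng.integers(len(choices))])
    order.insert(j, lad)


def _partial_section_penalty(view: P.SectionView, order_arr: np.ndarray) -> float:
    """Section penalty restricted to events present in ``order_arr``."""
    present = np.isin(view.events, order_arr)
    if not present.any():
        return 0.0
    pos = np.full(int(order_arr.max()) + 1, -1, dtype=np.int64)
    pos[order_arr] = np.arange(order_arr.size)
    evs = view.events[present]
    sub = evs[np.argsort(pos[evs], kind="stable")]
    idx = view.index_of[sub]
    obs = view.obs_height[idx]
    fadness = view.ev_is_fad[idx]
    h = view.heights
    diff = h[None, :] - obs[:, None]
    cost = np.abs(diff)
    cost[fadness[:, None] & (diff > 1e-12)] = np.inf
    cost[~fadness[:, None] & (diff < -1e-12)] = np.inf
    dp = cost[0].copy()
    for i in range(1, cost.shape[0]):
        dp = cost[i] + np.minimum.accumulate(dp)
    return float(dp.min()) * view.weight


def _build_member(problem: Problem, insert_order: list[int],
                  rng: np.random.Generator) -> CompositeSequence:
    order: list[int] = []
    for t in insert_order:
        _greedy_insert_taxon(order, t, problem, rng)
    seq = CompositeSequence(np.array(order, dtype=np.int64))
    total_penalty(seq, problem)
    return seq


def init_from_sections(ds_or_problem, cfg: EAConfig) -> Population:
    """Seed a population by constraint-respecting greedy insertion.

    The top-ranked section's taxa are inserted first, in their observed
    (level) order, which reproduces that section's event succession whenever
    it is globally feasible; remaining taxa follow in an order shuffled per
    member to diversify the population.
    """
    from .dataset import connectivity, rank_sections
    problem = ds_or_problem if isinstance(ds_or_problem, Problem) else compile_problem(ds_or_problem)
    ds = problem.ds
    comps = connectivity(ds)
    if len(comps) > 1:
        raise P.InfeasibleError(
            f"dataset is not correlatable: {len(comps)} components "
            f"{[sorted(c) for c in comps]}"
        )
    rng = np.random.default_rng(cfg.seed)
    top_id = rank_sections(ds)[0][0]
    top = ds.section(top_id)
    t_index = {t: i for i, t in enumerate(problem.taxon_ids)}
    top_taxa = sorted(top.local_ranges().items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
    base = [t_index[tid] for tid, _ in top_taxa]
    rest = sorted(set(range(problem.n_taxa)) - set(base))
    members = []
    seen: set[tuple] = set()
    for k in range(cfg.population_size):
        rest_k = list(rest)
        if k > 0:
            rng.shuffle(rest_k)
        m = _build_member(problem, base + rest_k, rng)
        # greedy insertion can converge to one optimum; nudge duplicates
        # apart with zero-cost feasible swaps (penalty-neutral, so agreeing
        # datasets keep their zero-penalty members)
        for _ in range(300):
            if tuple(m.order) not in seen:
                break
            mv = AdjacentSwap(int(rng.integers(problem.n_events - 1)))
            res = P.delta_penalty(m, mv, problem)
            if res is not None and abs(res[0]) <= 1e-12:
                _commit(m, *res)
        seen.add(tuple(m.order))
        members.append(m)
    pop = Population(members=members)
    pop.memory = deque(maxlen=cfg.memory_size)
    return pop


def init_from_sequences(seqs: list[CompositeSequence], problem: Problem,
                        cfg: EAConfig) -> Population:
    """Seed the population from prior composites (restarts, earlier runs).

    Inputs are feasibility-checked; the best ``population_size`` are kept and,
    if fewer are supplied, the remainder is filled with clones perturbed by
    random feasible adjacent swaps.
    """
    rng = np.random.default_rng(cfg.seed)
    checked = []
    for s in seqs:
        ok, viol = P.feasible(s, problem)
        if not ok:
            f, l = viol
            raise P.InfeasibleError(
                f"input sequence infeasible: {problem.describe_event(f)} must "
                f"precede {problem.describe_event(l)}"
            )
        s = s.copy()
        total_penalty(s, problem)
        checked.append(s)
    checked.sort(key=lambda s: s.cached_penalty)
    members = [s.copy() for s in checked[: cfg.population_size]]
    n = problem.n_events
    while len(members) < cfg.population_size:
        parent = checked[rng.integers(len(checked))].copy()
        for _ in range(max(1, n // 4)):
            mv = AdjacentSwap(int(rng.integers(n - 1)))
            res = P.delta_penalty(parent, mv, problem)
            if res is None:
                continue
            d, new_order, updates = res
            _commit(parent, d, new_order, updates)
        members.append(parent)
    pop = Population(members=members)
    pop.memory = deque(maxlen=cfg.memory_size)
    return pop


# ---------------------------------------------------------------------------
# Move proposal
# ---------------------------------------------------------------------------

def mutate_small(seq: CompositeSequence, rng: np.random.Generator,
                 problem: Problem) -> CompositeSequence | None:
    """Swap one uniformly chosen adjacent pair; ``None`` when infeasible."""
    mv = _propose_small(seq, problem, rng)
    if not P.move_feasible(seq.order, mv, problem):
        return None
    return CompositeSequence(P.apply_move(seq.order, mv))


def mutate_large(seq: CompositeSequence, rng: np.random.Generator,
                 problem: Problem) -> CompositeSequence | None:
    """Move one event to another position, shifting the block between by one."""
    mv = _propose_large(seq, problem, rng)
    if mv is None or not P.move_feasible(seq.order, mv, problem):
        return None
    return CompositeSequence(P.apply_move(seq.order, mv))


def recombine(p1: CompositeSequence, p2: CompositeSequence,
              rng: np.random.Generator, problem: Problem) -> CompositeSequence | None:
    """Order-based window crossover; identity windows return a copy of p1."""
    mv = _propose_recombine(p1, p2, rng)
    if mv is None:  # degenerate or already-ordered window: offspring == p1
        return CompositeSequence(p1.order.copy())
    if not P.move_feasible(p1.order, mv, problem):
        return None
    return CompositeSequence(P.apply_move(p1.order, mv))


def _propose_small(seq, problem, rng):
    return AdjacentSwap(int(rng.integers(seq.order.size - 1)))


def _propose_large(seq, problem, rng):
    n = seq.order.size
    i = int(rng.integers(n))
    j = int(rng.integers(n))
    if i == j:
        return None  # identity, counted as rejection
    return BlockMove(i, j)


def _propose_recombine(p1: CompositeSequence, p2: CompositeSequence,
                       rng: np.random.Generator):
    """Order-based crossover: a window of p1 reordered to p2's relative order."""
    n = p1.order.size
    a, b = sorted((int(rng.integers(n)), int(rng.integers(n))))
    if a == b:
        return None
    window = p1.order[a: b + 1]
    pos2 = np.empty(n, dtype=np.int64)
    pos2[p2.order] = np.arange(n)
    new_window = window[np.argsort(pos2[window], kind="stable")]
    if np.array_equal(new_window, window):
        return None
    return WindowReorder(a, b, tuple(int(e) for e in new_window))


def _commit(seq: CompositeSequence, delta: float, new_order: np.ndarray,
            updates: dict[int, float]) -> None:
    seq.order = new_order
    for si, v in updates.items():
        seq.section_penalties[si] = v
    seq.cached_penalty = float(seq.cached_penalty + delta)


def _memory_entry(order: np.ndarray, move) -> tuple | None:
    if isinstance(move, AdjacentSwap):
        return ("swap", int(order[move.i]), int(order[move.i + 1]))
    if isinstance(move, BlockMove):
        return ("move", int(order[move.i]), int(order[move.j]))
    return None  # recombination windows are not replayable loci


def _replay(entry: tuple, seq: CompositeSequence):
    """Re-target a remembered improving move at the current sequence."""
    kind, ea, eb = entry
    pos = seq.positions
    ia, ib = int(pos[ea]), int(pos[eb])
    if kind == "swap":
        if abs(ia - ib) != 1:
            return None  # no longer adjacent: inapplicable
        return AdjacentSwap(min(ia, ib))
    if ia == ib:
        return None
    return BlockMove(ia, ib)


# ---------------------------------------------------------------------------
# The main loop
# ---------------------------------------------------------------------------

def _rank_weights(penalties: np.ndarray) -> np.ndarray:
    """Linear rank bias: the best member gets twice the weight of the worst."""
    n = penalties.size
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(penalties, kind="stable")] = np.arange(n)  # 0 = best
    w = 2.0 - ranks / max(n - 1, 1)
    return w / w.sum()


def evolve_run(ds_or_problem, cfg: EAConfig,
               population: Population | None = None):
    """Run the steady-state evolutionary search.

    Returns ``(best CompositeSequence, history DataFrame)``.  The history has
    one row per annealing stage with the best/mean penalty, acceptance rate
    and temperature.  Fully reproducible from ``cfg.seed``.
    """
    problem = ds_or_problem if isinstance(ds_or_problem, Problem) else compile_problem(ds_or_problem)
    rng = np.random.default_rng(cfg.seed + 1)
    pop = population if population is not None else init_from_sections(problem, cfg)
    pop.memory = deque(pop.memory, maxlen=cfg.memory_size)

    steps = max(cfg.steps, 1)
    per_stage = cfg.trials // steps
    history = []
    stale = 0
    for stage in range(steps):
        temp = cfg.start_temperature * (steps - 1 - stage) / max(steps - 1, 1)
        accepted = 0
        for _ in range(per_stage):
            weights = _rank_weights(pop.penalties)
            pi = int(rng.choice(len(pop.members), p=weights))
            parent = pop.members[pi]
            u = float(rng.random())
            move = None
            if u < cfg.memory_replay_rate and pop.memory:
                entry = pop.memory[int(rng.integers(len(pop.memory)))]
                move = _replay(entry, parent)
            elif u < cfg.memory_replay_rate + cfg.recombination_rate and len(pop.members) > 1:
                qi = int(rng.choice(len(pop.members), p=weights))
                if qi != pi:
                    move = _propose_recombine(parent, pop.members[qi], rng)
            else:
                if float(rng.random()) < cfg.large_mutation_rate:
                    move = _propose_large(parent, problem, rng)
                else:
                    move = _propose_small(parent, problem, rng)
            if move is None:
                continue
            res = P.delta_penalty(parent, move, problem)
            if res is None:
                continue  # infeasible offspring: fatal mutation, discarded
            delta, new_order, updates = res
            if delta < -1e-12:
                accept = True
            elif temp > 0:
                accept = float(rng.random()) < math.exp(-max(delta, 0.0) / temp)
            else:
                accept = False  # at T=0 only strictly better sequences pass
            if not accept:
                continue
            accepted += 1
            if delta < -1e-12:
                entry = _memory_entry(parent.order, move)
                if entry is not None:
                    pop.memory.append(entry)
            offspring = CompositeSequence(
                new_order, parent.cached_penalty + delta,
                parent.section_penalties.copy())
            for si, v in updates.items():
                offspring.section_penalties[si] = v
            off_pen = float(offspring.cached_penalty)
            # natural selection: an offspring that beats the current worst
            # replaces it; otherwise the accepted (possibly uphill) offspring
            # continues its parent's annealing chain in place
            wi = int(np.argmax(pop.penalties))
            if off_pen < pop.members[wi].cached_penalty:
                pop.members[wi] = offspring
            else:
                pop.members[pi] = offspring
            if off_pen < pop.best_penalty - 1e-12:
                pop.best_penalty = off_pen
                pop.best_order = offspring.order.copy()
        pens = pop.penalties
        history.append({
            "stage": stage, "temperature": temp,
            "best": float(pop.best_penalty),
            "population_best": float(pens.min()),
            "population_mean": float(pens.mean()),
            "acceptance_rate": accepted / max(per_stage, 1),
        })
        if len(history) > 1 and history[-1]["best"] < history[-2]["best"] - 1e-12:
            stale = 0
        else:
            stale += 1
        if cfg.convergence_patience is not None and stale >= cfg.convergence_patience:
            logger.info("converged after %d stages (best %.4f)", stage + 1, pop.best_penalty)
            break
    best = CompositeSequence(pop.best_order.copy())
    total_penalty(best, problem)
    return best, pd.DataFrame(history)


def compare_runs(ds: StratDataset, cfg_ea: EAConfig,
                 cfg_baseline: EAConfig | None = None,
                 n_seeds: int = 10) -> pd.DataFrame:
    """Full EA vs a pure-annealing baseline at equal trial budgets.

    The baseline disables recombination and move-replay memory and shrinks the
    population to two members, reducing the search to annealed mutation.
    Returns one row per seed with both final penalties.
    """
    if cfg_baseline is None:
        cfg_baseline = replace(cfg_ea, recombination_rate=0.0,
                               memory_replay_rate=0.0, population_size=2)
    problem = compile_problem(ds)
    rows = []
    for k in range(n_seeds):
        ea_best, _ = evolve_run(problem, replace(cfg_ea, seed=cfg_ea.seed + k))
        base_best, _ = evolve_run(problem, replace(cfg_baseline, seed=cfg_baseline.seed + k))
        rows.append({"seed": cfg_ea.seed + k,
                     "ea_penalty": ea_best.cached_penalty,
                     "baseline_penalty": base_best.cached_penalty})
    df = pd.DataFrame(rows)
    df.attrs["ea_mean"] = float(df["ea_penalty"].mean())
    df.attrs["baseline_mean"] = float(df["baseline_penalty"].mean())
    return df
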