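"""Composite-sequence feasibility and the range-extension penalty.

A composite sequence is a total order over every taxon's FAD and LAD.  Its
misfit against one section is the minimum total stratigraphic range extension
(in height units, times the section weight) needed to reconcile the section's
observed local ranges with the composite order: observed events must be placed
at non-decreasing heights along the composite, a FAD may only be moved down
(earlier) and a LAD only up (later), and the classic result that an optimal
placement exists on the section's own level grid reduces the minimisation to a
dynamic program over (event, level) states.

Two hard feasibility rules restrict the search space:

(i)  every taxon's FAD precedes its own LAD;
(ii) for every section and ordered taxon pair (A, B) observed in it with
     local FAD level of A <= local LAD level of B, FAD_A precedes LAD_B in
     the composite (superpositional/coexistence constraints).

Rule (ii) subsumes observed coexistence and guarantees that an extension-only
monotone placement exists in every section, so the penalty is always finite.
All constraints are of the form "some FAD before some LAD", hence the
constraint digraph is bipartite and always satisfiable.

Event encoding: taxa are indexed 0..T-1 in sorted taxon_id order; taxon t's
FAD is event 2t and its LAD is event 2t+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FAD, LAD, BioEvent, Section, StratDataset

INF = np.inf


def event_id(taxon_index: int, kind: str) -> int:
    return 2 * taxon_index + (0 if kind == FAD else 1)


def is_fad(event: int) -> bool:
    return event % 2 == 0

def taxon_of(event: int) -> int:
    return event // 2


class InfeasibleError(ValueError):
    """A sequence violates a hard stratigraphic constraint."""


# ---------------------------------------------------------------------------
# Compiled problem
# ---------------------------------------------------------------------------

@dataclass
class SectionView:
    """A section pre-indexed for fast penalty evaluation."""

    section_id: str
    weight: float
    heights: np.ndarray            # level grid, strictly increasing
    events: np.ndarray             # event ids of locally observed taxa
    obs_height: np.ndarray         # observed datum height per event (aligned)
    ev_is_fad: np.ndarray          # bool, aligned with events
    taxon_set: frozenset           # taxon indices observed here
    index_of: np.ndarray = None    # global event id -> row in `events` (-1 absent)


@dataclass
class Problem:
    """A dataset compiled to integer events, constraints and section views."""

    taxon_ids: list[str]
    sections: list[SectionView]
    # rule (ii) pairs as parallel arrays plus a set for O(1) membership
    c_fad: np.ndarray
    c_lad: np.ndarray
    pair_set: frozenset
    sections_of_taxon: list[list[int]]
    ds: StratDataset

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_events(self) -> int:
        return 2 * len(self.taxon_ids)

    def taxon_index(self, taxon_id: str) -> int:
        return self.taxon_ids.index(taxon_id)

    def event_of(self, taxon_id: str, kind: str) -> int:
        return event_id(self.taxon_ids.index(taxon_id), kind)

    def describe_event(self, event: int) -> BioEvent:
        return BioEvent(self.taxon_ids[taxon_of(event)], FAD if is_fad(event) else LAD)


def compile_problem(ds: StratDataset) -> Problem:
    """Index taxa/events, derive superpositional constraints, build views."""
    taxon_ids = sorted(ds.taxa)
    t_index = {t: i for i, t in enumerate(taxon_ids)}
    views = []
    pairs: set[tuple[int, int]] = set()
    sections_of_taxon: list[list[int]] = [[] for _ in taxon_ids]

    # rule (i) as explicit pairs so one membership structure covers everything
    for t in range(len(taxon_ids)):
        pairs.add((event_id(t, FAD), event_id(t, LAD)))

    for si, s in enumerate(ds.sections):
        ranges = s.local_ranges()
        evs, obs, fadness = [], [], []
        for tid, (lo, hi) in sorted(ranges.items()):
            t = t_index[tid]
            sections_of_taxon[t].append(si)
            evs.append(event_id(t, FAD)); obs.append(s.height_of(lo)); fadness.append(True)
            evs.append(event_id(t, LAD)); obs.append(s.height_of(hi)); fadness.append(False)
        ev_arr = np.array(evs, dtype=np.int64)
        index_of = np.full(2 * len(taxon_ids), -1, dtype=np.int64)
        index_of[ev_arr] = np.arange(ev_arr.size)
        views.append(SectionView(
            section_id=s.section_id,
            weight=s.weight,
            heights=s.heights.copy(),
            events=ev_arr,
            obs_height=np.array(obs, dtype=float),
            ev_is_fad=np.array(fadness, dtype=bool),
            taxon_set=frozenset(t_index[t] for t in ranges),
            index_of=index_of,
        ))
        # rule (ii): FAD_A before LAD_B whenever A starts at/below B's top
        items = [(t_index[tid], lo, hi) for tid, (lo, hi) in ranges.items()]
        for ta, lo_a, _ in items:
            for tb, _, hi_b in items:
                if ta != tb and lo_a <= hi_b:
                    pairs.add((event_id(ta, FAD), event_id(tb, LAD)))

    arr = np.array(sorted(pairs), dtype=np.int64)
    return Problem(
        taxon_ids=taxon_ids,
        sections=views,
        c_fad=arr[:, 0],
        c_lad=arr[:, 1],
        pair_set=frozenset(f * (2 * len(taxon_ids)) + l for f, l in pairs),
        sections_of_taxon=sections_of_taxon,
        ds=ds,
    )


# ---------------------------------------------------------------------------
# Composite sequence
# ---------------------------------------------------------------------------

@dataclass
class CompositeSequence:
    """A feasible permutation of all events; index 0 = oldest.

    ``section_penalties`` caches each section's contribution so that moves can
    be evaluated incrementally; ``cached_penalty`` is their sum.
    """

    order: np.ndarray
    cached_penalty: float | None = None
    section_penalties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        pos = np.empty_like(self.order)
        pos[self.order] = np.arange(self.order.size)
        return pos

    def copy(self) -> "CompositeSequence":
        return CompositeSequence(
            self.order.copy(),
            self.cached_penalty,
            None if self.section_penalties is None else self.section_penalties.copy(),
        )

    def to_frame(self, problem: Problem) -> pd.DataFrame:
        rows = []
        for rank, ev in enumerate(self.order):
            be = problem.describe_event(int(ev))
            rows.append({"rank": rank, "taxon": be.taxon_id, "event_kind": be.kind})
        return pd.DataFrame(rows)


def sequence_from_frame(df: pd.DataFrame, problem: Problem) -> CompositeSequence:
    order = [problem.event_of(str(r.taxon), str(r.event_kind))
             for r in df.sort_values("rank").itertuples()]
    return CompositeSequence(np.array(order, dtype=np.int64))


def write_composite(seq: CompositeSequence, problem: Problem, path, extra: pd.DataFrame | None = None) -> None:
    df = seq.to_frame(problem)
    if extra is not None:
        df = df.join(extra)
    df.to_csv(path, index=False)


def read_composite(path, problem: Problem) -> CompositeSequence:
    return sequence_from_frame(pd.read_csv(path), problem)


# ---------------------------------------------------------------------------
# Feasibility
# ---------------------------------------------------------------------------

def _check_permutation(seq: CompositeSequence, problem: Problem) -> None:
    if seq.order.size != problem.n_events or \
            not np.array_equal(np.sort(seq.order), np.arange(problem.n_events)):
        raise InfeasibleError("sequence is not a permutation of the dataset's events")


def feasible(seq: CompositeSequence, problem: Problem) -> tuple[bool, tuple[int, int] | None]:
    """Check rules (i)+(ii); returns (ok, first violated (FAD, LAD) pair)."""
    _check_permutation(seq, problem)
    pos = seq.positions
    bad = pos[problem.c_fad] > pos[problem.c_lad]
    if bad.any():
        k = int(np.argmax(bad))
        return False, (int(problem.c_fad[k]), int(problem.c_lad[k]))
    return True, None


def _order_feasible(order: np.ndarray, problem: Problem) -> bool:
    pos = np.empty(problem.n_events, dtype=np.int64)
    pos[order] = np.arange(order.size)
    return bool(np.all(pos[problem.c_fad] < pos[problem.c_lad]))


# ---------------------------------------------------------------------------
# Penalty
# ---------------------------------------------------------------------------

def _section_cost_matrix(view: SectionView, seq_order: np.ndarray):
    """Events of this section in composite order + their (event x level) costs."""
    pos = np.full(seq_order.size, -1, dtype=np.int64)
    pos[seq_order] = np.arange(seq_order.size)
    sub = view.events[np.argsort(pos[view.events], kind="stable")]
    idx = view.index_of[sub]
    obs = view.obs_height[idx]
    fadness = view.ev_is_fad[idx]
    h = view.heights
    diff = h[None, :] - obs[:, None]          # placed - observed
    cost = np.abs(diff)
    # FAD may only move down (placed <= observed); LAD only up
    cost[fadness[:, None] & (diff > 1e-12)] = INF
    cost[~fadness[:, None] & (diff < -1e-12)] = INF
    return sub, obs, cost


def section_penalty_value(view: SectionView, seq_order: np.ndarray) -> float:
    """Minimum weighted total extension for one section (DP over the grid)."""
    if view.events.size == 0:
        return 0.0
    _, _, cost = _section_cost_matrix(view, seq_order)
    dp = cost[0].copy()
    for i in range(1, cost.shape[0]):
        dp = cost[i] + np.minimum.accumulate(dp)
    val = float(dp.min())
    if not np.isfinite(val):
        raise InfeasibleError(
            f"no extension-only placement exists in section {view.section_id!r}; "
            "sequence violates a superpositional constraint"
        )
    return val * view.weight


@dataclass
class Placement:
    """Witness of one section's optimal fit: placed heights and extensions."""

    section_id: str
    events: np.ndarray          # event ids, in composite order
    observed: np.ndarray        # observed datum heights
    placed: np.ndarray          # optimal placed heights (non-decreasing)
    extension: np.ndarray       # |placed - observed| per event
    section_penalty: float      # sum(extension) * weight

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "event": self.events, "observed": self.observed,
            "placed": self.placed, "extension": self.extension,
        })


def section_penalty(seq: CompositeSequence, view: SectionView,
                    problem: Problem) -> Placement:
    """Optimal extension-only placement with backtracking.

    Ties break toward the smaller placed height; this affects the witness
    only, never the penalty value.
    """
    ok, viol = feasible(seq, problem)
    if not ok:
        f, l = viol
        raise InfeasibleError(
            f"infeasible sequence: {problem.describe_event(f)} must precede "
            f"{problem.describe_event(l)}"
        )
    sub, obs, cost = _section_cost_matrix(view, seq.order)
    k = cost.shape[0]
    dps = np.empty_like(cost)
    dps[0] = cost[0]
    for i in range(1, k):
        dps[i] = cost[i] + np.minimum.accumulate(dps[i - 1])
    j = int(np.argmin(dps[k - 1]))
    picks = [j]
    for i in range(k - 2, -1, -1):
        j = int(np.argmin(dps[i][: j + 1]))
        picks.append(j)
    picks.reverse()
    placed = view.heights[np.array(picks, dtype=np.int64)]
    ext = np.abs(placed - obs)
    return Placement(
        section_id=view.section_id, events=sub, observed=obs, placed=placed,
        extension=ext, section_penalty=float(ext.sum()) * view.weight,
    )


def all_section_penalties(seq: CompositeSequence, problem: Problem) -> np.ndarray:
    return np.array([section_penalty_value(v, seq.order) for v in problem.sections])


def total_penalty(seq: CompositeSequence, problem: Problem) -> float:
    """Sum of per-section penalties; cached on the sequence."""
    ok, viol = feasible(seq, problem)
    if not ok:
        f, l = viol
        raise InfeasibleError(
            f"infeasible sequence: {problem.describe_event(f)} must precede "
            f"{problem.describe_event(l)}"
        )
    per = all_section_penalties(seq, problem)
    seq.section_penalties = per
    seq.cached_penalty = float(per.sum())
    return seq.cached_penalty


def composite_ranges(seq: CompositeSequence, problem: Problem) -> dict[str, tuple[int, int]]:
    """Per-taxon (FAD position, LAD position) in the composite order."""
    pos = seq.positions
    out = {}
    for t, tid in enumerate(problem.taxon_ids):
        f, l = int(pos[event_id(t, FAD)]), int(pos[event_id(t, LAD)])
        if f >= l:
            raise InfeasibleError(f"taxon {tid!r}: FAD does not precede LAD")
        out[tid] = (f, l)
    return out


# ---------------------------------------------------------------------------
# Moves and incremental evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacentSwap:
    """Swap the events at positions i and i+1 (small mutation)."""
    i: int


@dataclass(frozen=True)
class BlockMove:
    """Remove the event at i, reinsert at j; the block between shifts by one
    (large mutation)."""
    i: int
    j: int


@dataclass(frozen=True)
class WindowReorder:
    """Reorder positions a..b (inclusive) to ``new_window`` (recombination)."""
    a: int
    b: int
    new_window: tuple


def apply_move(order: np.ndarray, move) -> np.ndarray:
    new = order.copy()
    if isinstance(move, AdjacentSwap):
        i = move.i
        new[i], new[i + 1] = order[i + 1], order[i]
    elif isinstance(move, BlockMove):
        ev = order[move.i]
        new = np.delete(order, move.i)
        new = np.insert(new, move.j, ev)
    elif isinstance(move, WindowReorder):
        new[move.a: move.b + 1] = np.array(move.new_window, dtype=np.int64)
    else:
        raise TypeError(f"unknown move type {type(move)!r}")
    return new


def move_feasible(order: np.ndarray, move, problem: Problem) -> bool:
    """Constraint check specialised per move type (no full re-scan for swaps)."""
    n_ev = problem.n_events
    pair = problem.pair_set
    if isinstance(move, AdjacentSwap):
        x, y = int(order[move.i]), int(order[move.i + 1])
        # only a (FAD x, LAD y) constraint can be inverted
        return not (is_fad(x) and not is_fad(y) and (x * n_ev + y) in pair)
    if isinstance(move, BlockMove):
        i, j = move.i, move.j
        x = int(order[i])
        if i < j:       # x moves later: must not be required before any block event
            block = order[i + 1: j + 1]
            if not is_fad(x):
                return True
            return not any((x * n_ev + int(b)) in pair for b in block)
        elif i > j:     # x moves earlier: no block event may be required before x
            block = order[j: i]
            if is_fad(x):
                return True
            return not any((int(b) * n_ev + x) in pair for b in block)
        return True
    if isinstance(move, WindowReorder):
        # only within-window pairs can invert; check them directly
        w = list(move.new_window)
        posw = {e: k for k, e in enumerate(w)}
        for k, e in enumerate(w):
            if is_fad(e):
                continue
            # e is a LAD: any FAD constrained before it must not come later
            for k2 in range(k + 1, len(w)):
                f = w[k2]
                if is_fad(f) and (f * n_ev + e) in pair:
                    return False
        _ = posw
        return True
    raise TypeError(f"unknown move type {type(move)!r}")


def affected_sections(order: np.ndarray, move, problem: Problem) -> list[int]:
    """Sections whose restricted event order can change under ``move``."""
    if isinstance(move, AdjacentSwap):
        ta, tb = taxon_of(int(order[move.i])), taxon_of(int(order[move.i + 1]))
        sa = set(problem.sections_of_taxon[ta])
        sb = set(problem.sections_of_taxon[tb])
        return sorted(sa & sb) if ta != tb else sorted(sa)
    if isinstance(move, BlockMove):
        i, j = move.i, move.j
        if i == j:
            return []
        x = taxon_of(int(order[i]))
        block = order[i + 1: j + 1] if i < j else order[j: i]
        block_taxa = {taxon_of(int(b)) for b in block}
        sx = set(problem.sections_of_taxon[x])
        out = set()
        for t in block_taxa:
            out |= sx & set(problem.sections_of_taxon[t])
        return sorted(out)
    if isinstance(move, WindowReorder):
        taxa = {taxon_of(int(e)) for e in move.new_window}
        counts: dict[int, int] = {}
        for t in taxa:
            for s in problem.sections_of_taxon[t]:
                counts[s] = counts.get(s, 0) + 1
        return sorted(s for s, c in counts.items() if c >= 2)
    raise TypeError(f"unknown move type {type(move)!r}")


def delta_penalty(seq: CompositeSequence, move, problem: Problem):
    """Exact penalty change of ``move``, recomputing only affected sections.

    Returns ``(delta, new_order, updates)`` where ``updates`` maps section
    index to its new penalty, or ``None`` if the offspring is infeasible
    (rejection is a value, not an exception).
    """
    if seq.section_penalties is None:
        total_penalty(seq, problem)
    if not move_feasible(seq.order, move, problem):
        return None
    new_order = apply_move(seq.order, move)
    updates: dict[int, float] = {}
    delta = 0.0
    for si in affected_sections(seq.order, move, problem):
        new_p = section_penalty_value(problem.sections[si], new_order)
        updates[si] = new_p
        delta += new_p - seq.section_penalties[si]
    return float(delta), new_order, updates
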