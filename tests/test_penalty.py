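"""Feasibility rules and the range-extension penalty, against brute force."""

import numpy as np
import pytest

import stratseq as ss
from stratseq import penalty as P
from stratseq.dataset import FAD, LAD

from conftest import (brute_force_section_penalty, make_dataset,
                      random_feasible_order, random_small_instance)


def order_of(problem, *events):
    return P.CompositeSequence(np.array(
        [problem.event_of(t, k) for t, k in events], dtype=np.int64))


class TestFeasibility:
    def test_single_taxon_fad_before_lad(self):
        prob = ss.compile_problem(make_dataset({"S": {"a": [1, 2]}}))
        ok, _ = P.feasible(order_of(prob, ("a", FAD), ("a", LAD)), prob)
        assert ok
        bad, viol = P.feasible(order_of(prob, ("a", LAD), ("a", FAD)), prob)
        assert not bad and viol == (prob.event_of("a", FAD), prob.event_of("a", LAD))

    def test_observed_coexistence_must_survive(self):
        # a and b overlap at level 2: both FADs must precede both LADs
        prob = ss.compile_problem(make_dataset({"S": {"a": [1, 2], "b": [2, 3]}}))
        seq = order_of(prob, ("a", FAD), ("a", LAD), ("b", FAD), ("b", LAD))
        ok, viol = P.feasible(seq, prob)
        assert not ok
        assert viol == (prob.event_of("b", FAD), prob.event_of("a", LAD))

    def test_mismatched_events_raise(self):
        prob = ss.compile_problem(make_dataset({"S": {"a": [1, 2]}}))
        with pytest.raises(P.InfeasibleError):
            P.feasible(P.CompositeSequence(np.array([0, 0])), prob)


class TestSectionPenalty:
    def test_agreeing_order_is_free(self):
        ds = make_dataset({"S": {"a": [1, 2], "b": [3, 4]}})
        prob = ss.compile_problem(ds)
        seq = order_of(prob, ("a", FAD), ("a", LAD), ("b", FAD), ("b", LAD))
        pl = P.section_penalty(seq, prob.sections[0], prob)
        assert pl.section_penalty == 0.0
        assert np.all(pl.extension == 0)

    def test_interleaved_ranges_cost_one(self):
        # heights 1..4, A at 1-2, B at 3-4; composite interleaves their ranges
        ds = make_dataset({"S": {"A": [1, 2], "B": [3, 4]}})
        prob = ss.compile_problem(ds)
        seq = order_of(prob, ("A", FAD), ("B", FAD), ("A", LAD), ("B", LAD))
        pl = P.section_penalty(seq, prob.sections[0], prob)
        assert pl.section_penalty == pytest.approx(1.0)

    def test_weight_scales_linearly(self):
        spec = {"S": {"A": [1, 2], "B": [3, 4]}}
        ds1 = make_dataset(spec)
        ds2 = make_dataset(spec, weights={"S": 2.0})
        for ds, expect in ((ds1, 1.0), (ds2, 2.0)):
            prob = ss.compile_problem(ds)
            seq = order_of(prob, ("A", FAD), ("B", FAD), ("A", LAD), ("B", LAD))
            assert P.total_penalty(seq, prob) == pytest.approx(expect)

    def test_placement_witness_invariants(self, problem20):
        rng = np.random.default_rng(0)
        seq = P.CompositeSequence(random_feasible_order(problem20, rng))
        for view in problem20.sections:
            pl = P.section_penalty(seq, view, problem20)
            assert np.all(np.diff(pl.placed) >= -1e-12)
            fad = np.array([P.is_fad(int(e)) for e in pl.events])
            assert np.all(pl.placed[fad] <= pl.observed[fad] + 1e-12)
            assert np.all(pl.placed[~fad] >= pl.observed[~fad] - 1e-12)
            assert pl.section_penalty == pytest.approx(pl.extension.sum() * view.weight)

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            ds = random_small_instance(rng)
            prob = ss.compile_problem(ds)
            order = random_feasible_order(prob, rng)
            got = P.section_penalty_value(prob.sections[0], order)
            want = brute_force_section_penalty(prob.sections[0], order)
            assert got == pytest.approx(want, abs=1e-9)


class TestTotalAndDelta:
    def test_additivity_over_duplicate_sections(self):
        spec = {"S1": {"A": [1, 2], "B": [3, 4]}, "S2": {"A": [1, 2], "B": [3, 4]}}
        prob = ss.compile_problem(make_dataset(spec))
        seq = order_of(prob, ("A", FAD), ("B", FAD), ("A", LAD), ("B", LAD))
        assert P.total_penalty(seq, prob) == pytest.approx(2.0)
        assert np.allclose(seq.section_penalties, [1.0, 1.0])

    def test_total_equals_sum_of_sections(self, problem20):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = P.CompositeSequence(random_feasible_order(problem20, rng))
            total = P.total_penalty(seq, problem20)
            parts = [P.section_penalty(seq, v, problem20).section_penalty
                     for v in problem20.sections]
            assert total == pytest.approx(sum(parts))

    def test_delta_locality_untouched_sections(self, problem20):
        rng = np.random.default_rng(4)
        seq = P.CompositeSequence(random_feasible_order(problem20, rng))
        P.total_penalty(seq, problem20)
        mv = P.AdjacentSwap(0)
        affected = P.affected_sections(seq.order, mv, problem20)
        ta = P.taxon_of(int(seq.order[0]))
        tb = P.taxon_of(int(seq.order[1]))
        for si, view in enumerate(problem20.sections):
            if si not in affected:
                assert not ({ta, tb} <= set(view.taxon_set))

    def test_delta_matches_full_recompute(self, problem20):
        rng = np.random.default_rng(5)
        seq = P.CompositeSequence(random_feasible_order(problem20, rng))
        P.total_penalty(seq, problem20)
        n = seq.order.size
        checked = 0
        while checked < 150:
            if rng.random() < 0.5:
                mv = P.AdjacentSwap(int(rng.integers(n - 1)))
            else:
                i, j = (int(v) for v in rng.integers(n, size=2))
                if i == j:
                    continue
                mv = P.BlockMove(i, j)
            res = P.delta_penalty(seq, mv, problem20)
            if res is None:
                continue
            delta, new_order, updates = res
            fresh = P.CompositeSequence(new_order.copy())
            assert seq.cached_penalty + delta == pytest.approx(
                P.total_penalty(fresh, problem20), abs=1e-9)
            seq.order = new_order
            for si, v in updates.items():
                seq.section_penalties[si] = v
            seq.cached_penalty += delta
            checked += 1

    def test_infeasible_move_is_rejection_value(self):
        prob = ss.compile_problem(make_dataset({"S": {"a": [1, 2]}}))
        seq = order_of(prob, ("a", FAD), ("a", LAD))
        P.total_penalty(seq, prob)
        assert P.delta_penalty(seq, P.AdjacentSwap(0), prob) is None


class TestInvariance:
    def test_penalty_invariant_under_relabeling_and_section_order(self):
        spec = {"S1": {"a": [1, 3], "b": [2, 4]}, "S2": {"b": [1, 2], "c": [1, 3]}}
        relabeled = {"S2x": {"q": [1, 2], "r": [1, 3]},
                     "S1x": {"p": [1, 3], "q": [2, 4]}}
        prob1 = ss.compile_problem(make_dataset(spec))
        prob2 = ss.compile_problem(make_dataset(relabeled))
        rng = np.random.default_rng(9)
        mapping = {"a": "p", "b": "q", "c": "r"}
        for _ in range(20):
            o1 = random_feasible_order(prob1, rng)
            events = [prob1.describe_event(int(e)) for e in o1]
            o2 = np.array([prob2.event_of(mapping[e.taxon_id], e.kind)
                           for e in events])
            p1 = P.total_penalty(P.CompositeSequence(o1), prob1)
            p2 = P.total_penalty(P.CompositeSequence(o2), prob2)
            assert p1 == pytest.approx(p2)


def test_composite_ranges_positions():
    prob = ss.compile_problem(make_dataset({"S": {"a": [1, 3], "b": [2, 4]}}))
    seq = order_of(prob, ("a", FAD), ("b", FAD), ("a", LAD), ("b", LAD))
    ranges = P.composite_ranges(seq, prob)
    assert ranges == {"a": (0, 2), "b": (1, 3)}
    used = sorted(p for pair in ranges.values() for p in pair)
    assert used == list(range(4))


def test_composite_csv_round_trip(tmp_path, problem20):
    rng = np.random.default_rng(11)
    seq = P.CompositeSequence(random_feasible_order(problem20, rng))
    path = tmp_path / "composite.csv"
    P.write_composite(seq, problem20, path)
    back = P.read_composite(path, problem20)
    assert np.array_equal(back.order, seq.order)
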