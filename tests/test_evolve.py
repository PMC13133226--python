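"""Evolutionary search: moves, initialisation, selection and reproducibility."""

import dataclasses

import numpy as np
import pytest

import stratseq as ss
from stratseq import evolve as E
from stratseq import penalty as P
from stratseq.dataset import FAD, LAD

from conftest import consistent_dataset, make_dataset, random_feasible_order


@pytest.fixture(scope="module")
def agree_problem():
    ds, _ = consistent_dataset(n_taxa=8, n_sections=3, seed=2)
    return ss.compile_problem(ds)


def small_cfg(**kw):
    base = dict(population_size=4, start_temperature=2.0, steps=10,
                trials=600, seed=0)
    base.update(kw)
    return ss.EAConfig(**base)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ss.EAConfig(population_size=1)
        with pytest.raises(ValueError):
            ss.EAConfig(trials=10, steps=20)
        with pytest.raises(ValueError):
            ss.EAConfig(recombination_rate=1.5)


class TestMutation:
    def test_small_mutation_changes_two_positions(self, problem20):
        rng = np.random.default_rng(0)
        seq = P.CompositeSequence(random_feasible_order(problem20, rng))
        for _ in range(30):
            off = E.mutate_small(seq, rng, problem20)
            if off is not None:
                assert int((off.order != seq.order).sum()) == 2

    def test_swap_breaking_own_range_rejected(self):
        prob = ss.compile_problem(make_dataset({"S": {"a": [1, 2]}}))
        seq = P.CompositeSequence(np.array([prob.event_of("a", FAD),
                                            prob.event_of("a", LAD)]))
        rng = np.random.default_rng(0)
        assert E.mutate_small(seq, rng, prob) is None

    def test_large_mutation_preserves_multiset(self, problem20):
        rng = np.random.default_rng(1)
        seq = P.CompositeSequence(random_feasible_order(problem20, rng))
        got = 0
        while got < 20:
            off = E.mutate_large(seq, rng, problem20)
            if off is not None:
                assert np.array_equal(np.sort(off.order), np.sort(seq.order))
                ok, _ = P.feasible(off, problem20)
                assert ok
                got += 1


class TestRecombination:
    def test_identical_parents_identity(self, problem20):
        rng = np.random.default_rng(2)
        p1 = P.CompositeSequence(random_feasible_order(problem20, rng))
        off = E.recombine(p1, p1, rng, problem20)
        assert off is not None and np.array_equal(off.order, p1.order)

    def test_window_matches_second_parent_order(self, problem20):
        rng = np.random.default_rng(3)
        for _ in range(30):
            p1 = P.CompositeSequence(random_feasible_order(problem20, rng))
            p2 = P.CompositeSequence(random_feasible_order(problem20, rng))
            mv = E._propose_recombine(p1, p2, rng)
            if mv is None:
                continue
            window = p1.order[mv.a: mv.b + 1]
            assert sorted(mv.new_window) == sorted(window.tolist())
            pos2 = p2.positions
            ranks = [int(pos2[e]) for e in mv.new_window]
            assert ranks == sorted(ranks)


class TestInit:
    def test_agreeing_sections_give_zero_penalty_members(self, agree_problem):
        pop = E.init_from_sections(agree_problem, small_cfg())
        assert all(m.cached_penalty == pytest.approx(0.0) for m in pop.members)

    def test_members_feasible_and_distinct(self, problem20):
        cfg = small_cfg(population_size=6, seed=1)
        pop = E.init_from_sections(problem20, cfg)
        orders = {tuple(m.order) for m in pop.members}
        assert len(orders) == len(pop.members)
        for m in pop.members:
            ok, _ = P.feasible(m, problem20)
            assert ok

    def test_same_seed_same_population(self, problem20):
        cfg = small_cfg(seed=7)
        p1 = E.init_from_sections(problem20, cfg)
        p2 = E.init_from_sections(problem20, cfg)
        for a, b in zip(p1.members, p2.members):
            assert np.array_equal(a.order, b.order)

    def test_disconnected_dataset_refused(self):
        ds = make_dataset({"S1": {"a": [1, 2]}, "S2": {"b": [1, 2]}})
        with pytest.raises(P.InfeasibleError, match="component"):
            E.init_from_sections(ss.compile_problem(ds), small_cfg())

    def test_init_from_sequences_fills_and_checks(self, problem20):
        rng = np.random.default_rng(5)
        seqs = [P.CompositeSequence(random_feasible_order(problem20, rng))
                for _ in range(3)]
        for s in seqs:
            P.total_penalty(s, problem20)
        cfg = small_cfg(population_size=8)
        pop = E.init_from_sequences(seqs, problem20, cfg)
        assert len(pop.members) == 8
        assert pop.best_penalty <= min(s.cached_penalty for s in seqs) + 1e-12
        for m in pop.members:
            ok, _ = P.feasible(m, problem20)
            assert ok

    def test_init_from_sequences_rejects_infeasible(self, problem20):
        bad = P.CompositeSequence(np.arange(problem20.n_events)[::-1].copy())
        with pytest.raises(P.InfeasibleError):
            E.init_from_sequences([bad], problem20, small_cfg())


class TestRun:
    def test_zero_conflict_terminates_at_zero(self, agree_problem):
        best, hist = ss.evolve_run(agree_problem, small_cfg())
        assert best.cached_penalty == pytest.approx(0.0)

    def test_best_trace_monotone_and_reproducible(self, problem20):
        cfg = small_cfg(steps=15, trials=1500, seed=3)
        best1, h1 = ss.evolve_run(problem20, cfg)
        best2, h2 = ss.evolve_run(problem20, cfg)
        assert np.all(np.diff(h1["best"].to_numpy()) <= 1e-12)
        assert np.array_equal(best1.order, best2.order)
        assert h1.equals(h2)

    def test_zero_temperature_is_strict_descent(self, problem20):
        cfg = small_cfg(start_temperature=0.0, steps=8, trials=800,
                        recombination_rate=0.0, memory_replay_rate=0.0)
        _, hist = ss.evolve_run(problem20, cfg)
        # with only-improving acceptance every member is non-increasing,
        # so the population mean never rises
        means = hist["population_mean"].to_numpy()
        assert np.all(np.diff(means) <= 1e-9)

    def test_convergence_patience_stops_early(self, agree_problem):
        cfg = small_cfg(steps=10, trials=1000, convergence_patience=2)
        _, hist = ss.evolve_run(agree_problem, cfg)
        assert len(hist) <= 4


class TestCompare:
    def test_equal_configs_identical_results(self, problem20):
        cfg = small_cfg(steps=5, trials=400)
        df = ss.compare_runs(problem20.ds, cfg, cfg_baseline=cfg, n_seeds=2)
        assert np.allclose(df["ea_penalty"], df["baseline_penalty"])
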