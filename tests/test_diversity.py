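"""Richness counting, proportional rates, rarefaction and normalisation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import stratseq as ss
from stratseq import calibrate as C
from stratseq import diversity as D
from stratseq import penalty as P

from conftest import consistent_dataset, random_feasible_order


def expected_rarefied(counts, n):
    """Hypergeometric closed form E[S_n] = sum_i 1 - C(N-N_i, n)/C(N, n)."""
    counts = np.asarray(counts)
    N = counts.sum()
    return float(sum(1 - comb(N - c, n, exact=True) / comb(N, n, exact=True)
                     for c in counts))


class TestUnbinnedRichness:
    def test_running_sum_matches_direct_count(self, problem20):
        rng = np.random.default_rng(0)
        for _ in range(10):
            seq = P.CompositeSequence(random_feasible_order(problem20, rng))
            P.total_penalty(seq, problem20)
            levels = C.cluster_levels(seq, problem20, merge=False)
            rich = D.unbinned_richness(levels, problem20)["richness"].to_numpy()
            ranges = D.taxon_level_ranges(levels, problem20)
            for k in range(len(levels)):
                direct = int(((ranges["fad_level"] <= k) &
                              (k <= ranges["lad_level"])).sum())
                assert rich[k] == direct

    def test_edge_levels(self, problem20):
        rng = np.random.default_rng(1)
        seq = P.CompositeSequence(random_feasible_order(problem20, rng))
        P.total_penalty(seq, problem20)
        levels = C.cluster_levels(seq, problem20, merge=False)
        rich = D.unbinned_richness(levels, problem20)["richness"].to_numpy()
        assert rich[0] >= 1  # the oldest level hosts at least its own FAD
        assert rich[-1] >= 1

    def test_genus_collapse_and_ratio(self):
        ds, _ = consistent_dataset(n_taxa=6, n_sections=2, seed=3)
        # assign genera: two taxa per genus
        for i, (tid, t) in enumerate(sorted(ds.taxa.items())):
            ds.taxa[tid] = type(t)(tid, name=tid, genus=f"G{i // 2}", group=t.group)
        prob = ss.compile_problem(ds)
        rng = np.random.default_rng(2)
        seq = P.CompositeSequence(random_feasible_order(prob, rng))
        P.total_penalty(seq, prob)
        levels = C.cluster_levels(seq, prob, merge=False)
        out = D.unbinned_richness(levels, prob)
        assert (out["genus_richness"] <= out["richness"]).all()
        sel = out["genus_richness"] > 0
        assert np.allclose(out.loc[sel, "species_genus_ratio"],
                           out.loc[sel, "richness"] / out.loc[sel, "genus_richness"])


class TestBinnedRates:
    def test_rate_arithmetic(self):
        # 10 taxa alive through one 0.2-Myr bin, 2 originating inside it
        fad = np.array([1.1, 1.15] + [2.0] * 8)
        lad = np.array([0.5] * 10)
        df = D.binned_rates(fad, lad, bin_width=0.2)
        row = df[(df["bin_old"] >= 1.15) & (df["bin_young"] <= 1.1)].iloc[0]
        assert row["n_lineages"] == 10
        assert row["n_orig"] == 2
        assert row["origination"] == pytest.approx(2 / (10 * 0.2))
        assert row["turnover"] == pytest.approx(row["origination"] + row["extinction"])
        assert row["net_diversification"] == pytest.approx(
            row["origination"] - row["extinction"])

    def test_eventless_bins_have_zero_rates(self):
        fad = np.array([3.0, 2.9])
        lad = np.array([0.1, 0.2])
        df = D.binned_rates(fad, lad, bin_width=0.2)
        mid = df[(df["bin_old"] < 2.5) & (df["bin_young"] > 0.5)]
        assert (mid["origination"] == 0).all()
        assert (mid["extinction"] == 0).all()

    def test_origination_totals_preserved(self):
        rng = np.random.default_rng(4)
        fad = rng.uniform(1, 10, 50)
        lad = fad - rng.uniform(0.1, 3, 50)
        df = D.binned_rates(fad, lad, bin_width=0.2)
        assert df["n_orig"].sum() == 50
        assert df["n_ext"].sum() == 50

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            D.binned_rates(np.array([1.0]), np.array([0.5]), bin_width=0)


class TestRarefy:
    def test_full_sample_returns_all_taxa(self):
        counts = [5, 3, 2]
        mean, lo, hi = D.rarefy(counts, 10, iters=200, seed=0)
        assert mean == 3.0 and lo == 3.0 and hi == 3.0

    def test_single_draw(self):
        mean, *_ = D.rarefy([4, 4], 1, iters=200, seed=0)
        assert mean == 1.0

    def test_oversized_sample_missing(self):
        mean, lo, hi = D.rarefy([2, 2], 10, iters=10, seed=0)
        assert np.isnan(mean) and np.isnan(lo) and np.isnan(hi)

    def test_monotone_in_n_and_bounded(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 20, size=12)
        means = [D.rarefy(counts, n, iters=400, seed=6)[0]
                 for n in (5, 15, 30, int(counts.sum()))]
        assert all(b >= a - 0.15 for a, b in zip(means, means[1:]))
        assert means[-1] == len(counts)

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            counts = rng.integers(1, 15, size=8)
            n = int(rng.integers(2, counts.sum()))
            mean, _, _ = D.rarefy(counts, n, iters=800, seed=int(rng.integers(1e6)))
            want = expected_rarefied(counts, n)
            se = np.sqrt(len(counts)) / np.sqrt(800)  # generous MC bound
            assert abs(mean - want) < 3 * max(se, 0.05)


class TestMinMax:
    def test_example_and_affine_invariance(self):
        assert np.allclose(D.minmax_normalize([2, 4, 6]), [0, 0.5, 1])
        x = np.array([3.0, 1.0, 7.0, 5.0])
        assert np.allclose(D.minmax_normalize(2.5 * x + 4), D.minmax_normalize(x))

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            D.minmax_normalize([1.0, 1.0])


@pytest.fixture(scope="module")
def calibrated(problem20, optimized20):
    best, _ = optimized20
    levels = C.cluster_levels(best, problem20)
    rng = np.random.default_rng(8)
    n = len(levels)
    ranks = np.sort(rng.choice(n, size=min(10, n - 1), replace=False)).astype(float)
    ages = 48 - 28 * ranks / (n - 1) + rng.normal(0, 0.1, ranks.size)
    model = C.bootstrap_age_curve(ranks, ages, n, n_boot=80, seed=9)
    return levels, model


class TestBootstrapSeries:
    def test_richness_envelope_brackets_point(self, problem20, calibrated):
        levels, model = calibrated
        grid = np.arange(np.ceil(model.level_ages.min()) + 1,
                         np.floor(model.level_ages.max()) - 1, 0.5)
        out = D.bootstrap_richness(levels, problem20, model, grid)
        assert (out["lo"] <= out["richness"] + 1e-12).all()
        assert (out["hi"] >= out["richness"] - 1e-12).all()

    def test_zero_uncertainty_collapses_envelope(self, problem20, optimized20):
        best, _ = optimized20
        levels = C.cluster_levels(best, problem20)
        n = len(levels)
        ranks = np.linspace(0, n - 1, 8)
        ages = 48 - 28 * ranks / (n - 1)  # exact line, no noise
        model = C.bootstrap_age_curve(ranks, ages, n, n_boot=60, seed=10)
        grid = np.arange(21, 47, 0.5)
        out = D.bootstrap_richness(levels, problem20, model, grid)
        assert np.allclose(out["lo"], out["richness"])
        assert np.allclose(out["hi"], out["richness"])

    def test_rate_envelopes_well_formed(self, problem20, calibrated):
        levels, model = calibrated
        out = D.bootstrap_rates(levels, problem20, model, bin_width=1.0)
        assert {"origination_lo", "origination_hi",
                "extinction_lo", "extinction_hi"} <= set(out.columns)
        ok = out["origination_lo"].notna() & out["origination_hi"].notna()
        assert (out.loc[ok, "origination_lo"] <= out.loc[ok, "origination_hi"] + 1e-9).all()
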