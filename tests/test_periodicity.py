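"""Unit and property tests for filtering, normalization, the two rank tests,
rank combination and the dual-cutoff selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau

from cycletx import (
    PeriodicityParams,
    SelectionRule,
    average_replicates,
    filter_expressed,
    jtk_pvalue,
    rain_pvalue,
    rank_and_combine,
    select_periodic,
    zscore_normalize,
)
from cycletx.periodicity import jtk_waveform_pvalues, rain_waveform_pvalues

from conftest import make_timecourse


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

class TestFilterExpressed:
    def test_strict_inequality_at_threshold(self):
        tc = make_timecourse([[0.99, 0.99], [1.01, 1.01]], times=[0.0, 1.0])
        kept = filter_expressed(tc, 1.0)
        assert kept.gene_ids == ["g1"]

    def test_threshold_zero_is_identity_for_positive_matrix(self):
        tc = make_timecourse([[2.0, 11.0], [4.0, 5.0]], times=[0.0, 1.0])
        kept = filter_expressed(tc, 0.0)
        assert kept.gene_ids == tc.gene_ids
        np.testing.assert_array_equal(kept.values, tc.values)

    def test_three_gene_toy(self):
        tc = make_timecourse([[2.0, 2.0], [11.0, 11.0], [10.0, 10.0]], times=[0.0, 1.0])
        kept = filter_expressed(tc, 10.0)
        assert kept.gene_ids == ["g1"]


class TestZscore:
    def test_closed_form_population_sd(self):
        tc = make_timecourse([[1.0, 2.0, 3.0]], times=[0, 1, 2])
        z = zscore_normalize(tc)
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3.0 / 2.0)
        np.testing.assert_allclose(z.values[0], expected, atol=1e-12)
        assert abs(z.values[0].mean()) < 1e-9
        assert abs(z.values[0].std(ddof=0) - 1) < 1e-9

    def test_idempotent(self):
        tc = make_timecourse(np.random.default_rng(0).gamma(2, 5, size=(5, 8)))
        once = zscore_normalize(tc)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_constant_row_error_names_gene(self):
        tc = make_timecourse([[5.0, 5.0, 5.0]], gene_ids=["flatgene"], times=[0, 1, 2])
        with pytest.raises(ValueError, match="flatgene"):
            zscore_normalize(tc)


class TestAverageReplicates:
    def test_mean_of_cells(self):
        a = make_timecourse([[2.0, 2.0]], times=[0, 1])
        b = make_timecourse([[4.0, 4.0]], times=[0, 1])
        avg = average_replicates([a, b])
        np.testing.assert_array_equal(avg.values, [[3.0, 3.0]])

    def test_equal_replicates_identity(self, tiny_tc):
        avg = average_replicates([tiny_tc, tiny_tc])
        np.testing.assert_array_equal(avg.values, tiny_tc.values)

    def test_mismatched_gene_sets_reported(self):
        a = make_timecourse([[1.0, 1.0]], gene_ids=["gA"], times=[0, 1])
        b = make_timecourse([[1.0, 1.0]], gene_ids=["gB"], times=[0, 1])
        with pytest.raises(ValueError, match="gA"):
            average_replicates([a, b])


# ---------------------------------------------------------------------------
# JTK-style test
# ---------------------------------------------------------------------------

class TestJtk:
    def test_constant_series_degenerate(self, fast_params):
        res = jtk_pvalue(np.full(16, 3.0), fast_params)
        assert res.p == 1.0
        assert res.degenerate

    def test_exact_waveform_pvalues_match_enumeration(self, exact_params):
        """Per-waveform p equals the full-permutation tail of Kendall tau."""
        rng = np.random.default_rng(5)
        series = rng.normal(size=6)
        table = jtk_waveform_pvalues(series, exact_params)
        t = np.arange(6)
        perms = list(itertools.permutations(series))
        for period, lag, p_impl in zip(table["period"], table["lag"], table["p"]):
            ref = np.cos(2 * np.pi * (t - lag) / period)
            tau_obs = kendalltau(series, ref).statistic
            taus = np.array([kendalltau(np.array(pm), ref).statistic for pm in perms])
            p_oracle = np.mean(taus >= tau_obs - 1e-12)
            assert abs(p_impl - p_oracle) < 1e-12

    def test_noiseless_cosine_attains_grid_minimum(self):
        params = PeriodicityParams(n_permutations=20000, seed=11)
        t = np.arange(16)
        series = np.cos(2 * np.pi * t / 16)
        table = jtk_waveform_pvalues(series, params)
        # own waveform (period 16, lag 0) carries the smallest achievable p
        best = table.loc[(table.period == 16) & (table.lag == 0), "p"].iloc[0]
        assert best == table["p"].min()
        assert best <= 2.0 / params.n_permutations

    def test_sign_reversal_antiphase_symmetry(self):
        # even period: the negated reference is on the lag grid itself
        params = PeriodicityParams(period_grid_samples=(16,), n_permutations=2000, seed=7)
        rng = np.random.default_rng(3)
        series = np.cos(2 * np.pi * np.arange(16) / 16) + 0.3 * rng.normal(size=16)
        fwd = jtk_pvalue(series, params)
        rev = jtk_pvalue(-series, params)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)
        assert rev.best_lag == (fwd.best_lag + fwd.best_period // 2) % fwd.best_period

    def test_short_series_rejected(self, fast_params):
        with pytest.raises(ValueError):
            jtk_pvalue(np.array([1.0, 2.0, 3.0]), fast_params)


class TestRain:
    def test_constant_series_p_one(self, fast_params):
        assert rain_pvalue(np.full(16, 2.0), fast_params).p == 1.0

    def test_exact_umbrella_matches_hand_enumeration(self, exact_params):
        """Exact-mode umbrella p equals a hand-coded full enumeration."""
        rng = np.random.default_rng(8)
        series = rng.normal(size=6)
        table = rain_waveform_pvalues(series, exact_params)

        def umbrella_stat(x, peak, trough, period=6):
            # concordance along the circular rise (trough->peak) and fall
            def arc(start, stop):
                out, s = [], start
                while True:
                    out.append(s)
                    if s == stop:
                        break
                    s = (s + 1) % period
                return out
            stat = 0.0
            for positions, sgn in ((arc(trough, peak), 1), (arc(peak, trough), -1)):
                for a in range(len(positions)):
                    for b in range(a + 1, len(positions)):
                        stat += sgn * np.sign(x[positions[b]] - x[positions[a]])
            return stat

        perms = [np.array(pm) for pm in itertools.permutations(series)]
        for peak, trough, p_impl in zip(table["peak"], table["trough"], table["p"]):
            s_obs = umbrella_stat(series, peak, trough)
            null = np.array([umbrella_stat(pm, peak, trough) for pm in perms])
            p_oracle = np.mean(null >= s_obs - 1e-12)
            assert abs(p_impl - p_oracle) < 1e-12

    def test_rise_fall_peak_detected(self, fast_params):
        series = np.concatenate([np.arange(9.0), 8.0 - 1.1 * np.arange(1, 8)])
        res = rain_pvalue(series, fast_params)
        assert res.p <= 5e-3
        assert res.best_peak == 8

    def test_null_noise_not_anticonservative(self, fast_params):
        rng = np.random.default_rng(21)
        ps = np.array([rain_pvalue(rng.normal(size=16), fast_params).p
                       for _ in range(120)])
        # stochastically >= uniform within Monte-Carlo slack
        assert (ps < 0.05).mean() <= 0.11
        assert ps.mean() > 0.4


# ---------------------------------------------------------------------------
# ranking and selection
# ---------------------------------------------------------------------------

class TestRankAndCombine:
    def test_three_gene_hand_example(self):
        p_jtk = pd.Series({"gA": 0.001, "gB": 0.5, "gC": 0.9})
        p_rain = pd.Series({"gA": 0.002, "gB": 0.8, "gC": 0.4})
        table = rank_and_combine(p_jtk, p_rain).set_index("gene_id")
        assert table.loc["gA", "combined_rank"] == 2
        assert table.loc["gB", "combined_rank"] == 5
        assert table.loc["gC", "combined_rank"] == 5

    def test_identical_pvalues_rank_by_gene_id(self):
        genes = ["gC", "gA", "gB"]
        p = pd.Series(0.5, index=genes)
        table = rank_and_combine(p, p).set_index("gene_id")
        assert list(table.sort_values("rank_jtk").index) == ["gA", "gB", "gC"]
        assert (table["combined_rank"] == 2 * table["rank_jtk"]).all()

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError):
            rank_and_combine(pd.Series({"a": 0.1}), pd.Series({"a": 0.1, "b": 0.2}))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=40))
    def test_bh_and_rank_invariants(self, ps):
        genes = [f"g{i:03d}" for i in range(len(ps))]
        pj = pd.Series(ps, index=genes)
        pr = pd.Series(list(reversed(ps)), index=genes)
        table = rank_and_combine(pj, pr)
        n = len(ps)
        for col in ("rank_jtk", "rank_rain"):
            assert sorted(table[col]) == list(range(1, n + 1))
        assert (table["combined_rank"] >= 2).all()
        assert (table["q_jtk"] >= table["p_jtk"] - 1e-15).all()
        assert (table["q_jtk"] <= 1.0).all()
        # BH is monotone: sorting by raw p never decreases q
        srt = table.sort_values("p_jtk")
        assert (np.diff(srt["q_jtk"]) >= -1e-15).all()


def _rank_table(ranks: dict) -> pd.DataFrame:
    return pd.DataFrame({"gene_id": list(ranks), "combined_rank": list(ranks.values())})


class TestSelectPeriodic:
    def test_five_gene_hand_fixture(self):
        rep1 = _rank_table({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        rep2 = _rank_table({"a": 2, "b": 3, "c": 1, "d": 5, "e": 4})
        avg = _rank_table({"a": 2, "b": 3, "c": 1, "d": 4, "e": 5})
        rule = SelectionRule(loose_cutoff=3, strict_cutoff=2)
        assert select_periodic(rep1, rep2, avg, rule) == ["c", "a"]

    def test_manual_include_beyond_cutoff(self):
        ranks = {f"g{i}": i for i in range(1, 11)}
        t = _rank_table(ranks)
        rule = SelectionRule(loose_cutoff=5, strict_cutoff=3, manual_include=("g9",))
        out = select_periodic(t, t, t, rule)
        assert "g9" in out
        assert len(out) == 4  # min(strict, candidates) + 1 manual include

    def test_all_selected_when_cutoffs_cover_universe(self):
        ranks = {f"g{i}": i for i in range(1, 6)}
        t = _rank_table(ranks)
        rule = SelectionRule(loose_cutoff=5, strict_cutoff=5)
        assert set(select_periodic(t, t, t, rule)) == set(ranks)

    def test_manual_include_unknown_gene_rejected(self):
        t = _rank_table({"a": 1})
        with pytest.raises(ValueError, match="ghost"):
            select_periodic(t, t, t, SelectionRule(1, 1, manual_include=("ghost",)))

    def test_enlarging_loose_cutoff_monotone_below_capacity(self):
        # while candidates stay below the strict capacity, widening the loose
        # net only ever adds genes
        genes = [f"g{i:02d}" for i in range(1, 31)]
        rep1 = _rank_table({g: i for i, g in enumerate(genes, start=1)})
        rep2 = _rank_table({g: 31 - i for i, g in enumerate(genes, start=1)})
        avg = rep1
        base = set(select_periodic(rep1, rep2, avg, SelectionRule(16, 5)))
        assert base == {"g15", "g16"}  # candidates below strict capacity
        wider = set(select_periodic(rep1, rep2, avg, SelectionRule(18, 5)))
        assert base <= wider and len(wider) == 5
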