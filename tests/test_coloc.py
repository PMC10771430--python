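"""Colocalization: Bayes factors, H0-H4 enumeration, fine-mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pqtlmr.coloc import (
    DEFAULT_PRIOR_SD,
    coloc_abf,
    coloc_susie,
    log_abf,
    multi_trait_coloc,
    susie_rss,
)
from pqtlmr.simulate import SimConfig, simulate_region, simulate_tables
from conftest import ar1_ld


class TestLogABF:
    def test_null_beta_shrinks(self):
        se = 0.1
        r = DEFAULT_PRIOR_SD**2 / (DEFAULT_PRIOR_SD**2 + se**2)
        val = log_abf(0.0, se)
        assert val == pytest.approx(0.5 * np.log1p(-r))
        assert val < 0

    def test_large_z_limit(self):
        """For V << prior^2, log ABF -> z^2/2 + 0.5 log(V/prior^2)."""
        se, z = 1e-4, 5.0
        beta = z * se
        expected = z**2 / 2 + 0.5 * np.log(se**2 / DEFAULT_PRIOR_SD**2)
        assert log_abf(beta, se) == pytest.approx(expected, rel=1e-3)

    def test_monotone_in_abs_z(self):
        se = 0.05
        zs = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        vals = log_abf(zs * se, np.full_like(zs, se))
        assert np.all(np.diff(vals) > 0)

    def test_no_overflow_extreme_z(self):
        val = log_abf(200.0 * 0.01, 0.01)
        assert np.isfinite(val)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            log_abf(0.1, 0.0)


class TestColocABF:
    def test_null_region_h0(self):
        region = simulate_region(SimConfig(causal_model="null", n_snps=500, seed=2))
        res = coloc_abf(region.tables["exposure"], region.tables["outcome"])
        assert res["h0"] > 0.9

    def test_pp_sums_to_one(self):
        region = simulate_region(SimConfig(seed=0, n_snps=50))
        res = coloc_abf(region.tables["exposure"], region.tables["outcome"])
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_up_to_h1_h2_swap(self):
        region = simulate_region(SimConfig(seed=1, n_snps=50))
        t1, t2 = region.tables["exposure"], region.tables["outcome"]
        a = coloc_abf(t1, t2, priors=(1e-4, 2e-4, 1e-5))
        b = coloc_abf(t2, t1, priors=(2e-4, 1e-4, 1e-5))
        np.testing.assert_allclose(
            a.pp, b.pp[[0, 2, 1, 3, 4]], atol=1e-12
        )

    def test_maf_filter_applied(self):
        region = simulate_region(SimConfig(seed=0, n_snps=20))
        # force one SNP below the MAF cut in both tables
        for tab in region.tables.values():
            tab.df.loc[0, "eaf"] = 0.005
        res = coloc_abf(region.tables["exposure"], region.tables["outcome"])
        assert res.n_snps == 19

    def test_no_shared_snps_errors(self):
        r1 = simulate_region(SimConfig(seed=0, n_snps=5))
        r2 = simulate_region(SimConfig(seed=0, n_snps=5))
        r2.tables["outcome"].df["snp"] = [f"x{i}" for i in range(5)]
        t2 = r2.tables["outcome"]
        with pytest.raises(ValueError, match="no shared"):
            coloc_abf(r1.tables["exposure"], t2)

    def test_window_filter(self):
        region = simulate_region(SimConfig(seed=0, n_snps=21))
        center = int(region.variants["pos"].iloc[10])
        res = coloc_abf(
            region.tables["exposure"], region.tables["outcome"],
            window=100_000, center_pos=center,
        )
        assert res.n_snps < 21

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_pp_always_normalized(self, seed):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.normal(0, 3, 30), rng.normal(0, 3, 30)
        l1 = log_abf(z1 * 0.02, np.full(30, 0.02))
        l2 = log_abf(z2 * 0.02, np.full(30, 0.02))
        from pqtlmr.coloc import _enumerate

        res = _enumerate(l1, l2, (1e-4, 1e-4, 1e-5), None)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.pp >= 0)


class TestSusieRSS:
    def test_single_causal_recovered(self):
        hits = 0
        reps = 25
        for s in range(reps):
            region = simulate_region(SimConfig(n_snps=100, seed=s))
            tab = region.tables["exposure"]
            z = (tab.df["beta"] / tab.df["se"]).to_numpy()
            fit = susie_rss(z, region.ld, 3301, L=5)
            causal = region.ld.snps[region.truth["effects"]["exposure"]["index"]]
            hits += len(fit.credible_sets) == 1 and causal in fit.credible_sets[0].snps
        assert hits >= 0.9 * reps

    def test_two_independent_signals_two_sets(self):
        ld = ar1_ld(80, 0.9)
        effects = np.zeros(80)
        effects[10] = 0.2
        effects[70] = 0.2  # r(10,70) ~ 0.9^60 ~ 0
        tabs = simulate_tables({"t": effects}, {"t": 10_000}, ld, np.full(80, 0.3), seed=4)
        z = (tabs["t"].df["beta"] / tabs["t"].df["se"]).to_numpy()
        fit = susie_rss(z, ld, 10_000, L=5)
        assert len(fit.credible_sets) == 2
        sets = [set(cs.indices) for cs in fit.credible_sets]
        assert not (sets[0] & sets[1])

    def test_null_z_no_credible_sets(self):
        ld = ar1_ld(50, 0.8)
        rng = np.random.default_rng(0)
        fit = susie_rss(rng.standard_normal(50), ld, 10_000, L=5)
        assert fit.credible_sets == []

    def test_alpha_rows_normalized(self):
        region = simulate_region(SimConfig(n_snps=40, seed=0))
        z = (region.tables["exposure"].df["beta"] / region.tables["exposure"].df["se"]).to_numpy()
        fit = susie_rss(z, region.ld, 3301, L=4)
        np.testing.assert_allclose(fit.alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_credible_sets_meet_coverage_and_purity(self):
        region = simulate_region(SimConfig(n_snps=60, seed=1))
        z = (region.tables["exposure"].df["beta"] / region.tables["exposure"].df["se"]).to_numpy()
        fit = susie_rss(z, region.ld, 3301, L=5, coverage=0.95, purity_min=0.5)
        for cs in fit.credible_sets:
            assert cs.coverage >= 0.95
            assert cs.purity >= 0.5


class TestColocSusie:
    def test_identical_fits_diagonal_h4(self):
        region = simulate_region(SimConfig(n_snps=60, seed=3))
        z = (region.tables["exposure"].df["beta"] / region.tables["exposure"].df["se"]).to_numpy()
        fit = susie_rss(z, region.ld, 3301, L=3)
        assert fit.credible_sets
        results = coloc_susie(fit, fit)
        for res in results:
            i, j = res.components
            if i == j:
                assert res.argmax == "h4"

    def test_disjoint_signals_h3(self):
        ld = ar1_ld(80, 0.9)
        e1, e2 = np.zeros(80), np.zeros(80)
        e1[10] = 0.2
        e2[70] = 0.15
        tabs = simulate_tables(
            {"t1": e1, "t2": e2}, {"t1": 10_000, "t2": 20_000}, ld, np.full(80, 0.3), seed=0
        )
        z1 = (tabs["t1"].df["beta"] / tabs["t1"].df["se"]).to_numpy()
        z2 = (tabs["t2"].df["beta"] / tabs["t2"].df["se"]).to_numpy()
        f1 = susie_rss(z1, ld, 10_000, L=3)
        f2 = susie_rss(z2, ld, 20_000, L=3)
        results = coloc_susie(f1, f2)
        assert results and all(res.argmax == "h3" for res in results)

    def test_no_credible_sets_empty(self):
        ld = ar1_ld(30, 0.5)
        rng = np.random.default_rng(0)
        f1 = susie_rss(rng.standard_normal(30), ld, 5000, L=2)
        f2 = susie_rss(rng.standard_normal(30), ld, 5000, L=2)
        assert coloc_susie(f1, f2) == []

    def test_l1_matches_abf_ordering(self):
        """Single-signal simulations: susie-pairwise and single-variant
        coloc agree on the winning hypothesis."""
        agree, tried = 0, 0
        for s in range(20):
            region = simulate_region(SimConfig(n_snps=60, seed=100 + s))
            t1, t2 = region.tables["exposure"], region.tables["outcome"]
            abf = coloc_abf(t1, t2, maf_min=0.0)
            z1 = (t1.df["beta"] / t1.df["se"]).to_numpy()
            z2 = (t2.df["beta"] / t2.df["se"]).to_numpy()
            f1 = susie_rss(z1, region.ld, 3301, L=1)
            f2 = susie_rss(z2, region.ld, 370_000, L=1)
            pairs = coloc_susie(f1, f2)
            if pairs:
                tried += 1
                agree += pairs[0].argmax == abf.argmax
        assert tried >= 15 and agree >= 0.95 * tried


class TestMultiTraitColoc:
    def _three(self, third_null=False, seed=0):
        ld = ar1_ld(60, 0.8)
        e = np.zeros(60)
        e[30] = 0.1
        effects = {"a": e, "b": e, "c": np.zeros(60) if third_null else e}
        return simulate_tables(
            effects, {t: 20_000 for t in effects}, ld, np.full(60, 0.3), seed=seed
        )

    def test_all_shared_high_pp(self):
        tabs = self._three()
        res = multi_trait_coloc(list(tabs.values()))
        assert res.pp_all_shared > 0.8
        assert res.candidate_snp is not None

    def test_one_null_trait_reports_none(self):
        tabs = self._three(third_null=True)
        res = multi_trait_coloc(list(tabs.values()))
        assert res.candidate_snp is None

    def test_trait_order_invariant(self):
        tabs = list(self._three().values())
        a = multi_trait_coloc(tabs)
        b = multi_trait_coloc(tabs[::-1])
        assert a.pp_all_shared == pytest.approx(b.pp_all_shared, abs=1e-12)
        assert a.candidate_snp == b.candidate_snp

    def test_two_traits_rejected(self):
        tabs = list(self._three().values())[:2]
        with pytest.raises(ValueError, match="coloc_abf"):
            multi_trait_coloc(tabs)

    def test_flagged_simplified(self):
        res = multi_trait_coloc(list(self._three().values()))
        assert "simplified" in res.method


def test_log_space_no_overflow_extreme_signals():
    """|z| up to 200 in both traits stays finite and H4-dominant."""
    ld = ar1_ld(20, 0.5)
    se = np.full(20, 0.01)
    beta1 = np.zeros(20)
    beta1[10] = 200 * 0.01
    import pandas as pd
    from pqtlmr.sumstats import SummaryStatsTable

    def tab(name, beta):
        return SummaryStatsTable(
            name,
            pd.DataFrame(
                {
                    "snp": ld.snps, "chr": "1", "pos": range(1, 21),
                    "ea": "A", "nea": "G", "eaf": 0.3,
                    "beta": beta, "se": se,
                    "pval": 0.5, "n": 1000,
                }
            ),
        )

    res = coloc_abf(tab("t1", beta1), tab("t2", beta1.copy()))
    assert np.all(np.isfinite(res.pp))
    assert res.argmax == "h4"
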