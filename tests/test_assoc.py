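import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mixqtl import (
    FilterConfig,
    SimConfig,
    fit_asc,
    fit_trc,
    meta_combine,
    permute_gene,
    prepare_gene,
    run_cis_scan,
    simulate_dataset,
)


class TestFitTrc:
    def test_perfect_fit(self):
        x = np.tile([0.0, 0.5, 1.0], 4)[:10]
        y = 0.3 * x
        beta, se, p, n = fit_trc(y, x)
        assert beta == pytest.approx(0.3, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_variant_is_na(self):
        beta, se, p, n = fit_trc(np.random.default_rng(0).normal(size=10),
                                 np.zeros(10))
        assert np.isnan(beta) and np.isnan(p)

    def test_matches_ols_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(10, 60)
            x = rng.choice([0.0, 0.5, 1.0], size=n, p=[0.5, 0.4, 0.1])
            if np.var(x) == 0:
                continue
            y = 0.2 * x + rng.normal(0, 0.5, size=n)
            beta, se, p, _ = fit_trc(y, x)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert beta == pytest.approx(fit.params[1], abs=1e-12)
            assert se == pytest.approx(fit.bse[1], abs=1e-12)
            assert p == pytest.approx(fit.pvalues[1], abs=1e-12)

    def test_recovers_simulated_effect_within_three_se(self):
        rng = np.random.default_rng(7)
        x = rng.choice([0.0, 0.5, 1.0], size=100, p=[0.49, 0.42, 0.09])
        y = 0.2 * x + rng.normal(0, 0.5, size=100)
        beta, se, _, _ = fit_trc(y, x)
        assert abs(beta - 0.2) < 3 * se


class TestFitAsc:
    def test_perfect_antisymmetric_fit(self):
        beta, se, p, n = fit_asc(np.array([0.7, -0.7, 0.7]),
                                 np.array([1.0, -1.0, 1.0]), np.ones(3))
        assert beta == pytest.approx(0.7, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_no_heterozygous_carriers_is_na(self):
        beta, *_ = fit_asc(np.ones(5), np.zeros(5), np.ones(5))
        assert np.isnan(beta)

    def test_matches_weighted_gls_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 50
            x = rng.choice([-1.0, 0.0, 1.0], size=n)
            w = rng.uniform(0.5, 30.0, size=n)
            y = 0.4 * x + rng.normal(0, 1.0 / np.sqrt(w))
            if not np.any(x != 0):
                continue
            beta, se, p, _ = fit_asc(y, x, w)
            fit = sm.WLS(y, x, weights=w).fit()
            assert beta == pytest.approx(fit.params[0], abs=1e-10)
            assert se == pytest.approx(fit.bse[0], abs=1e-10)
            assert p == pytest.approx(fit.pvalues[0], abs=1e-10)


class TestMetaCombine:
    def test_equal_weight_average(self):
        beta, se, _ = meta_combine(1.0, 1.0, 0.0, 1.0)
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-6)

    def test_infinite_variance_component_is_ignored(self):
        beta, se, p = meta_combine(0.8, 0.1, 0.0, 1e8)
        assert beta == pytest.approx(0.8, abs=1e-6)

    def test_normal_quantile(self):
        _, _, p = meta_combine(1.959964, 1.0, np.nan, np.nan)
        assert p == pytest.approx(0.05, abs=1e-5)

    def test_symmetry_and_precision_gain(self):
        b1, s1 = meta_combine(0.3, 0.2, -0.1, 0.4)[:2]
        b2, s2 = meta_combine(-0.1, 0.4, 0.3, 0.2)[:2]
        assert b1 == pytest.approx(b2) and s1 == pytest.approx(s2)
        assert s1 <= min(0.2, 0.4)

    def test_both_na_propagates(self):
        assert all(np.isnan(v) for v in meta_combine(np.nan, np.nan,
                                                     np.nan, np.nan))


class TestCisScan:
    def test_gene_without_asc_falls_back_to_trc(self, null_dataset):
        counts = null_dataset.counts
        counts_noasc = type(counts)(total=counts.total,
                                    asc1=np.zeros_like(counts.asc1),
                                    asc2=np.zeros_like(counts.asc2),
                                    libsize=counts.libsize)
        prep = prepare_gene(counts_noasc)
        res = run_cis_scan(prep, null_dataset.geno)
        assert all(r.method == "trc" for r in res)
        assert all(np.isnan(r.beta_asc) for r in res)

    def test_allele_flip_negates_betas_keeps_pvalues(self, signal_dataset):
        ds = signal_dataset
        prep = prepare_gene(ds.counts)
        res = run_cis_scan(prep, ds.geno)[0]
        flipped = type(ds.geno)(variant_ids=list(ds.geno.variant_ids),
                                positions=ds.geno.positions,
                                hap1=1 - ds.geno.hap1, hap2=1 - ds.geno.hap2,
                                samples=ds.geno.samples)
        res_f = run_cis_scan(prep, flipped)[0]
        assert res_f.beta_trc == pytest.approx(-res.beta_trc, rel=1e-9)
        assert res_f.beta_asc == pytest.approx(-res.beta_asc, rel=1e-9)
        assert res_f.p_meta == pytest.approx(res.p_meta, rel=1e-9)

    def test_combined_test_beats_trc_alone_in_most_replicates(self):
        wins = 0
        n_rep = 30
        for s in range(n_rep):
            ds = simulate_dataset(SimConfig(seed=6000 + s, afc=2.0))
            prep = prepare_gene(ds.counts)
            r = run_cis_scan(prep, ds.geno.subset_variants(ds.causal_idx))[0]
            z_meta = abs(r.beta_meta / r.se_meta)
            z_trc = abs(r.beta_trc / r.se_trc)
            wins += z_meta > z_trc
        assert wins > n_rep / 2


class TestPermutation:
    def test_deterministic_given_seed(self, null_dataset):
        prep = prepare_gene(null_dataset.counts)
        a = permute_gene(prep, seed=5)
        b = permute_gene(prep, seed=5)
        np.testing.assert_array_equal(a.y_trc, b.y_trc)
        np.testing.assert_array_equal(a.y_asc, b.y_asc)

    def test_single_sample_is_identity(self):
        from mixqtl import PreparedGene
        prep = PreparedGene(y_trc=np.array([1.0]), trc_mask=np.array([True]),
                            y_asc=np.array([0.5]), w=np.array([2.0]),
                            asc_mask=np.array([True]))
        out = permute_gene(prep, seed=0)
        assert out.y_trc[0] == 1.0 and out.y_asc[0] == 0.5

    def test_permuted_null_pvalues_are_uniform(self):
        """Scanning permuted data yields uniform p-values (KS at alpha=0.01)."""
        pvals = []
        cfg = FilterConfig()
        for s in range(150):
            ds = simulate_dataset(SimConfig(seed=8000 + s, n_samples=200,
                                            afc=1.5))
            prep = permute_gene(prepare_gene(ds.counts, cfg), seed=s)
            r = run_cis_scan(prep, ds.geno, cfg)[0]
            if np.isfinite(r.p_meta):
                pvals.append(r.p_meta)
        assert len(pvals) > 100
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
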