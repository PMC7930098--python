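import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixqtl import (
    FilterConfig,
    GeneCounts,
    adjust_covariates,
    cap_weights,
    compute_asc,
    compute_trc,
    gene_passes_asc_filters,
    prepare_gene,
)


def _counts(total, asc1, asc2, lib):
    return GeneCounts(total=np.asarray(total), asc1=np.asarray(asc1),
                      asc2=np.asarray(asc2), libsize=np.asarray(lib))


class TestComputeTrc:
    def test_log_ratio_formula(self):
        c = _counts([200], [0], [0], [1_000_000])
        y, mask = compute_trc(c)
        assert y[0] == pytest.approx(np.log(1e-4), abs=1e-6)
        assert y[0] == pytest.approx(-9.210340, abs=1e-6)

    def test_zero_count_imputed_to_one(self):
        y, _ = compute_trc(_counts([0], [0], [0], [1_000_000]))
        assert y[0] == pytest.approx(-14.508658, abs=1e-6)

    def test_count_equal_to_twice_libsize_gives_zero(self):
        y, _ = compute_trc(_counts([2_000_000], [0], [0], [1_000_000]))
        assert y[0] == pytest.approx(0.0, abs=1e-12)


class TestComputeAsc:
    def test_balanced_counts(self):
        y, w, mask = compute_asc(_counts([200], [50], [50], [1_000_000]))
        assert mask[0]
        assert y[0] == pytest.approx(0.0)
        assert w[0] == pytest.approx(25.0)

    def test_twofold_imbalance(self):
        y, w, _ = compute_asc(_counts([200], [100], [50], [1_000_000]))
        assert y[0] == pytest.approx(np.log(2), abs=1e-6)
        assert w[0] == pytest.approx(1.0 / 0.03, abs=1e-3)

    def test_outlier_and_low_count_masks(self):
        c = _counts([3000, 100, 100], [1200, 15, 16], [300, 50, 16], [1e6] * 3)
        _, _, mask = compute_asc(c)
        assert not mask[0]  # 1200 > 1000 outlier cap
        assert not mask[1]  # 15 is not strictly greater than the threshold
        assert mask[2]

    @given(a1=st.integers(16, 1000), a2=st.integers(16, 1000))
    @settings(max_examples=30, deadline=None)
    def test_log_ratio_antisymmetry(self, a1, a2):
        ya, _, _ = compute_asc(_counts([a1 + a2], [a1], [a2], [10**6]))
        yb, _, _ = compute_asc(_counts([a1 + a2], [a2], [a1], [10**6]))
        assert ya[0] == pytest.approx(-yb[0], abs=1e-12)


class TestCapWeights:
    def test_cap_at_ten_fold(self):
        np.testing.assert_allclose(cap_weights(np.array([5.0, 100.0]), n=200),
                                   [5.0, 50.0])

    def test_small_cohorts_get_tighter_cap(self):
        w = cap_weights(np.array([2.0, 100.0]), n=50)  # K = 5
        np.testing.assert_allclose(w, [2.0, 10.0])

    def test_equal_weights_unchanged(self):
        w = np.full(7, 3.3)
        np.testing.assert_allclose(cap_weights(w, n=100), w)

    def test_empty_input(self):
        assert cap_weights(np.array([]), n=100).size == 0

    @given(st.lists(st.floats(0.1, 1e4), min_size=1, max_size=30),
           st.integers(1, 2000))
    @settings(max_examples=50, deadline=None)
    def test_capped_ratio_never_exceeds_k(self, raw, n):
        w = cap_weights(np.array(raw), n=n)
        k = max(1.0, min(10.0, n / 10.0))
        assert w.max() / w.min() <= k * (1 + 1e-12)


class TestGeneFilters:
    def test_boundary_counts_pass(self):
        n = 515
        asc1 = np.r_[np.full(15, 50), np.zeros(n - 15, dtype=int)]
        total = np.r_[np.full(500, 100), np.zeros(n - 500, dtype=int)]
        c = _counts(total, asc1, asc1, np.full(n, 10**6))
        assert gene_passes_asc_filters(c)

    def test_one_fewer_asc_sample_fails(self):
        n = 515
        asc1 = np.r_[np.full(14, 50), np.zeros(n - 14, dtype=int)]
        total = np.full(n, 100)
        c = _counts(total, asc1, asc1, np.full(n, 10**6))
        assert not gene_passes_asc_filters(c)

    def test_zero_thresholds_always_pass(self):
        cfg = FilterConfig(gene_min_asc_samples=0, gene_asc_reads_per_hap=0,
                           gene_min_trc_samples=0, gene_trc_min_reads=0)
        c = _counts([0], [0], [0], [1])
        assert gene_passes_asc_filters(c, cfg)


class TestAdjustCovariates:
    def test_no_significant_covariate_returns_centered_y(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(200) + 5.0
        # covariates orthogonal to y by construction: independent noise,
        # regenerated until stage-1 keeps nothing
        for s in range(20):
            c = np.random.default_rng(100 + s).standard_normal((200, 2))
            out = adjust_covariates(y, c)
            if np.allclose(out, y - y.mean()):
                break
        else:
            pytest.fail("no draw produced an empty selection")

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal((100, 1))
        y = 2.0 * c[:, 0]
        out = adjust_covariates(y, c)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_monte_carlo_matches_direct_two_stage_oracle(self):
        """Residuals equal an independently coded two-stage OLS on shared data."""
        rng = np.random.default_rng(2)
        n = 500
        c = rng.standard_normal((n, 3))
        y = 0.5 * c[:, 0] + rng.standard_normal(n)
        out = adjust_covariates(y, c)

        # oracle: plain normal equations, selection by t-test
        from scipy import stats
        X = np.column_stack([np.ones(n), c])
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ bhat
        s2 = resid @ resid / (n - X.shape[1])
        cov = s2 * np.linalg.inv(X.T @ X)
        tstat = bhat / np.sqrt(np.diag(cov))
        pvals = 2 * stats.t.sf(np.abs(tstat), n - X.shape[1])
        keep = [j for j in range(1, 4) if pvals[j] < 0.05]
        X2 = np.column_stack([np.ones(n)] + [c[:, j - 1] for j in keep])
        b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
        np.testing.assert_allclose(out, y - X2 @ b2, atol=1e-8)
        assert np.var(out) == pytest.approx(1.0, rel=0.15)

    def test_output_centered_and_orthogonal_to_kept_covariates(self):
        rng = np.random.default_rng(3)
        n = 400
        c = rng.standard_normal((n, 2))
        y = 1.0 * c[:, 0] - 0.5 * c[:, 1] + rng.standard_normal(n)
        out = adjust_covariates(y, c)
        assert abs(out.mean()) < 1e-8
        assert abs(out @ c[:, 0]) < 1e-8 * n
        assert abs(out @ c[:, 1]) < 1e-8 * n

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n > K"):
            adjust_covariates(np.ones(3), np.ones((3, 3)))


def test_prepare_gene_combines_masks_and_caps(null_dataset):
    prep = prepare_gene(null_dataset.counts)
    assert prep.n_trc == null_dataset.counts.n_samples
    w = prep.w[prep.asc_mask]
    assert np.all(w > 0)
    assert w.max() / w.min() <= 10.0 + 1e-9
    assert np.all(np.isfinite(prep.y_asc[prep.asc_mask]))
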