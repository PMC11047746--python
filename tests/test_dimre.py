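import numpy as np
import pytest

from magecls.data import ExpressionMatrix, SyntheticSpec, generate_synthetic_mage
from magecls.dimre import (
    class_stats_summary,
    default_n_out,
    fft_forward,
    fft_inverse,
    fft_reduce,
    first_canonical_correlation,
    fit_gene_mixture,
    mm_reduce,
)


def brute_force_dft(x):
    """O(N^2) evaluation of X(c) = sum_n x_n exp(-2 pi i c n / N)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    n = np.arange(N)
    W = np.exp(-2j * np.pi * np.outer(n, n) / N)
    return W @ x


def _matrix_from(values):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    labels = ["ADCA"] * (s - s // 2) + ["MPM"] * (s // 2)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(s)],
        labels=labels,
    )


class TestFFT:
    def test_constant_signal_is_dc_only(self):
        s = fft_forward([3.0, 3.0, 3.0, 3.0])
        np.testing.assert_allclose(s.coefficients[0], 12.0, atol=1e-12)
        np.testing.assert_allclose(s.coefficients[1:], 0.0, atol=1e-12)

    def test_four_point_hand_values(self):
        s = fft_forward([1.0, 2.0, 3.0, 4.0])
        expected = np.array([10.0, -2.0 + 2.0j, -2.0, -2.0 - 2.0j])
        np.testing.assert_allclose(s.coefficients, expected, atol=1e-9)

    @pytest.mark.parametrize("N", [8, 64, 127, 256])
    def test_matches_brute_force(self, N):
        rng = np.random.default_rng(N)
        x = rng.normal(size=N)
        s = fft_forward(x)
        np.testing.assert_allclose(
            s.coefficients, brute_force_dft(x), rtol=1e-9, atol=1e-9
        )

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        s = fft_forward(x)
        np.testing.assert_allclose(
            np.sum(np.abs(x) ** 2),
            np.sum(np.abs(s.coefficients) ** 2) / 64,
            rtol=1e-12,
        )

    def test_conjugate_symmetry_for_real_input(self):
        x = np.random.default_rng(1).normal(size=32)
        c = fft_forward(x).coefficients
        np.testing.assert_allclose(c[1:], np.conj(c[1:][::-1]), atol=1e-9)

    def test_round_trip_identity(self):
        x = np.random.default_rng(2).normal(size=128)
        np.testing.assert_allclose(fft_inverse(fft_forward(x)), x, atol=1e-9)

    def test_inverse_of_dc_spectrum(self):
        from magecls.dimre import FFTSpectrum

        out = fft_inverse(FFTSpectrum(np.array([12.0, 0, 0, 0], dtype=complex), 4))
        np.testing.assert_allclose(out, [3.0, 3.0, 3.0, 3.0], atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fft_forward([])


class TestFFTReduce:
    def test_default_ratio(self):
        assert default_n_out(12_533) == 1253

    def test_constant_gene_vector_dc_only(self):
        m = _matrix_from(np.full((16, 2), 5.0))
        red = fft_reduce(m, n_out=4)
        np.testing.assert_allclose(red.values[:, 0], 16 * 5.0)
        np.testing.assert_allclose(red.values[:, 1:], 0.0, atol=1e-9)

    def test_matches_brute_force_magnitudes(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 3))
        red = fft_reduce(_matrix_from(vals), n_out=2)
        for j in range(3):
            spec = brute_force_dft(vals[:, j])
            np.testing.assert_allclose(
                red.values[j], np.abs(spec[:2]), rtol=1e-9, atol=1e-9
            )

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(30, 6))
        red = fft_reduce(_matrix_from(vals), n_out=5)
        perm = [5, 3, 0, 1, 4, 2]
        red_p = fft_reduce(_matrix_from(vals[:, perm]), n_out=5)
        np.testing.assert_allclose(red.values[perm], red_p.values)

    def test_n_out_bounds(self):
        m = _matrix_from(np.ones((10, 2)))
        with pytest.raises(ValueError):
            fft_reduce(m, n_out=11)


class TestGeneMixture:
    def test_unimodal_recovery_rate(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(0.0, 1.0, size=200)
            if fit_gene_mixture(x, seed=0).n_components == 1:
                hits += 1
        assert hits >= 45  # >= 90%

    def test_bimodal_recovery_rate_and_means(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            x = np.concatenate(
                [rng.normal(-5, 1, size=100), rng.normal(5, 1, size=100)]
            )
            res = fit_gene_mixture(x, seed=0)
            if res.n_components == 2:
                hits += 1
                assert abs(res.means[0] + 5) < 0.5
                assert abs(res.means[1] - 5) < 0.5
        assert hits >= 45

    def test_constant_input_degenerate(self):
        res = fit_gene_mixture(np.full(30, 7.0))
        assert res.n_components == 1
        assert res.variances[0] == pytest.approx(1e-6)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(-3, 1, 80), rng.normal(3, 1, 80)])
        res = fit_gene_mixture(x, seed=0)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bic_penalty_increases_with_params(self):
        # at equal likelihood the 5-parameter model must carry the larger
        # penalty: bic_2 - bic_1 = 3 ln(n) + 2(ln L1 - ln L2)
        rng = np.random.default_rng(12)
        x = rng.normal(size=150)
        res = fit_gene_mixture(x, seed=0)
        penalty_gap = 3 * np.log(res.n_obs)
        assert res.bic_2 - res.bic_1 >= penalty_gap - 2 * abs(
            res.log_likelihood
        ) * 0 - 1e-9 or res.bic_2 > res.bic_1 - penalty_gap


class TestMMReduce:
    def test_bimodal_genes_selected(self):
        rng = np.random.default_rng(21)
        n_samples = 80
        vals = rng.normal(0, 1, size=(100, n_samples))
        half = n_samples // 2
        for g in range(5):  # 6-SD separated mixture in the first 5 genes
            vals[g, :half] -= 3.0
            vals[g, half:] += 3.0
        red = mm_reduce(_matrix_from(vals), n_out=5)
        selected = {p.split()[0] for p in red.provenance.values()}
        assert selected == {f"gene_id=g{i}" for i in range(5)}

    def test_no_reduction_boundary_is_transpose(self):
        rng = np.random.default_rng(22)
        vals = rng.normal(size=(12, 9))
        red = mm_reduce(_matrix_from(vals), n_out=12)
        np.testing.assert_array_equal(red.values, vals.T)

    def test_deterministic_ranking(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(size=(30, 40))
        a = mm_reduce(_matrix_from(vals), n_out=10)
        b = mm_reduce(_matrix_from(vals), n_out=10)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.provenance == b.provenance


class TestClassStats:
    def test_symmetric_sequence_moments(self):
        from scipy import stats as ss

        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.mean(v) == 3.0
        assert np.var(v, ddof=1) == 2.5
        assert ss.skew(v, bias=False) == pytest.approx(0.0, abs=1e-12)

    def test_identical_classes_null_ttest(self):
        from magecls.dimre import ReducedFeatures

        block = np.random.default_rng(31).normal(size=(4, 6))
        vals = np.vstack([block, block])
        r = ReducedFeatures(values=vals, method="fft", n_out=6)
        labels = ["A"] * 4 + ["B"] * 4
        summ = class_stats_summary(r, labels)
        assert summ["A"].t_stat == pytest.approx(0.0, abs=1e-12)
        assert summ["A"].p_value == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_correlation_guard(self):
        from magecls.dimre import ReducedFeatures

        vals = np.vstack([np.ones((3, 5)), np.random.default_rng(32).normal(size=(3, 5))])
        r = ReducedFeatures(values=vals, method="fft", n_out=5)
        summ = class_stats_summary(r, ["A"] * 3 + ["B"] * 3)
        assert summ["A"].pcc is None  # zero-variance class block

    def test_per_class_moments_match_scipy(self):
        from scipy import stats as ss
        from magecls.dimre import ReducedFeatures

        rng = np.random.default_rng(33)
        vals = rng.lognormal(size=(10, 4))
        r = ReducedFeatures(values=vals, method="mm", n_out=4)
        summ = class_stats_summary(r, ["A"] * 5 + ["B"] * 5)
        a = vals[:5].ravel()
        assert summ["A"].mean == pytest.approx(a.mean())
        assert summ["A"].kurtosis == pytest.approx(
            ss.kurtosis(a, fisher=False, bias=False)
        )


class TestCanonicalCorrelation:
    def test_self_correlation_is_one(self):
        a = np.random.default_rng(41).normal(size=(50, 3))
        assert first_canonical_correlation(a, a) == pytest.approx(1.0, abs=1e-6)

    def test_independent_matrices_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(500, 2))
            b = rng.normal(size=(500, 2))
            vals.append(first_canonical_correlation(a, b))
        assert np.median(vals) < 0.3

    def test_single_column_equals_abs_pearson(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(100, 1))
        b = -0.6 * a + rng.normal(size=(100, 1))
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert first_canonical_correlation(a, b) == pytest.approx(abs(r), abs=1e-6)

    def test_rank_deficient_regularized(self):
        a = np.ones((20, 3))  # zero variance, rank deficient
        b = np.random.default_rng(43).normal(size=(20, 2))
        val = first_canonical_correlation(a, b)
        assert 0.0 <= val <= 1.0

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            a = rng.normal(size=(15, 4))
            b = rng.normal(size=(15, 6))
            assert 0.0 <= first_canonical_correlation(a, b) <= 1.0


def test_synthetic_gordon_fft_feature_count():
    # the full-scale dimensionality contract: 12,533 genes -> 1253 features
    m = generate_synthetic_mage(
        SyntheticSpec(n_genes=12_533, n_pos=150, n_neg=31, seed=2)
    )
    red = fft_reduce(m)
    assert red.values.shape == (181, 1253)
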