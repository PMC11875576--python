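"""Complex correlation, its permutation test, and KDE mutual information."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from wavefbn import (
    DegenerateInputError,
    InvalidArgumentError,
    MiEstimatorConfig,
    MiMatrix,
    ccc,
    ccc_permutation_pvalue,
    mutual_information,
    normalize_mi_matrix,
)
from conftest import complex_pair


def ccc_loops(x, y):
    """Brute-force oracle: the defining sums written as explicit loops."""
    xb = sum(x) / len(x)
    yb = sum(y) / len(y)
    num = 0.0
    dx = 0.0
    dy = 0.0
    for xi, yi in zip(x, y):
        num += (xi - xb) * np.conj(yi - yb)
        dx += abs(xi - xb) ** 2
        dy += abs(yi - yb) ** 2
    return num / np.sqrt(dx * dy)


class TestCcc:
    def test_self_correlation_is_one(self):
        x, _ = complex_pair(0)
        res = ccc(x, x)
        assert res.rc == pytest.approx(1.0, abs=1e-12)
        assert res.magnitude == pytest.approx(1.0, abs=1e-12)

    def test_complex_scaling_identity(self):
        x, _ = complex_pair(1)
        c = 2.0 - 1.5j
        res = ccc(x, c * x)
        assert res.magnitude == pytest.approx(1.0, abs=1e-12)
        assert res.rc == pytest.approx(np.conj(c) / abs(c), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_explicit_loop_oracle(self, seed):
        x, y = complex_pair(seed, n=40)
        expected = ccc_loops(list(x), list(y))
        res = ccc(x, y)
        assert res.rc == pytest.approx(expected, abs=1e-12)
        assert res.magnitude <= 1 + 1e-12

    def test_fixed_vector_example(self):
        x = np.array([1 + 0j, 2 + 1j, 0 - 1j, 3 + 2j])
        y = np.array([0 + 1j, 1 + 1j, 1 - 2j, 2 + 3j])
        assert ccc(x, y).rc == pytest.approx(ccc_loops(list(x), list(y)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_real_input_reduces_to_pearson(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(50), r.standard_normal(50)
        assert ccc(x, y).rc.real == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)
        assert abs(ccc(x, y).rc.imag) < 1e-15

    def test_errors(self):
        x, y = complex_pair(2)
        with pytest.raises(InvalidArgumentError):
            ccc(x, y[:-1])
        with pytest.raises(DegenerateInputError):
            ccc(np.ones(10, dtype=complex), y[:10])
        with pytest.raises(InvalidArgumentError):
            ccc(x[:2], y[:2])


class TestPermutationPvalue:
    def test_identical_signals_are_significant(self):
        r = np.random.default_rng(3)
        x = r.standard_normal(240) + 1j * r.standard_normal(240)
        assert ccc_permutation_pvalue(x, x, n_iter=1000, seed=0) <= 0.01

    def test_single_iteration_values(self):
        x, y = complex_pair(4, n=30)
        assert ccc_permutation_pvalue(x, y, n_iter=1, seed=5) in (0.5, 1.0)

    def test_deterministic_given_seed(self):
        x, y = complex_pair(5, n=60)
        p1 = ccc_permutation_pvalue(x, y, n_iter=200, seed=9)
        p2 = ccc_permutation_pvalue(x, y, n_iter=200, seed=9)
        assert p1 == p2

    def test_superuniform_under_independence(self):
        # P(p <= alpha) <= alpha + Monte Carlo slack for independent inputs
        n_rep, b = 150, 99
        pvals = []
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            x = r.standard_normal(60) + 1j * r.standard_normal(60)
            y = r.standard_normal(60) + 1j * r.standard_normal(60)
            pvals.append(ccc_permutation_pvalue(x, y, n_iter=b, seed=rep))
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1):
            rate = np.mean(pvals <= alpha)
            assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_rep)

    def test_circular_scheme(self):
        x, y = complex_pair(6, n=80)
        p = ccc_permutation_pvalue(x, y, n_iter=100, seed=1, scheme="circular")
        assert 0 < p <= 1


class TestMutualInformation:
    def test_bivariate_gaussian_closed_form(self):
        rho = 0.8
        z = np.random.default_rng(0).multivariate_normal(
            [0, 0], [[1, rho], [rho, 1]], size=2000
        )
        est = mutual_information(z[:, 0], z[:, 1])
        truth = -0.5 * np.log(1 - rho**2)
        assert est == pytest.approx(truth, rel=0.15)

    def test_independent_uniforms_near_zero(self):
        r = np.random.default_rng(1)
        assert mutual_information(r.uniform(size=2000), r.uniform(size=2000)) <= 0.05

    def test_exact_symmetry(self):
        r = np.random.default_rng(2)
        x, y = r.standard_normal(200), r.standard_normal(200)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_nonnegative(self):
        r = np.random.default_rng(3)
        assert mutual_information(r.standard_normal(100), r.standard_normal(100)) >= 0.0

    def test_increasing_affine_invariance(self):
        r = np.random.default_rng(4)
        x = r.standard_normal(500)
        y = x + 0.5 * r.standard_normal(500)
        base = mutual_information(x, y)
        scaled = mutual_information(3.0 * x + 7.0, 0.1 * y - 2.0)
        assert scaled == pytest.approx(base, rel=0.05)

    def test_diagonal_kernel_option(self):
        rho = 0.8
        z = np.random.default_rng(5).multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000)
        cfg = MiEstimatorConfig(kernel_cov="diagonal")
        est = mutual_information(z[:, 0], z[:, 1], cfg)
        assert 0 < est < -0.5 * np.log(1 - rho**2)  # product kernel under-smooths rho

    def test_errors(self):
        r = np.random.default_rng(6)
        x = r.standard_normal(100)
        with pytest.raises(DegenerateInputError):
            mutual_information(x, np.ones(100))
        with pytest.raises(InvalidArgumentError):
            mutual_information(x[:10], x[:10])
        with pytest.raises(InvalidArgumentError):
            MiEstimatorConfig(bandwidth_rule="fixed")


class TestNormalizeMiMatrix:
    def test_affine_endpoints(self):
        m = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.8], [0.5, 0.8, 0.0]])
        out = normalize_mi_matrix(MiMatrix(m)).values
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(sorted(out[iu]), [0.0, 0.5, 1.0])

    def test_constant_off_diagonal_maps_to_zero(self):
        m = np.full((4, 4), 0.3)
        out = normalize_mi_matrix(MiMatrix(m)).values
        assert np.all(out == 0.0)

    def test_monotone_rank_preserving(self):
        r = np.random.default_rng(7)
        m = r.uniform(size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        out = normalize_mi_matrix(MiMatrix(m)).values
        iu = np.triu_indices(5, 1)
        assert np.array_equal(np.argsort(m[iu]), np.argsort(out[iu]))

    def test_idempotent_when_already_spanning(self):
        m = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 1.0], [0.5, 1.0, 0.0]])
        out = normalize_mi_matrix(MiMatrix(m)).values
        np.testing.assert_allclose(out, m)
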