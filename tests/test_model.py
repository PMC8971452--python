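import numpy as np
import pandas as pd
import pytest

from plscova.model import CrossBlockSVD, cross_block_matrix


def _standardize(A):
    return (A - A.mean(0)) / A.std(0, ddof=1)


class TestCrossBlockMatrix:
    def test_identical_and_orthogonal_columns(self):
        rng = np.random.default_rng(1)
        x = _standardize(rng.normal(size=(32, 1)))
        a = _standardize(np.tile([-1.0, 1.0], 16)[:, None])
        b = _standardize(np.repeat([-1.0, 1.0], 16)[:, None])  # orthogonal to a
        assert cross_block_matrix(x, x)[0, 0] == pytest.approx(1.0)
        assert cross_block_matrix(a, b)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pearson_example(self):
        """r between (1,-1,0) and (0,-1,1) is 0.5 by the direct formula."""
        x = _standardize(np.array([[1.0], [-1.0], [0.0]]))
        y = _standardize(np.array([[0.0], [-1.0], [1.0]]))
        assert cross_block_matrix(x, y)[0, 0] == pytest.approx(0.5)

    def test_subject_mismatch_and_unstandardised_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="mismatch"):
            cross_block_matrix(rng.normal(size=(10, 2)), rng.normal(size=(9, 2)))
        with pytest.raises(ValueError, match="standardised"):
            cross_block_matrix(rng.normal(size=(10, 2)) + 5,
                               _standardize(rng.normal(size=(10, 2))))


class TestSVDDecomposition:
    def test_diagonal_matrix(self):
        X = np.eye(3)[:, :2] * 0  # dummy; construct results directly from R
        # diag(3, 1): singular values (3, 1), saliences = coordinate axes
        rng = np.random.default_rng(3)
        n = 40
        model = CrossBlockSVD(_standardize(rng.normal(size=(n, 2))),
                              _standardize(rng.normal(size=(n, 2))))
        from plscova.model import _svd_saliences
        U, s, V = _svd_saliences(np.diag([3.0, 1.0]), 2)
        np.testing.assert_allclose(s, [3.0, 1.0])
        np.testing.assert_allclose(np.abs(U), np.eye(2), atol=1e-12)

    def test_rank_one_norm_product(self):
        u = np.array([2.0, 0.0, 0.0])  # norm 2
        v = np.array([0.0, 3.0])       # norm 3
        from plscova.model import _svd_saliences
        _, s, _ = _svd_saliences(np.outer(u, v), 2)
        assert s[0] == pytest.approx(6.0)
        assert s[1] == pytest.approx(0.0, abs=1e-12)

    def test_singular_values_match_eigendecomposition_oracle(self):
        """sigma^2 of R equals the eigenvalues of R'R from an independent
        eigensolver."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            R = rng.normal(size=(5, 3))
            from plscova.model import _svd_saliences
            _, s, _ = _svd_saliences(R, 3)
            eig = np.sort(np.linalg.eigvalsh(R.T @ R))[::-1]
            np.testing.assert_allclose(s ** 2, eig, atol=1e-10)

    def test_nan_rejected(self):
        from plscova.model import _svd_saliences
        with pytest.raises(ValueError, match="finite"):
            _svd_saliences(np.array([[1.0, np.nan]]), 1)


class TestResults:
    def test_reconstruction_and_unit_norm(self, standardized_pair):
        X, Y = standardized_pair
        res = CrossBlockSVD(X, Y).fit()
        R = res.cross_corr
        approx = res.x_saliences @ np.diag(res.singular_values) @ res.y_saliences.T
        assert np.linalg.norm(R - approx) < 1e-8 * np.linalg.norm(R)
        np.testing.assert_allclose(np.linalg.norm(res.x_saliences, axis=0), 1, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(res.y_saliences, axis=0), 1, atol=1e-10)

    def test_explained_covariance_properties(self, standardized_pair):
        X, Y = standardized_pair
        res = CrossBlockSVD(X, Y).fit()
        frac = res.explained_covariance
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(res.singular_values) <= 1e-12).all()
        # sigma=(2,1) -> 80/20 split
        s = np.array([2.0, 1.0])
        np.testing.assert_allclose(s ** 2 / (s ** 2).sum(), [0.8, 0.2])

    def test_column_permutation_equivariance(self, standardized_pair):
        """Permuting X columns permutes x-saliences identically and leaves
        singular values unchanged."""
        X, Y = standardized_pair
        rng = np.random.default_rng(5)
        perm = rng.permutation(X.shape[1])
        res = CrossBlockSVD(X, Y).fit()
        res_p = CrossBlockSVD(X[:, perm], Y).fit()
        np.testing.assert_allclose(res_p.singular_values, res.singular_values, atol=1e-10)
        np.testing.assert_allclose(res_p.x_saliences, res.x_saliences[perm], atol=1e-8)

    def test_sign_convention(self, standardized_pair):
        X, Y = standardized_pair
        res = CrossBlockSVD(X, Y).fit()
        for k in range(res.n_components):
            col = res.x_saliences[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_first_scores_maximize_correlation_covariance(self, standardized_pair):
        """No random unit-norm weight pair beats the first component's
        cross-covariance."""
        X, Y = standardized_pair
        res = CrossBlockSVD(X, Y).fit()
        best = res.x_scores[:, 0] @ res.y_scores[:, 0] / (len(X) - 1)
        rng = np.random.default_rng(6)
        for _ in range(500):
            a = rng.normal(size=X.shape[1])
            b = rng.normal(size=Y.shape[1])
            a /= np.linalg.norm(a)
            b /= np.linalg.norm(b)
            cand = (X @ a) @ (Y @ b) / (len(X) - 1)
            assert cand <= best + 1e-10

    def test_top_feature_contributions(self):
        rng = np.random.default_rng(7)
        X = _standardize(rng.normal(size=(50, 3)))
        Y = _standardize(rng.normal(size=(50, 2)))
        res = CrossBlockSVD(X, Y, x_names=["a", "b", "c"]).fit()
        ranked = res.top_feature_contributions(component=1, side="x")
        assert list(np.abs(ranked["salience"])) == sorted(
            np.abs(res.x_saliences[:, 0]), reverse=True)
        with pytest.raises(ValueError, match="out of range"):
            res.top_feature_contributions(component=5)

    def test_from_dataframes_aligns_subjects(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(_standardize(rng.normal(size=(20, 3))),
                         index=[f"S{i}" for i in range(20)])
        Y = pd.DataFrame(_standardize(rng.normal(size=(20, 2))),
                         index=[f"S{i}" for i in range(19, -1, -1)])
        model = CrossBlockSVD.from_dataframes(X, Y)
        assert model.nobs == 20
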