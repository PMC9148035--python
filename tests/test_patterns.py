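"""PCA/varimax pattern extraction against independent formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutripatterns import (
    NutrientPatternModel,
    bartlett_sphericity,
    build_density_matrix,
    correlation_matrix,
    explained_variance_pct,
    fit_patterns,
    kmo_index,
    label_patterns,
    varimax,
)
from nutripatterns.patterns import varimax_criterion


# ---------------------------------------------------------------- oracles
def kmo_oracle(R: np.ndarray) -> float:
    """Direct-formula KMO: partial correlations via explicit 2x2 inversion
    of the precision submatrices (independent of the implementation path)."""
    p = R.shape[0]
    P = np.linalg.inv(R)
    r2 = 0.0
    q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            r2 += R[i, j] ** 2
            q2 += (-P[i, j] / np.sqrt(P[i, i] * P[j, j])) ** 2
    return r2 / (r2 + q2)


def kmo_oracle_regression(X: np.ndarray) -> float:
    """Data-level KMO oracle: anti-image partials from residual correlations
    of least-squares regressions on the remaining variables."""
    n, p = X.shape
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    r2 = 0.0
    q2 = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            A = np.column_stack([Z[:, others], np.ones(n)])
            ri = Z[:, i] - A @ np.linalg.lstsq(A, Z[:, i], rcond=None)[0]
            rj = Z[:, j] - A @ np.linalg.lstsq(A, Z[:, j], rcond=None)[0]
            q = np.corrcoef(ri, rj)[0, 1]
            r2 += 2 * R[i, j] ** 2
            q2 += 2 * q ** 2
    return r2 / (r2 + q2)


def bartlett_oracle(R: np.ndarray, n: int):
    p = R.shape[0]
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(np.linalg.det(R))
    df = p * (p - 1) // 2
    return chi2, df, stats.chi2.sf(chi2, df)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a @ b) / np.sqrt((a ** 2).sum() * (b ** 2).sum()))


# ------------------------------------------------------- correlation matrix
class TestCorrelationMatrix:
    def test_duplicate_columns_correlate_fully(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        R = correlation_matrix(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)}))
        assert R.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_nearly_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10_000, 5))
        R = correlation_matrix(X).to_numpy()
        off = R[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(10_000)

    def test_exactly_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        R = correlation_matrix(rng.normal(size=(50, 4))).to_numpy()
        assert np.array_equal(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1 + 1e-12)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"ok": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(X)


# ------------------------------------------------------------ KMO, Bartlett
class TestSamplingAdequacy:
    def test_kmo_uniform_offdiagonal_matches_oracle(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        assert kmo_index(R) == pytest.approx(kmo_oracle(R), abs=1e-10)

    @pytest.mark.parametrize("p,seed", [(3, 0), (4, 1), (5, 2), (6, 3)])
    def test_kmo_random_matrices_match_oracle(self, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, p)) @ rng.normal(size=(p, p))
        R = np.corrcoef(X, rowvar=False)
        assert kmo_index(R) == pytest.approx(kmo_oracle(R), abs=1e-10)

    def test_kmo_regression_oracle_on_data(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(300, 1))
        X = f @ rng.uniform(0.5, 1.0, size=(1, 4)) + 0.6 * rng.normal(size=(300, 4))
        R = np.corrcoef(X, rowvar=False)
        assert kmo_index(R) == pytest.approx(kmo_oracle_regression(X), abs=1e-8)

    def test_kmo_near_collinear_system_is_high(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=(5000, 1))
        X = 0.9 * f + np.sqrt(1 - 0.81) * rng.normal(size=(5000, 6))
        R = np.corrcoef(X, rowvar=False)
        assert kmo_index(R) > 0.8

    def test_kmo_identity_undefined(self):
        with pytest.raises(ValueError):
            kmo_index(np.eye(4))

    def test_bartlett_identity_is_null(self):
        chi2, df, p = bartlett_sphericity(np.eye(6), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bartlett_df_for_18_variables(self):
        R = 0.3 * np.ones((18, 18))
        np.fill_diagonal(R, 1.0)
        _, df, _ = bartlett_sphericity(R, n=608)
        assert df == 153

    def test_bartlett_closed_form_2x2(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        chi2, df, p = bartlett_sphericity(R, n=100)
        echi2, edf, ep = bartlett_oracle(R, 100)
        assert chi2 == pytest.approx(echi2, rel=1e-12)
        assert (df, p) == (edf, pytest.approx(ep, rel=1e-10))

    def test_bartlett_requires_n_gt_p(self):
        with pytest.raises(ValueError):
            bartlett_sphericity(np.eye(5), n=5)


# ------------------------------------------------------------------ varimax
class TestVarimax:
    @pytest.fixture
    def loadings(self):
        rng = np.random.default_rng(6)
        lam = rng.uniform(0.3, 0.9, size=(10, 2)) * rng.choice([1.0, -1.0], size=(10, 2))
        return lam

    def test_rotation_is_orthogonal(self, loadings):
        rotated, R = varimax(loadings)
        np.testing.assert_allclose(R @ R.T, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(rotated, loadings @ R, atol=1e-10)

    def test_communalities_invariant(self, loadings):
        rotated, _ = varimax(loadings)
        np.testing.assert_allclose(
            (rotated ** 2).sum(axis=1), (loadings ** 2).sum(axis=1), atol=1e-8)

    def test_criterion_not_decreased(self, loadings):
        rotated, _ = varimax(loadings)
        assert varimax_criterion(rotated) >= varimax_criterion(loadings) - 1e-10


# --------------------------------------------------------------- full model
class TestFitPatterns:
    def test_variance_explained_reporting(self):
        out = explained_variance_pct([5.119, 4.909], p=18)
        assert np.round(out, 1).tolist() == [28.4, 27.3]

    def test_full_rank_variance_sums_to_100(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 6)) @ rng.normal(size=(6, 6))
        res = fit_patterns(X, n_factors=6)
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-8)
        assert res.variance_explained_unrotated.sum() == pytest.approx(100.0, abs=1e-8)

    def test_scores_centered_and_communalities_preserved(self, planted_cohort):
        X = build_density_matrix(planted_cohort)
        res = fit_patterns(X, n_factors=2)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)
        h_rot = (res.loadings_rotated ** 2).sum(axis=1)
        h_unrot = (res.loadings_unrotated ** 2).sum(axis=1)
        np.testing.assert_allclose(h_rot, h_unrot, atol=1e-8)

    def test_single_factor_scores_order_matches_projection(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(200, 1))
        X = f @ np.array([[0.9, 0.8, 0.7]]) + 0.4 * rng.normal(size=(200, 3))
        res = fit_patterns(X, n_factors=1)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        R = np.corrcoef(X, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        pc1 = Z @ eigvec[:, -1]
        s = res.scores.to_numpy().ravel()
        rho = np.corrcoef(np.argsort(np.argsort(pc1)), np.argsort(np.argsort(s)))[0, 1]
        assert abs(rho) == pytest.approx(1.0)

    def test_planted_block_structure_recovered(self, planted_cohort, block_loadings):
        X = build_density_matrix(planted_cohort)
        res = fit_patterns(X, n_factors=2)
        L = res.loadings_rotated.to_numpy()
        # match recovered columns to planted columns by congruence
        congs = np.array([
            [tucker_congruence(L[:, i], block_loadings[:, j]) for j in range(2)]
            for i in range(2)
        ])
        best = congs.max(axis=1)
        assert (best >= 0.95).all()
        # salient-variable blocks reproduced at the 0.5 threshold
        labels = res.labels
        block_of = {0: set(X.columns[:9]), 1: set(X.columns[9:])}
        recovered = [set(v for v, _ in labels[j]) for j in range(2)]
        assert {frozenset(b) for b in block_of.values()} == {frozenset(r) for r in recovered}

    def test_sign_convention_largest_loading_positive(self, planted_cohort):
        X = build_density_matrix(planted_cohort)
        res = fit_patterns(X, n_factors=2)
        L = res.loadings_rotated.to_numpy()
        for j in range(2):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_invalid_n_factors(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        with pytest.raises(ValueError):
            NutrientPatternModel(X, n_factors=0)
        with pytest.raises(ValueError):
            NutrientPatternModel(X, n_factors=5)


class TestLabelPatterns:
    L = pd.DataFrame(
        {"f1": [0.858, 0.2, -0.707], "f2": [0.1, 0.62, 0.3]},
        index=["folate", "zinc", "carb_fiber_ratio"],
    )

    def test_high_loading_listed(self):
        labels = label_patterns(self.L)
        assert labels[0][0] == ("folate", pytest.approx(0.858))

    def test_negative_loading_sign_retained(self):
        labels = label_patterns(self.L)
        assert ("carb_fiber_ratio", pytest.approx(-0.707)) in labels[0]

    def test_empty_factor(self):
        labels = label_patterns(self.L, threshold=0.9)
        assert labels[0] == [] and labels[1] == []

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            label_patterns(self.L, threshold=0.0)


def test_loading_table_shape(default_cohort):
    X = build_density_matrix(default_cohort)
    res = fit_patterns(X, n_factors=2)
    tbl = res.loading_table()
    assert tbl.shape == (20, 2)  # 18 variables + variance + eigenvalue rows
    assert "Variance explained (%)" in tbl.index
    assert res.summary()  # renders without error
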