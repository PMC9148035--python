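"""Nutrient-pattern extraction: correlation-matrix PCA with varimax rotation.

The model is principal component analysis of the p x p Pearson correlation
matrix of energy-adjusted nutrient variables. The top-m component loadings
(eigenvector times sqrt(eigenvalue)) are rotated by Kaiser-normalized
varimax; per-participant factor scores use the regression (Thurstone)
method on the standardized variables. Sampling adequacy is reported through
the Kaiser-Meyer-Olkin index and Bartlett's test of sphericity.

Exposed in a statsmodels-like shape::

    model = NutrientPatternModel(density_df, n_factors=2)
    res = model.fit()
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def correlation_matrix(X) -> pd.DataFrame:
    """Pearson correlation matrix of the density variables.

    Symmetric with unit diagonal. Raises a named error for constant columns.
    """
    df = pd.DataFrame(X)
    arr = df.to_numpy(float)
    n, p = arr.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} rows, got {n}")
    sd = arr.std(axis=0)
    constant = np.asarray(df.columns)[sd == 0]
    if len(constant):
        raise ValueError(f"constant column(s): {list(constant)}")
    R = np.corrcoef(arr, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=df.columns, columns=df.columns)


def kmo_index(correlation) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image partial correlations obtained from the inverse
    correlation matrix. Undefined (raises) for an identity correlation.
    """
    R = np.asarray(pd.DataFrame(correlation), dtype=float)
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is singular") from exc
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d
    off = ~np.eye(p, dtype=bool)
    ssr = float((R[off] ** 2).sum())
    ssq = float((Q[off] ** 2).sum())
    if ssr + ssq == 0:
        raise ValueError("KMO undefined for an identity correlation matrix")
    return ssr / (ssr + ssq)


def bartlett_sphericity(correlation, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) ln det(R), df = p(p-1)/2; the p-value is
    the upper tail of the chi-squared distribution.
    """
    R = np.asarray(pd.DataFrame(correlation), dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("Bartlett's test requires n > p")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm, Kaiser row-normalized).

    Returns (rotated loadings, rotation matrix) with
    rotated = loadings @ rotation.
    """
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return L.copy(), np.eye(m)
    h = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        h_safe = np.where(h > 0, h, 1.0)
        A = L / h_safe[:, None]
    else:
        A = L.copy()
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        # gradient of the varimax criterion
        G = A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        d_new = s.sum()
        if d_new < d_old * (1 + tol):
            break
        d_old = d_new
    rotated = A @ R
    if kaiser_normalize:
        rotated = rotated * h_safe[:, None]
    return rotated, R


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings (raw varimax)."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float((L2.var(axis=0)).sum())


def explained_variance_pct(eigenvalues, p: int) -> np.ndarray:
    """Percent of total variance per component: 100 * eigenvalue / p.

    This is the reporting path for correlation-matrix PCA, where the total
    variance equals the number of variables p.
    """
    return 100.0 * np.asarray(eigenvalues, dtype=float) / p


def label_patterns(loadings_rotated, threshold: float = 0.5) -> dict:
    """Map each factor to its salient variables (|loading| >= threshold).

    Sign retained; entries sorted by |loading| descending. Factors with no
    salient variable map to an empty list.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    L = pd.DataFrame(loadings_rotated)
    labels: dict = {}
    for j, col in enumerate(L.columns):
        vals = L[col]
        sal = vals[vals.abs() >= threshold]
        ordered = sal.reindex(sal.abs().sort_values(ascending=False).index)
        labels[j] = [(str(v), float(x)) for v, x in ordered.items()]
    return labels


@dataclass
class NutrientPatternResults:
    """Fitted nutrient-pattern decomposition."""

    correlation: pd.DataFrame
    eigenvalues: np.ndarray              # all p eigenvalues, descending
    loadings_unrotated: pd.DataFrame     # p x m
    loadings_rotated: pd.DataFrame       # p x m
    rotation: np.ndarray                 # m x m orthogonal
    variance_explained: np.ndarray       # % per rotated factor (SS loadings / p)
    variance_explained_unrotated: np.ndarray  # % per component (eigenvalue / p)
    kmo: float
    bartlett: tuple[float, int, float]
    scores: pd.DataFrame                 # n x m regression factor scores
    labels: dict = field(default_factory=dict)
    n_obs: int = 0
    threshold: float = 0.5

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings_rotated ** 2).sum(axis=1)

    def loading_table(self, blank_below_threshold: bool = True) -> pd.DataFrame:
        """Variables x factors table, blanking |loading| < threshold.

        Appends 'Variance explained (%)' and 'Eigenvalues' rows, mirroring
        the conventional rotated-loading report.
        """
        L = self.loadings_rotated.copy()
        out = L.round(3).astype(object)
        if blank_below_threshold:
            out = out.where(L.abs() >= self.threshold, "")
        m = L.shape[1]
        out.loc["Variance explained (%)"] = np.round(
            self.variance_explained_unrotated[:m], 1)
        out.loc["Eigenvalues"] = np.round(self.eigenvalues[:m], 3)
        return out

    def eigenvalue_report(self) -> pd.DataFrame:
        """Advisory retention report: eigenvalues and the >1 rule."""
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues,
            "pct_variance": explained_variance_pct(self.eigenvalues, len(self.eigenvalues)),
            "greater_than_1": self.eigenvalues > 1.0,
        }, index=[f"PC{i + 1}" for i in range(len(self.eigenvalues))])

    def summary(self) -> str:
        m = self.loadings_rotated.shape[1]
        chi2, df, pval = self.bartlett
        lines = [
            "Nutrient pattern model (correlation-matrix PCA, varimax rotation)",
            f"  observations: {self.n_obs}   variables: {self.correlation.shape[0]}   factors: {m}",
            f"  KMO sampling adequacy: {self.kmo:.3f}",
            f"  Bartlett sphericity: chi2({df}) = {chi2:.1f}, p = {pval:.3g}",
            "  variance explained (%, by eigenvalue): "
            + ", ".join(f"{v:.1f}" for v in self.variance_explained_unrotated[:m]),
            "  variance explained (%, rotated SS loadings): "
            + ", ".join(f"{v:.1f}" for v in self.variance_explained),
            "",
            self.loading_table().to_string(),
        ]
        return "\n".join(lines)


class NutrientPatternModel:
    """PCA/varimax nutrient-pattern model over a density matrix.

    Parameters
    ----------
    data : DataFrame
        n x p energy-adjusted nutrient variables (rows: participants).
    n_factors : int
        Number of patterns to retain (fixed by design; an eigenvalue
        report is available on the results for advisory retention checks).
    threshold : float
        Absolute-loading cutoff for pattern labeling.
    """

    def __init__(self, data, n_factors: int = 2, threshold: float = 0.5):
        self.data = pd.DataFrame(data)
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if n_factors > self.data.shape[1]:
            raise ValueError("n_factors cannot exceed the number of variables")
        self.n_factors = int(n_factors)
        self.threshold = float(threshold)

    @classmethod
    def from_cohort(cls, cohort, n_factors: int = 2, threshold: float = 0.5):
        from .preprocessing import build_density_matrix
        return cls(build_density_matrix(cohort), n_factors=n_factors, threshold=threshold)

    def fit(self) -> NutrientPatternResults:
        X = self.data.to_numpy(float)
        n, p = X.shape
        m = self.n_factors
        R = correlation_matrix(self.data)
        Rv = R.to_numpy()

        eigval, eigvec = np.linalg.eigh(Rv)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        eigval = np.maximum(eigval, 0.0)

        L = eigvec[:, :m] * np.sqrt(eigval[:m])
        L_rot, rot = varimax(L)

        # sign convention: each factor's largest-|loading| variable positive
        flip = np.ones(m)
        for j in range(m):
            i_max = np.argmax(np.abs(L_rot[:, j]))
            if L_rot[i_max, j] < 0:
                flip[j] = -1.0
        L_rot = L_rot * flip
        rot = rot * flip

        # regression (Thurstone) scores on standardized variables
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        W = np.linalg.solve(Rv, L_rot)
        S = Z @ W

        var_rot = 100.0 * (L_rot ** 2).sum(axis=0) / p
        var_unrot = explained_variance_pct(eigval, p)

        cols = [f"factor_{j + 1}" for j in range(m)]
        res = NutrientPatternResults(
            correlation=R,
            eigenvalues=eigval,
            loadings_unrotated=pd.DataFrame(L, index=R.index, columns=cols),
            loadings_rotated=pd.DataFrame(L_rot, index=R.index, columns=cols),
            rotation=rot,
            variance_explained=var_rot,
            variance_explained_unrotated=var_unrot,
            kmo=kmo_index(R),
            bartlett=bartlett_sphericity(R, n),
            scores=pd.DataFrame(S, index=self.data.index, columns=cols),
            labels={},
            n_obs=n,
            threshold=self.threshold,
        )
        res.labels = label_patterns(res.loadings_rotated, self.threshold)
        return res


def fit_patterns(X, n_factors: int, threshold: float = 0.5) -> NutrientPatternResults:
    """Functional wrapper: fit the pattern model on a density matrix."""
    return NutrientPatternModel(X, n_factors=n_factors, threshold=threshold).fit()
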