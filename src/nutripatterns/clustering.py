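"""Ward hierarchical clustering of participants on factor scores.

Clusters minimize the increase in within-cluster sum of squares at each
merge (Ward's criterion on squared Euclidean dissimilarities). Cluster
labels for a chosen k are numbered by decreasing cluster size. Each
factor's contribution to the partition is summarized by eta-squared
(= R^2 = SS_between / SS_total from a one-way ANOVA on cluster membership).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform, pdist


def ward_linkage(scores) -> np.ndarray:
    """Agglomerative Ward merge sequence on an n x m score matrix.

    Returns the (n-1) x 4 merge table; merge heights are in the standard
    Ward distance convention (sqrt(2 x increase in within-cluster SS)) and
    are non-decreasing.
    """
    X = np.asarray(pd.DataFrame(scores), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("Ward clustering needs at least two observations")
    if np.isnan(X).any():
        raise ValueError("scores contain missing values")
    return linkage(X, method="ward")


def cut_clusters(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut the tree into k groups; label ids ordered by decreasing size.

    Ties in size are broken by the smallest member (row) index. Labels are
    1-based.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = fcluster(Z, t=k, criterion="maxclust")
    ids, counts = np.unique(raw, return_counts=True)
    first_member = np.array([np.argmax(raw == i) for i in ids])
    order = np.lexsort((first_member, -counts))
    remap = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([remap[int(v)] for v in raw])


def eta_squared(labels, values) -> tuple[float, float]:
    """Effect size eta^2 = SS_between / SS_total with its ANOVA p-value."""
    labels = np.asarray(labels)
    y = np.asarray(values, dtype=float)
    groups = [y[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    if sst == 0:
        raise ValueError("eta-squared undefined: total sum of squares is zero")
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    eta2 = ssb / sst
    k, n = len(groups), len(y)
    ssw = sst - ssb
    if ssw <= 0:
        return eta2, 0.0
    F = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(F, k - 1, n - k))
    return eta2, p


def cluster_share_table(labels) -> pd.DataFrame:
    """Cluster sizes with their percentage of the cohort (1-decimal report)."""
    labels = np.asarray(labels)
    sizes = pd.Series(labels).value_counts().sort_index()
    sizes.index.name = "cluster"
    return pd.DataFrame({
        "n": sizes,
        "pct": np.round(100.0 * sizes / len(labels), 1),
    })


def _mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over all points (Euclidean)."""
    D = squareform(pdist(X))
    n = len(labels)
    uniq = np.unique(labels)
    sil = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own)
        n_own = mask_own.sum()
        if n_own == 1:
            sil[i] = 0.0
            continue
        a = D[i, mask_own].sum() / (n_own - 1)
        b = min(D[i, labels == g].mean() for g in uniq if g != own)
        sil[i] = (b - a) / max(a, b)
    return float(sil.mean())


@dataclass
class ClusterResults:
    """Partition of participants in factor-score space."""

    linkage: np.ndarray
    k: int
    labels: np.ndarray                 # 1..k, ordered by decreasing size
    eta: pd.DataFrame                  # per factor: eta_squared, p_value
    cluster_sizes: pd.Series
    scores: pd.DataFrame
    advisory: pd.DataFrame | None = None  # merge-height / silhouette per k

    def size_table(self) -> pd.DataFrame:
        return cluster_share_table(self.labels)

    def label_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.scores.index,
            "cluster": self.labels,
        })

    def to_newick(self) -> str:
        """Linkage tree in Newick text form for external dendrogram viewers."""
        n = self.linkage.shape[0] + 1
        names = [str(i) for i in self.scores.index]
        nodes = {i: (names[i], 0.0) for i in range(n)}
        for r, (a, b, h, _) in enumerate(self.linkage):
            na, ha = nodes.pop(int(a))
            nb, hb = nodes.pop(int(b))
            nodes[n + r] = (f"({na}:{h - ha:.6g},{nb}:{h - hb:.6g})", h)
        (tree, _), = nodes.values()
        return tree + ";"

    def summary(self) -> str:
        lines = [
            f"Ward hierarchical clustering on {self.scores.shape[1]} factor scores",
            f"  n = {len(self.labels)}, k = {self.k}",
            "  cluster sizes: " + ", ".join(
                f"C{c}: {s}" for c, s in self.cluster_sizes.items()),
            "  factor contributions (eta^2 = SS_between/SS_total):",
        ]
        for name, row in self.eta.iterrows():
            lines.append(
                f"    {name}: eta2 = {row['eta_squared']:.3f} (p = {row['p_value']:.3g})")
        if self.advisory is not None:
            lines.append("  advisory k report:\n" + self.advisory.to_string())
        return "\n".join(lines)


class FactorScoreClustering:
    """Ward clustering model over participant factor scores.

    Parameters
    ----------
    scores : DataFrame
        n x m factor scores (rows indexed by participant).
    """

    def __init__(self, scores):
        self.scores = pd.DataFrame(scores)

    def fit(self, k: int = 6, advisory_range: tuple[int, int] = (3, 6)) -> ClusterResults:
        Z = ward_linkage(self.scores)
        labels = cut_clusters(Z, k)
        X = self.scores.to_numpy(float)

        eta_rows = {}
        for col in self.scores.columns:
            e2, p = eta_squared(labels, self.scores[col].to_numpy(float))
            eta_rows[col] = {"eta_squared": e2, "p_value": p}
        eta = pd.DataFrame(eta_rows).T

        sizes = pd.Series(labels).value_counts().sort_index()
        sizes.index.name = "cluster"

        lo, hi = advisory_range
        hi = min(hi, len(labels))
        rows = []
        heights = Z[:, 2]
        for kk in range(lo, hi + 1):
            lab_k = cut_clusters(Z, kk)
            rows.append({
                "k": kk,
                "merge_height": float(heights[-(kk - 1)]) if kk > 1 else np.nan,
                "mean_silhouette": _mean_silhouette(X, lab_k),
            })
        advisory = pd.DataFrame(rows).set_index("k") if rows else None

        return ClusterResults(
            linkage=Z, k=k, labels=labels, eta=eta,
            cluster_sizes=sizes, scores=self.scores, advisory=advisory,
        )
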