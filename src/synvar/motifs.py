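"""Structure in input profiles: correlations, clustering, PCA, binary motifs.

Input-input Pearson correlations with Bonferroni correction, k-means
subtyping of count profiles, PCA of standardized relative counts, and
presence/absence motif discovery via Hamming-distance agglomerative
clustering with a silhouette-chosen cluster number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .filtering import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "input_correlation_matrix",
    "kmeans_inputs",
    "PcaResult",
    "pca_project",
    "binarize_presence",
    "MotifResult",
    "hamming_cluster",
    "summarize_motifs",
]


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: int

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if self.p_adjusted.loc[a, b] < alpha:
                    rows.append(
                        {
                            "type_a": a,
                            "type_b": b,
                            "r": self.r.loc[a, b],
                            "p_adjusted": self.p_adjusted.loc[a, b],
                        }
                    )
        return pd.DataFrame(rows, columns=["type_a", "type_b", "r", "p_adjusted"])


def input_correlation_matrix(matrix: ConnectivityMatrix) -> CorrelationResult:
    """Pairwise Pearson correlations between input-type counts across rows.

    Two-sided p values come from the t statistic t = r sqrt(n-2)/sqrt(1-r^2);
    Bonferroni adjustment multiplies by the number of unique off-diagonal
    pairs.  Pairs involving a constant column are reported missing.
    """
    data = matrix.drop_unknown().data.astype(float)
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 rows for correlations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns produce NaN r
        r = data.corr(method="pearson")
    rv = r.to_numpy(dtype=float).copy()
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt(n - 2) / np.sqrt(1.0 - rv**2)
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    np.fill_diagonal(p, 0.0)
    m = len(data.columns) * (len(data.columns) - 1) // 2
    p_adj = np.minimum(1.0, p * m)
    p_adj[np.isnan(rv)] = np.nan
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    p_adj = pd.DataFrame(p_adj, index=r.index, columns=r.columns)
    return CorrelationResult(r, p, p_adj, n)


def kmeans_inputs(
    matrix: ConnectivityMatrix, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """Euclidean k-means over row profiles; labels and cluster mean profiles.

    Deterministic given the seed; the best of ``n_restarts`` seeded
    initializations (by inertia) is kept.
    """
    data = matrix.drop_unknown().data.astype(float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(data):
        raise ValueError(f"k={k} exceeds number of rows ({len(data)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(data.to_numpy())
    labels = pd.Series(labels, index=data.index, name="cluster")
    means = data.groupby(labels).mean()
    return labels, means


@dataclass
class PcaResult:
    scores: pd.DataFrame          # rows x [PC1, PC2, ...]
    loadings: pd.DataFrame        # types x components
    explained_variance_ratio: np.ndarray
    dropped_types: list[str]


def pca_project(matrix: ConnectivityMatrix, n_components: int = 2) -> PcaResult:
    """PCA of standardized input profiles.

    Columns are standardized to mean 0 / variance 1, the covariance matrix
    eigen-decomposed, and rows projected on the leading eigenvectors.  The
    sign convention makes each component's largest-magnitude loading
    positive.  Zero-variance columns are dropped with a warning.
    """
    data = matrix.drop_unknown().data.astype(float)
    if len(data) < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 types")
    std = data.std(axis=0, ddof=0)
    dropped = list(data.columns[std == 0])
    if dropped:
        logger.warning("dropping zero-variance columns: %s", dropped)
        data = data.drop(columns=dropped)
        std = std.drop(dropped)
    z = (data - data.mean(axis=0)) / std
    cov = np.cov(z.to_numpy(), rowvar=False, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    k = min(n_components, len(evals))
    comps = evecs[:, :k]
    for j in range(k):
        if comps[np.argmax(np.abs(comps[:, j])), j] < 0:
            comps[:, j] = -comps[:, j]
    scores = z.to_numpy() @ comps
    names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.index, columns=names),
        loadings=pd.DataFrame(comps, index=data.columns, columns=names),
        explained_variance_ratio=evals[:k] / evals.sum() if evals.sum() else evals[:k],
        dropped_types=dropped,
    )


def binarize_presence(
    matrix: ConnectivityMatrix,
    exclude_types: tuple[str, ...] = ("L3", "Mi4", "CT1"),
) -> pd.DataFrame:
    """Presence/absence of the variable inputs (core types excluded).

    Returns the indicator of count > 0 with the excluded columns (and
    UNKNOWN) removed; excluded types absent from the matrix only warn.
    """
    data = matrix.drop_unknown().data
    missing = [t for t in exclude_types if t not in data.columns]
    if missing:
        logger.warning("exclude types not in matrix: %s", missing)
    keep = [c for c in data.columns if c not in exclude_types]
    if not keep:
        logger.warning("all types excluded; returning empty binary matrix")
    return (data[keep] > 0).astype(int)


@dataclass
class MotifResult:
    distances: pd.DataFrame       # Hamming distances in bits
    linkage: np.ndarray
    labels_by_k: dict[int, pd.Series]
    silhouette_by_k: pd.Series
    chosen_k: int

    @property
    def labels(self) -> pd.Series:
        return self.labels_by_k[self.chosen_k]


def hamming_cluster(
    binary: pd.DataFrame,
    k_range: range = range(4, 16),
    linkage: str = "average",
    normalized: bool = False,
) -> MotifResult:
    """Agglomerative clustering of binary profiles under Hamming distance.

    The distance between two profiles is the number of differing bits
    (or the differing fraction when ``normalized``).  The tree is cut at
    each candidate k; the mean silhouette coefficient, computed on the
    same Hamming distances, selects the cluster number (ties broken
    toward the smallest k).
    """
    x = binary.to_numpy(dtype=float)
    n = len(binary)
    if n <= max(k_range):
        raise ValueError("need more rows than the largest candidate k")
    d = pdist(x, metric="hamming")
    if not normalized:
        d = d * binary.shape[1]
    if d.max() == 0:
        raise ValueError(
            "all profiles are identical; silhouette is undefined — "
            "supply heterogeneous presence profiles or widen the type set"
        )
    Z = scipy_linkage(d, method=linkage)
    square = squareform(d)
    labels_by_k: dict[int, pd.Series] = {}
    sil = {}
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = pd.Series(lab, index=binary.index, name="motif")
        if len(np.unique(lab)) < 2:
            sil[k] = np.nan
            continue
        sil[k] = silhouette_score(square, lab, metric="precomputed")
    sil = pd.Series(sil).sort_index()
    chosen = int(sil.idxmax())  # idxmax returns the first (smallest) argmax
    return MotifResult(
        distances=pd.DataFrame(square, index=binary.index, columns=binary.index),
        linkage=Z,
        labels_by_k=labels_by_k,
        silhouette_by_k=sil,
        chosen_k=chosen,
    )


def summarize_motifs(
    binary: pd.DataFrame,
    labels: pd.Series,
    dominance_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-cluster presence fractions and dominating types.

    A type dominates a cluster when its presence fraction is above
    ``dominance_threshold`` (consistently present) or below
    1 - threshold (consistently absent).
    """
    if not labels.index.equals(binary.index):
        labels = labels.reindex(binary.index)
    rows = []
    for cluster, idx in binary.groupby(labels).groups.items():
        sub = binary.loc[idx]
        frac = sub.mean(axis=0)
        dominating = [
            t
            for t in binary.columns
            if frac[t] >= dominance_threshold or frac[t] <= 1 - dominance_threshold
        ]
        row = {"cluster": cluster, "n": len(sub), "dominating": dominating}
        row.update({f"frac_{t}": frac[t] for t in binary.columns})
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
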