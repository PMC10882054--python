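"""Wiring-heterogeneity statistics over connectivity matrices.

Cosine similarity of input profiles within and between hemisphere groups,
per-input-type variability (std and coefficient of variation), rank-order
structure, and nonparametric group comparisons (Kruskal-Wallis with
Dunn-Bonferroni post hoc tests).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .filtering import UNKNOWN, ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityDistribution",
    "pairwise_cosine_similarity",
    "cross_group_cosine_similarity",
    "input_variation",
    "rank_order",
    "rank_range",
    "GroupComparison",
    "compare_groups",
]


@dataclass
class SimilarityDistribution:
    """Pairwise cosine similarities within (or across) a group of profiles."""

    group: str
    values: np.ndarray
    pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else np.nan


def _profiles(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Numeric profiles with UNKNOWN excluded and zero-norm rows dropped."""
    data = matrix.drop_unknown().data.astype(float)
    norms = np.linalg.norm(data.to_numpy(), axis=1)
    if (norms == 0).any():
        logger.warning(
            "%d zero-norm rows excluded from cosine similarity",
            int((norms == 0).sum()),
        )
        data = data[norms > 0]
    return data


def pairwise_cosine_similarity(
    matrix: ConnectivityMatrix, group: str = "all"
) -> SimilarityDistribution:
    """All unordered within-group pairs, cos(u, v) = u.v / (|u||v|)."""
    data = _profiles(matrix)
    ids = list(data.index)
    if len(ids) < 2:
        return SimilarityDistribution(group, np.empty(0), [])
    sims = 1.0 - pdist(data.to_numpy(), metric="cosine")
    pairs = list(itertools.combinations(ids, 2))
    return SimilarityDistribution(group, sims, pairs)


def cross_group_cosine_similarity(
    matrix_a: ConnectivityMatrix,
    matrix_b: ConnectivityMatrix,
    group: str = "RL",
) -> SimilarityDistribution:
    """All cross pairs between two groups (the mixed-hemisphere set)."""
    a = _profiles(matrix_a)
    b = _profiles(matrix_b)
    common = a.columns.intersection(b.columns)
    a, b = a[common], b[common]
    an = a.to_numpy() / np.linalg.norm(a.to_numpy(), axis=1, keepdims=True)
    bn = b.to_numpy() / np.linalg.norm(b.to_numpy(), axis=1, keepdims=True)
    sims = (an @ bn.T).ravel()
    pairs = [(i, j) for i in a.index for j in b.index]
    return SimilarityDistribution(group, sims, pairs)


def input_variation(
    matrix: ConnectivityMatrix, ddof: int = 0
) -> pd.DataFrame:
    """Per input type: mean count, std and coefficient of variation.

    Population std (ddof=0) by default.  The c.v. is reported missing when
    the mean is zero.
    """
    data = matrix.drop_unknown().data.astype(float)
    mean = data.mean(axis=0)
    std = data.std(axis=0, ddof=ddof)
    cv = std / mean.where(mean != 0)
    out = pd.DataFrame({"mean": mean, "std": std, "cv": cv})
    out.attrs["ddof"] = ddof
    return out


def rank_order(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Per-row rank of each input type by count (1 = largest).

    Ties share the minimum rank; absent inputs (count 0) are unranked
    (NaN).
    """
    data = matrix.drop_unknown().data.astype(float)
    ranks = data.rank(axis=1, method="min", ascending=False)
    return ranks.where(data > 0)


def rank_range(ranks: pd.DataFrame) -> pd.DataFrame:
    """Min/max/modal rank per input type across rows."""
    out = pd.DataFrame(
        {
            "min_rank": ranks.min(axis=0),
            "max_rank": ranks.max(axis=0),
            "modal_rank": ranks.mode(axis=0).iloc[0],
            "n_ranked": ranks.notna().sum(axis=0),
        }
    )
    return out


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn-Bonferroni pairwise results."""

    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted


def compare_groups(distributions: list[SimilarityDistribution]) -> GroupComparison:
    """Omnibus Kruskal-Wallis test followed by Dunn post hoc comparisons.

    Dunn's z statistics use the tie-corrected pooled rank variance; raw
    two-sided p values are Bonferroni-adjusted over the number of pairs.
    """
    if len(distributions) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(d.values, dtype=float) for d in distributions]
    names = [d.group for d in distributions]
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")

    h, p = stats.kruskal(*samples)

    # Dunn's test on the joint ranking
    all_vals = np.concatenate(samples)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    sizes = [len(s) for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(samples))
    ]
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    m = len(samples) * (len(samples) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * m),
            }
        )
    return GroupComparison(float(h), float(p), pd.DataFrame(rows))
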