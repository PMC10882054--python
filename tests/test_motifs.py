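"""Correlation structure, subtype clustering, PCA, binary motif discovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from synvar.filtering import ConnectivityMatrix, run_pipeline
from synvar.motifs import (
    binarize_presence,
    hamming_cluster,
    input_correlation_matrix,
    kmeans_inputs,
    pca_project,
    summarize_motifs,
)
from synvar.synthetic import (
    generate_connectome,
    generate_motif_profiles,
    subtype_configs,
)

from conftest import matrix_from_frame


def combined_subtype_matrix(seed=0, n_columns=30, mode="absolute"):
    """Concatenate a CT1-dominated and an Mi4-dominated population."""
    cfg_a, cfg_b = subtype_configs(seed=seed, n_columns=n_columns)
    parts, labels = [], []
    for tag, cfg in (("ct1", cfg_a), ("mi4", cfg_b)):
        syn, ann, _ = generate_connectome(cfg)
        mat, _, _ = run_pipeline(syn, ann, mode=mode)
        d = mat.data.copy()
        d.index = [f"{tag}_{i}" for i in d.index]
        parts.append(d)
        labels += [tag] * len(d)
    data = pd.concat(parts).fillna(0.0)
    return ConnectivityMatrix(data, mode), pd.Series(labels, index=data.index)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, 8).astype(float)
        m = matrix_from_frame({"a": x, "b": x})
        res = input_correlation_matrix(m)
        assert res.r.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        x = np.array([1.0, 2, 3, 4, 5])
        m = matrix_from_frame({"a": x, "b": -x})
        res = input_correlation_matrix(m)
        assert res.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_pearsonr_oracle(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            rng.integers(0, 15, (5, 3)).astype(float), columns=list("abc")
        )
        res = input_correlation_matrix(matrix_from_frame(data))
        for a, b in itertools.combinations("abc", 2):
            r, p = stats.pearsonr(data[a], data[b])
            assert res.r.loc[a, b] == pytest.approx(r, abs=1e-12)
            assert res.p.loc[a, b] == pytest.approx(p, abs=1e-12)
            assert res.p_adjusted.loc[a, b] == pytest.approx(
                min(1.0, p * 3), abs=1e-12
            )

    def test_constant_column_reported_missing(self):
        m = matrix_from_frame({"a": [1.0, 2, 3], "b": [4.0, 4, 4]})
        res = input_correlation_matrix(m)
        assert np.isnan(res.r.loc["a", "b"])
        assert np.isnan(res.p_adjusted.loc["a", "b"])

    def test_planted_antagonism_is_significant(self):
        m, _ = combined_subtype_matrix(seed=2)
        res = input_correlation_matrix(m)
        sig = res.significant_pairs(0.001)
        pair = sig[
            (sig[["type_a", "type_b"]].isin(["Mi4", "CT1"]).sum(axis=1) == 2)
        ]
        assert len(pair) == 1 and pair["r"].iloc[0] < 0


class TestKmeans:
    def test_two_point_masses_perfectly_separated(self):
        data = pd.DataFrame(
            [[10, 0]] * 5 + [[0, 10]] * 5, columns=["a", "b"], dtype=float
        )
        labels, means = kmeans_inputs(matrix_from_frame(data), 2, seed=0)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_k_equals_n_zero_inertia(self):
        data = pd.DataFrame([[0.0, 0], [5, 5], [10, 0]], columns=["a", "b"])
        labels, means = kmeans_inputs(matrix_from_frame(data), 3, seed=0)
        assert labels.nunique() == 3

    def test_k_larger_than_n_rejected(self):
        data = pd.DataFrame([[1.0, 2]], columns=["a", "b"])
        with pytest.raises(ValueError):
            kmeans_inputs(matrix_from_frame(data), 2)

    def test_determinism(self):
        m, _ = combined_subtype_matrix(seed=1, n_columns=10)
        l1, _ = kmeans_inputs(m, 2, seed=42)
        l2, _ = kmeans_inputs(m, 2, seed=42)
        assert (l1 == l2).all()

    def test_recovers_planted_subtypes(self):
        m, truth = combined_subtype_matrix(seed=0)
        labels, _ = kmeans_inputs(m, 2, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.9


class TestPca:
    def test_rank_one_data_explained_by_pc1(self):
        base = np.array([1.0, 2, 3])
        data = pd.DataFrame(np.outer([1, 2, 3, 4], base), columns=list("abc"))
        res = pca_project(matrix_from_frame(data))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_cloud_splits_variance(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        res = pca_project(matrix_from_frame(data))
        assert res.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_column_dropped(self):
        data = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 4, 4], "c": [0.0, 1, 2]})
        res = pca_project(matrix_from_frame(data))
        assert res.dropped_types == ["b"]
        assert "b" not in res.loadings.index

    def test_row_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res1 = pca_project(matrix_from_frame(data))
        res2 = pca_project(matrix_from_frame(data.iloc[::-1]))
        s1 = res1.scores.sort_index()
        s2 = res2.scores.sort_index()
        for pc in s1.columns:
            assert np.allclose(s1[pc], s2[pc]) or np.allclose(s1[pc], -s2[pc])

    def test_antagonistic_types_load_with_opposite_signs(self):
        m, _ = combined_subtype_matrix(seed=0, mode="relative")
        res = pca_project(m)
        assert (
            res.loadings.loc["Mi4", "PC1"] * res.loadings.loc["CT1", "PC1"] < 0
        )


class TestBinarize:
    def test_indicator_before_exclusion(self):
        data = pd.DataFrame({"x": [0, 3], "y": [5, 0]})
        out = binarize_presence(matrix_from_frame(data), exclude_types=())
        assert out.values.tolist() == [[0, 1], [1, 0]]

    def test_core_types_excluded(self):
        data = pd.DataFrame({"L3": [3, 4], "Mi4": [1, 1], "CT1": [2, 2], "C3": [0, 5]})
        out = binarize_presence(matrix_from_frame(data))
        assert list(out.columns) == ["C3"]

    def test_excluding_everything_warns_not_errors(self):
        data = pd.DataFrame({"a": [1, 2]})
        out = binarize_presence(matrix_from_frame(data), exclude_types=("a",))
        assert out.shape == (2, 0)

    def test_matches_ground_truth_presence(self, small_pipeline, small_connectome):
        matrix, _, _, truth = small_pipeline
        _, cfg = small_connectome
        variable = [t.name for t in cfg.variable_types]
        out = binarize_presence(matrix)
        common = [c for c in out.columns if c in variable]
        expect = truth.presence[common].reindex(out.index)
        assert (out[common].to_numpy() == expect.to_numpy()).all()


def brute_force_average_linkage(dist, k, max_branches=500):
    """All k-clusterings reachable by greedy average-linkage merges.

    Exhaustive over merge pairs; when several pairs tie for the minimum
    average distance every branch is followed, so the result is the set of
    valid agglomerative outcomes.
    """
    results = []
    stack = [[frozenset([i]) for i in range(len(dist))]]
    seen = set()
    visited = set()
    while stack and len(results) < max_branches:
        clusters = stack.pop()
        state = frozenset(clusters)
        if state in visited:
            continue
        visited.add(state)
        if len(clusters) == k:
            key = frozenset(clusters)
            if key not in seen:
                seen.add(key)
                labels = np.empty(len(dist), dtype=int)
                for c, members in enumerate(sorted(clusters, key=min)):
                    labels[list(members)] = c
                results.append(labels)
            continue
        dists = {}
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dists[(i, j)] = np.mean(
                    [dist[a, b] for a in clusters[i] for b in clusters[j]]
                )
        # average linkage is reducible: merging any reciprocal nearest
        # neighbours yields a valid dendrogram, so follow each such pair
        nn = {
            i: min(
                d for (a, b), d in dists.items() if i in (a, b)
            )
            for i in range(len(clusters))
        }
        for (i, j), d in dists.items():
            if d <= nn[i] + 1e-9 and d <= nn[j] + 1e-9:
                merged = [
                    c for idx, c in enumerate(clusters) if idx not in (i, j)
                ]
                merged.append(clusters[i] | clusters[j])
                stack.append(merged)
    return results


class TestHammingCluster:
    def test_hamming_distance_counts_differing_bits(self):
        binary = pd.DataFrame(
            [[1, 0, 1, 1]] * 6 + [[1, 1, 0, 1]] * 6, columns=list("wxyz")
        )
        binary.iloc[0, 0] = 0  # break exact ties for the silhouette
        res = hamming_cluster(binary, k_range=range(2, 5))
        assert res.distances.iloc[1, 6] == 2

    def test_metric_axioms_on_random_profiles(self):
        rng = np.random.default_rng(0)
        binary = pd.DataFrame(rng.integers(0, 2, (12, 9)))
        res = hamming_cluster(binary, k_range=range(2, 6))
        d = res.distances.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(12), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_two_planted_motifs_recovered(self):
        binary, labels = generate_motif_profiles(60, 2, 17, 0.02, seed=3)
        res = hamming_cluster(binary, k_range=range(2, 8))
        assert res.chosen_k == 2
        assert adjusted_rand_score(labels, res.labels) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_labels_match_brute_force_merges(self, seed):
        rng = np.random.default_rng(seed)
        binary = pd.DataFrame(rng.integers(0, 2, (9, 25)))
        res = hamming_cluster(binary, k_range=range(2, 5))
        for k in range(2, 5):
            # tied dendrogram heights can make an exact k-cut impossible;
            # compare at the partition size actually produced
            k_eff = res.labels_by_k[k].nunique()
            oracle = brute_force_average_linkage(res.distances.to_numpy(), k_eff)
            assert any(
                adjusted_rand_score(labels, res.labels_by_k[k]) == 1.0
                for labels in oracle
            )

    def test_identical_rows_rejected_with_guidance(self):
        binary = pd.DataFrame([[1, 0, 1]] * 20)
        with pytest.raises(ValueError, match="identical"):
            hamming_cluster(binary, k_range=range(2, 5))

    def test_too_few_rows_rejected(self):
        binary = pd.DataFrame(np.eye(5, dtype=int))
        with pytest.raises(ValueError):
            hamming_cluster(binary, k_range=range(4, 16))


class TestMotifSummary:
    def test_identical_cluster_fractions_are_binary(self):
        binary = pd.DataFrame([[1, 0]] * 4 + [[0, 1]] * 4, columns=["a", "b"])
        labels = pd.Series([0] * 4 + [1] * 4, index=binary.index)
        out = summarize_motifs(binary, labels)
        assert set(out[["frac_a", "frac_b"]].to_numpy().ravel()) <= {0.0, 1.0}
        assert out.loc[0, "dominating"] == ["a", "b"]

    def test_single_row_cluster(self):
        binary = pd.DataFrame([[1, 0], [1, 1], [0, 1]], columns=["a", "b"])
        labels = pd.Series([0, 1, 2], index=binary.index)
        out = summarize_motifs(binary, labels)
        assert out.loc[1, "frac_b"] == 1.0 and out.loc[1, "n"] == 1

    def test_planted_motifs_dominating_types(self):
        binary, labels = generate_motif_profiles(80, 2, 10, 0.0, seed=4)
        out = summarize_motifs(binary, labels)
        # zero noise: every type is fully present or absent in each motif
        assert all(
            out.loc[c, "dominating"] == list(binary.columns)
            for c in out.index
        )
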