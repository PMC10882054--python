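#!/usr/bin/env python
"""Search for structure in the input profiles.

Input-input Pearson correlations (Bonferroni-corrected), k-means at k=2
and k=6, PCA of standardized relative counts, and presence/absence motif
discovery on the variable inputs via Hamming-distance agglomerative
clustering with silhouette model selection over k=4..15.
"""

import argparse
import json
from pathlib import Path

from synvar.io import read_matrix_csv
from synvar.motifs import (
    binarize_presence,
    hamming_cluster,
    input_correlation_matrix,
    kmeans_inputs,
    pca_project,
    summarize_motifs,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    matrix = read_matrix_csv(args.results / "matrix_absolute.csv")
    relative = read_matrix_csv(args.results / "matrix_relative.csv", "relative")

    corr = input_correlation_matrix(matrix)
    corr.r.to_csv(args.results / "input_correlations.csv")
    sig = corr.significant_pairs(0.001)
    sig.to_json(args.results / "significant_correlations.json", orient="records")

    for k in (2, 6):
        labels, means = kmeans_inputs(matrix, k=k, seed=args.seed)
        labels.to_csv(args.results / f"kmeans_k{k}_labels.csv")
        means.to_csv(args.results / f"kmeans_k{k}_means.csv")

    pca = pca_project(relative)
    pca.scores.to_csv(args.results / "pca_scores.csv")
    pca.loadings.to_csv(args.results / "pca_loadings.csv")

    binary = binarize_presence(matrix)
    motifs = hamming_cluster(binary, k_range=range(4, 16))
    motifs.silhouette_by_k.rename("silhouette").to_csv(
        args.results / "silhouette_curve.csv"
    )
    motifs.labels.to_csv(args.results / "motif_labels.csv")
    summarize_motifs(binary, motifs.labels).to_csv(
        args.results / "motif_summary.csv"
    )

    print(f"significant correlated pairs (p_adj < 0.001): {len(sig)}")
    print(
        "PC1/PC2 explained variance: "
        f"{100 * pca.explained_variance_ratio[0]:.1f}% / "
        f"{100 * pca.explained_variance_ratio[1]:.1f}%"
    )
    print(
        f"motif clustering over {binary.shape[1]} variable inputs: "
        f"chosen k = {motifs.chosen_k} "
        f"(silhouette {motifs.silhouette_by_k.max():.3f})"
    )


if __name__ == "__main__":
    main()
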