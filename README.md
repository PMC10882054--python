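# synvar

Quantifying presynaptic-input heterogeneity across the retinotopic columns
of the fly optic lobe.

Columnar interneurons of the *Drosophila* medulla (Tm9, Tm1, Tm2) repeat
once per retinotopic column, yet their presynaptic wiring need not repeat.
`synvar` is an analysis pipeline for measuring that variability from
connectome synapse tables and for corroborating it with light microscopy
and physiology:

- **Synapse filtering** — ingest automatically detected synapses (one row
  per synapse with pre-segment, post-target, 3D position, cleft score),
  apply confidence and redundancy filters, and build target-cell × input-type
  connectivity matrices (absolute counts, relative fractions, or
  presence/absence).
- **Heterogeneity statistics** — pairwise cosine similarity of input
  profiles within and across hemispheres, per-type variability (std and
  coefficient of variation), rank-order structure, and Kruskal–Wallis /
  Dunn–Bonferroni group comparisons.
- **Motif discovery** — input–input Pearson correlations with Bonferroni
  correction, k-means subtyping, PCA of standardized relative counts, and
  presence/absence motif clustering (Hamming distance, agglomerative
  linkage, silhouette-chosen cluster number over k = 4–15).
- **Spatial mapping** — per-column coordinates (presynaptic site nearest
  the dendritic-postsynapse centroid), dorsoventral assignment by planar
  SVD, presence maps, and a join-count permutation test for spatial
  structure.
- **Puncta apposition** — the expansion-microscopy counterpart: detect
  Brp-like presynaptic puncta (local maxima, 200-nm separation), binarize
  the dendrite-membrane mask, and count puncta within 300 nm of the mask
  per column ROI.
- **Trace clustering** — ΔF/F normalization with a mean-augmented
  denominator, ΔF/F = (F − F0)/(F0 + F̄), z-scoring, and k-means under the
  correlation distance to expose the diversity of response time courses.
- **Synthetic data** — generators for connectomes, two-channel image
  volumes and trace sets with full ground truth, so every stage is
  testable end to end without any external download.

The statistics at the core are elementary but the bookkeeping is not:
every filter (cleft score ≥ 50, redundant detections < 100 nm apart,
partner cells with ≥ 3 synapses, input types present in ≥ 5% of columns)
changes what "an input" means, and the package treats that chain as a
single auditable pipeline whose conservation identities are tested
exactly.

## Worked example

The `analysis/` scripts run the whole study on synthetic data at the
study's scale (two mirrored hemispheres of 170 columns each, 3 core input
types, 17 variable types):

```sh
python analysis/01_simulate_connectome.py --seed 1
python analysis/02_build_matrices.py
python analysis/03_heterogeneity.py
python analysis/04_motifs.py
```

which prints, among other things:

```
39009 synapses survive cleft + redundancy filters
340 columns x 20 retained input types
synapses per column (identified): 85.6 +/- 15.7
strongest inputs (mean synapses/column):
  L3: 25.1
  CT1: 15.4
  Mi4: 13.9
mean cosine similarity R: 0.850 (n=14365)
mean cosine similarity L: 0.859 (n=14365)
mean cosine similarity RL: 0.855 (n=28900)
motif clustering over 17 variable inputs: chosen k = 4 (silhouette 0.139)
```

Reading: the redundancy and confidence filters bring the detected-synapse
table back to exactly the planted connectivity; the three core inputs
(L3, CT1, Mi4) keep their planted per-column means; the two hemispheres
have nearly identical similarity structure (mean cosine similarity
differing by < 0.01); and with independently drawn variable inputs the
presence profiles carry no strong planted motif, so the silhouette value
at the chosen k stays low — in contrast to planted-motif data, where the
same procedure recovers the exact motif count (see the tests and the
acceptance script). Scripts `05`–`07` run the spatial, expansion-
microscopy and calcium-trace stages the same way.

## Layout

```
src/synvar/        library: synthetic, filtering, heterogeneity, motifs,
                   spatial, puncta, traces, io
analysis/          numbered narrative drivers writing tables to results/
tests/             pytest suite, including end-to-end property checks
scripts/           acceptance script
docs/methods.md    methods note: models, parameters, design choices
```
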