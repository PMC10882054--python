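# Methods

This note documents the models, parameters and numerical choices behind
`synvar`, and what the synthetic-data generators do and do not emulate.

## The filtering pipeline

A synapse table has one row per automatically detected synapse:
presynaptic segment id, postsynaptic target-cell id, 3D position in
nanometres, detection confidence (cleft score), and the postsynaptic
compartment (dendritic/axonal). The pipeline order is fixed and each
stage is idempotent on its own output:

1. **Cleft-score filter** (default ≥ 50, boundary inclusive) removes
   low-confidence detections.
2. **Redundancy removal** (default < 100 nm): within each
   (pre-segment, post-cell) pair — redundancy is a property of a
   *connection*, not of the whole volume — retention is greedy in
   descending cleft score with ties broken by input order, so the most
   confident detection of each site survives and the result is
   deterministic and idempotent. Synapses exactly at the radius are both
   kept (the rule is strictly "less than").
3. **Aggregation** per input cell and per input type. Segments without an
   annotation are mapped to an explicit `UNKNOWN` label, never dropped.
4. **Partner-count threshold** (default ≥ 3 synapses) applied per input
   *cell* before type aggregation; cells below it are zeroed and type
   totals recomputed. Multiplicity is the number of surviving cells of a
   type per column.
5. **Matrix modes**: absolute integer counts; relative fractions with the
   row's *full* post-threshold total (UNKNOWN included) as denominator,
   so removing rare types later cannot inflate fractions; binary
   presence.
6. **Presence cut** (default ≥ 5% of columns, boundary inclusive) drops
   input types too rare to analyze. The `UNKNOWN` column is exempt so the
   relative denominators stay interpretable.

Conservation is tested exactly: matrix total + UNKNOWN + sub-threshold
synapses = post-dedup synapse count.

## Heterogeneity statistics

Cosine similarity cos(u,v) = u·v/(‖u‖‖v‖) over unordered within-group
pairs of row profiles; the mixed two-hemisphere set is all cross pairs.
Similarity is computed on the presence-filtered type set with UNKNOWN
excluded; because it is scale-invariant per row, absolute and relative
modes give identical values on a common type set. Variability per type is
reported as mean, std (population by default, sample switchable) and
c.v. = std/mean (missing when the mean is 0). Ranks are dense per row,
1 = largest, ties share the minimum rank, absent inputs unranked. Group
comparison uses Kruskal–Wallis with Dunn's post hoc z tests
(tie-corrected pooled rank variance) and Bonferroni adjustment over the
pair count; scikit-posthocs-style Dunn tests are not in the dependency
stack, so the z statistic is implemented directly and verified against
the closed-form rank expression in the tests.

A caveat the acceptance output makes visible: similarity *pairs* are not
independent samples (each column participates in n−1 pairs), so with
hundreds of columns the omnibus test on tens of thousands of pairs is
over-powered and flags mean differences < 0.01 as significant. The
absolute between-hemisphere difference is therefore reported alongside
the p-value.

## Motif discovery

Pearson correlations between type counts across columns, two-sided p from
t = r√(n−2)/√(1−r²), Bonferroni over the m(m−1)/2 unique pairs; pairs
with a constant column are reported missing. K-means (Euclidean, 10
seeded restarts, best inertia) operates on count profiles. PCA
standardizes columns to unit variance, eigen-decomposes the covariance,
and fixes signs so each component's largest-magnitude loading is
positive; zero-variance columns are dropped with a warning. Binary motif
discovery excludes the core types (always present, hence uninformative
bits), computes pairwise Hamming distances in bits, clusters with
average-linkage agglomerative clustering on the precomputed distances
(the linkage criterion was an open choice; average is the standard
default for precomputed metrics) and selects the cluster number by the
mean silhouette computed on the *same* Hamming distances, over k = 4–15,
ties toward the smallest k. All-identical profiles are rejected with
guidance since the silhouette is undefined.

## Spatial mapping

A column's coordinate is the presynaptic site nearest (Euclidean, ties by
input order) the centroid of the target cell's dendritic postsynapses;
the dendritic/axonal flag must come with the data, as it is anatomical
information not derivable from the table. The dorsoventral split centers
each hemisphere's coordinates, projects onto the top-2 right singular
vectors, and draws the midline through the centroid along the first
principal axis; the label is the sign of the second in-plane coordinate.
Because an SVD axis has arbitrary sign, an explicit dorsal reference
point anchors the orientation; the split is then invariant to rigid
motions of the coordinates. Collinear inputs are rejected (no plane).

The join-count permutation test (a package addition, not part of the
original analysis repertoire) quantifies "no apparent spatial structure":
the statistic is the number of nearest-neighbour column pairs with equal
presence labels, compared with its distribution under ≥ 999 label
permutations; values outside the central 95% interval indicate clustered
or dispersed presence.

## Puncta apposition

All distances are image-space (post-expansion) nanometres; the expansion
factor is carried as metadata so biological-space values can be derived.
Puncta are local maxima (3×3×3 neighbourhood) above an intensity
threshold (Otsu per channel by default, always overridable and logged),
retained greedily by descending intensity subject to a 200-nm minimum
separation computed with anisotropic voxel sizes. The membrane mask is
binarized (Otsu or explicit threshold); each punctum's minimum distance
to the mask is read from an anisotropic Euclidean distance transform,
with an exhaustive puncta-to-voxel scan kept as the test oracle. Puncta
within 300 nm (inclusive) are counted as synapses into the ROI label at
their centre voxel; puncta outside all ROIs go to an explicit unassigned
bucket so counts are conserved. Shrinking the distance threshold never
increases a count.

## Trace normalization and clustering

Per ROI: (1) high-pass filtering implemented as subtraction of a
150-frame centred moving median — the operative specification is the
frame count; the filter's analytic form was open, and a moving baseline
is robust to response transients; (2) F0 = mean over background-stimulus
epochs; (3) ΔF/F = (F − F0)/(F0 + F̄) with F̄ the full raw-trace mean,
which keeps near-zero baselines from exploding; (4) averaging over
equal-length trials (before z-scoring); (5) linear interpolation to a
common 10 Hz. Z-scoring divides by the population std and errors on
constant traces, naming the ROI. Clustering uses the correlation
distance d = 1 − corr; on z-scored traces this is proportional to squared
Euclidean distance, so standard k-means minimizes it directly; traces are
re-z-scored internally, making labels invariant to per-trace affine gain.

## Synthetic-data generators

**Connectome.** Columns sit on a hexagonal lattice (5 µm pitch, a patch
wider than tall so the first principal axis is unambiguous), mirrored
into two independently sampled hemispheres at 170 columns each — the
scale of the real dataset. Defaults emulate the Tm9 architecture as
reported: three core inputs at per-column means 25 ± 7.3 (L3),
15.0 ± 5.7 (CT1, planted on the axonal compartment), 13.3 ± 7.0 (Mi4);
seventeen variable inputs with Bernoulli presence 0.10–0.80 and means
4–7, including wide-field types contributing up to 4 cells per column.
Counts follow a discretized normal truncated from below (the count model
is not observable from printed moments; truncated normal matches them
directly); a column's type total is drawn once and split across cells so
each cell clears the partner threshold, with multiplicity capped so that
split is possible without inflating the totals. Presence probabilities
and count means for the variable types are package choices tuned to the
printed aggregate statistics — ~8 input cells and ~8 types per column,
identified cells carrying ~74% of all inputs, core types carrying ~half
of the total input — and are not per-type measurements. Noise sources:
near-duplicate detections (< 100 nm jitter, slightly lower cleft score
than their source, so greedy dedup provably removes exactly them);
sub-threshold partner cells with 1–2 synapses, planted to carry ~25% of
each column's synapses (the unreconstructed floor); low-cleft detections
(score < 50); optionally unannotated cells (mapped to UNKNOWN). True
synapses of one connection are placed ≥ 100 nm apart by construction.
Cleft scores are normal(100, 25); genuine synapses are resampled to clear
the filter so the planted bookkeeping stays exact. The planted
dorsoventral label is the sign of the lattice's second principal axis
(max-y column dorsal), i.e. the half-plane a planar SVD split recovers.

What this generator does *not* emulate: neuron morphology, correlated
presence between types, distance-dependent connectivity, detection
biases that vary across the eye, or annotation errors. Exact planted-count
recovery therefore shows the bookkeeping is correct, not that the filters
are optimal for real detection noise.

**Volumes.** Gaussian spots (σ = 120 nm) at planted coordinates in the
puncta channel, cylindrical tubes in the membrane channel, additive
Gaussian noise, ROIs as equal slabs along x. Each planted punctum is
tagged with its containing ROI and its exhaustively computed minimum
distance to the mask, so apposition counts can be checked exactly at zero
noise. Real ExM data differ in background structure, mask complexity and
manually drawn ROIs.

**Traces.** ROI traces are amplitude × cluster template + Gaussian noise
with planted labels; templates share a time base. Real recordings add
motion, bleaching and correlated noise, none of which is modelled.

## Problem sizes and determinism

All generators, clusterings and permutation tests are deterministic given
a seed. Tests and the acceptance script use two 170-column hemispheres
for bookkeeping checks, 40-column hemispheres (replicated over 10 seeds)
for direction/recovery properties, 320-row planted-partition profiles for
motif selection, ≤ 32×96×96-voxel volumes for apposition checks, and
6-template/72–240-ROI trace sets — sizes at which every property under
test is already stable while the whole suite runs in well under a minute.
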