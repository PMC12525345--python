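# Methods

## Scope and data model

`degnet` consumes (a) a scored protein–protein edge list with a
protein→gene mapping, (b) per-gene differential-expression statistics
(log₂ fold change, p, BH-adjusted p) as produced by a DESeq2-style
analysis — the DE model itself is deliberately out of scope and its output
is treated as input — (c) per-gene count matrices used only for the
expression-level filter, and (d) a GMT annotation catalog with
parent→child term relations. All stages operate on a gene-level simple
undirected graph; edge confidences are retained as provenance but the
analysis adjacency is binary (an interaction either passed the confidence
filter or it did not — whether confidences should additionally weight the
random walks is not determinable from the method's description, and
binarization is the more conservative choice).

## Network construction

The construction order is fixed: confidence filter → protein-to-gene
mapping → restriction to genes expressed in ≥ 1 dataset → removal of
connected components with < 5 nodes. "Confidence above 150" is read as a
strict inequality. Protein pairs that collapse to one gene are dropped as
self-loops; duplicate gene pairs keep the maximum score; many-to-many
protein→gene mappings emit the full cross product before deduplication, so
evidence is kept without double counting. Node ordering for every matrix
view is lexicographic by gene id, making serialized matrices reproducible.

The degree-normalized adjacency is the symmetric form D^(−1/2)AD^(−1/2)
(entries 1/√(dᵢdⱼ) on edges). Symmetric normalization is preferred over the
row-stochastic D^(−1)A because it keeps the matrix symmetric, which in turn
keeps downstream cosine similarity a symmetric function of the node pair;
the row-stochastic form is available via `NetworkConfig.adjacency_mode`.

## Expression filter and DEG classification

A gene is expressed when its CPM reaches the threshold (default 2) in at
least `min_libraries` libraries in *each* group; for groups larger than
three libraries the requirement scales to max(`min_libraries`,
⌈2·group/3⌉). The boundary between the flat and proportional regimes
(group size 3) is a design choice exposed as
`DatasetConfig.proportional_group_size`. DEG status requires both
|log₂FC| ≥ the per-dataset cutoff and adjusted p < 0.05; the significance
threshold is a package convention (matching the upstream DE tool's default)
since fold-change cutoffs alone do not define significance.
Percent-down-regulated is reported at one decimal, round-half-up; for one
published dataset this yields 63.7 where the source prints 63.6 (the
quotient is 63.686…, consistent with truncation there); the package reports
the rounded value.

## Projection and Louvain clustering

DEGs present in the filtered network are "mapped"; the rest are uDEGs
triaged by biotype into coding / ncRNA (lncRNA plus other ncRNA) /
pseudogene / other. The explicit "other" bucket exists because biotype
catalogs are never exhaustive and the three named categories need not sum
to the uDEG total.

Louvain modularity (resolution 1.0, seeded) partitions the subgraph induced
by mapped DEGs — not the full network, which matches both the cluster-size
scale of interest and the existence of isolated DEGs; clustering the full
network is available behind a flag. Communities that come back disconnected
within the induced subgraph are split into connected parts before the
≥ 3-gene size filter, a repair rule guaranteeing every reported cluster is
internally connected. Cluster ids are assigned by decreasing size with
lexicographic tie-break, so a fixed seed reproduces identical cluster sets.
The causal gene is never injected into the induced subgraph; it enters only
through proximity scoring.

## Embedding

Walks: `num_walks` = 10 walks of `walk_length` = 100 start at every node;
transition probabilities are proportional to the normalized-adjacency
entries. The return/in-out biases p and q are implemented (second-order
walks), but at the default p = q = 1 the walk is first-order and simulated
fully vectorized. Word–context co-occurrence counts within the skip-gram
window (10) are accumulated over the corpus, converted to positive
pointwise mutual information, and factorized by truncated SVD at rank
`dimensions` = 128, with the embedding U·√Σ. This PPMI/SVD factorization is
the closed-form counterpart of skip-gram-with-negative-sampling training on
the same corpus; it was chosen because it is exactly reproducible (SVD sign
ambiguity is fixed deterministically) and fast enough that the multi-seed
benchmark suites run in seconds. Rank is capped at n for small graphs and
the vector matrix zero-padded to the requested width.

The 2-D visualization uses a second, denser walk set (d = 64, length 30,
200 walks/node) followed by UMAP (n_neighbors = 15, min_dist = 0.1,
euclidean); n_neighbors auto-shrinks with a warning on tiny graphs.

## Proximity score

Cosine similarities are mapped to link probabilities by logistic regression
(near-unregularized, C = 10⁶) on all network edges (subsampled above
20 000) versus an equal-size uniform sample of non-adjacent pairs; the 1:1
negative ratio and uniform sampling are reproducibility-motivated defaults
exposed in config. For a causal gene c, every other network gene g gets
P(link | sim(g, c)); these probabilities are rank-normalized over all
network genes (mean rank for ties), giving rank scores on (0, 1]. A
cluster's score combines its members' upper-tail p-values p_i = 1 − rank_i
via Fisher's method with the χ²(2k) upper tail; the score is 1 − combined p,
reported to two decimals (the exact value is kept in `score_exact`).
p-values are floored at ε = 10⁻¹² to keep ln p finite for top-ranked genes.
An alternative conversion p_i = 1 − association probability is available as
`probability_mode="direct"`; the rank mode is the default because it makes
the null distribution of scores approximately uniform regardless of the
link model's calibration. Rank normalization is computed over all network
genes (not DEGs only); the alternative is one flag away.

## Enrichment

ORA is the upper-tail hypergeometric test with population = the dataset's
network-mapped expressed genes (the space in which clusters were formed),
successes = term genes within that universe, draws = the query. BH
adjustment is applied within each query's term family; cluster-level
significance is adjusted p < 0.05. The comparative network across datasets
uses unadjusted p < 0.05 for node inclusion (both thresholds are config
keys), prunes any term with a retained descendant along the full transitive
closure of the parent→child relation, and weights edges by the number of
DEGs two terms share.

## Synthetic data

The generator emulates the structural assumptions of the analysis, not any
real dataset: a stochastic block model (default 500 genes, 5 equal blocks,
within-block edge probability 0.2, between-block 0.01) with one causal gene
in block 0; 10 DEGs planted in the causal block ("near") and 10 in the most
distant block ("far"); 10 extra DEG records for off-network genes (uDEGs)
with biotypes at 30 % coding / 50 % lncRNA / 20 % pseudogene, loosely
mirroring observed uDEG compositions; planted |log₂FC| ~ N(2.0, 0.3)
(floored just above the 0.6 calling cutoff) with adjusted p ~ U(0, 0.01),
background genes N(0, 0.2) with p ~ U(0.2, 1), so classification recovers
the planted set exactly by construction; negative-binomial counts
(dispersion 0.1, 3 vs 3 libraries, baseline means log-normal around 100)
with group means shifted by 2^log₂FC, plus 20 near-silent genes that the
CPM filter must drop; real edges scored uniformly on [151, 1000] plus 10 %
decoy edges scored ≤ 150 to exercise the confidence filter; and an
annotation catalog with one term per block, pairwise parent terms (for the
pruning rule) and random decoy terms. Everything is a deterministic
function of the seed, to the byte.

What the generator does not emulate: scale-free degree structure, hub
proteins, correlated annotation terms, library-size heterogeneity, and the
DE model's estimation noise (adjusted p-values are drawn, not computed).
Passing recovery tests therefore demonstrate that the scoring machinery
detects community-level proximity signal under clean modular structure,
not performance on real interactomes.

## Benchmarks and problem sizes

The recovery benchmark runs the full proximity chain on 20 seeded default
bundles and checks that the planted near set outscores the far set; the
planted sets themselves are scored (rather than the Louvain output) so the
comparison is well-defined in every run regardless of how the 20-gene
induced subgraph happens to partition. The null calibration embeds ten
Erdős–Rényi graphs (n = 300, p = 0.02) and scores 200 random 10-gene
clusters against random causal genes; the mean score sits near 0.5
(≈ 0.51; the small upward drift is the ε-floor contribution of top-ranked
genes that land in a random cluster with probability k/n). These problem
sizes keep the full suite under a minute on one core while leaving the
study-condition parameters (embedding dimensions, walk counts, SBM
densities) at their stated values.

## Numerical notes and limitations

- Ties in rank normalization use mean ranks; cluster ranking ties break by
  smaller cluster id.
- Logistic fitting with near-zero regularization can report large slopes on
  separable data; probabilities are still well-defined through the logistic
  link, and sklearn's solver handles separation gracefully.
- Fisher's method assumes independent p-values; cluster members' ranks are
  drawn without replacement and are weakly dependent, and members of a real
  cluster are topologically correlated — scores are a prioritization
  statistic, not calibrated significance tests.
- Single-seed-gene scoring only; multi-gene seeds, alternative embedding
  families and interactive visualization are out of scope.
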