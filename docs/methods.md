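# Methods

This note documents the statistical models and algorithmic conventions
implemented in `scheter`, the defaults it ships with, and what the synthetic
data used by the test suite does and does not establish about real data.

## Heterogeneity statistics

**Setting.** The input is a gene × cell matrix of depth-normalized
(RPKM/FPKM-like) expression values with a dropout mask and a cell → tumor
(patient) label map. A collection of tumors is called *heterogeneous* when
cells within tumors are more dissimilar to each other than cells between
tumors — a relational notion, distinct from subtype-composition diversity
indices, and one that needs no subtype demarcation.

**Average NSV fraction.** Each cell's expression vector over the selected
genes is z-scored with the population-variance convention (ddof = 0), so
`‖z‖² = n_genes` for every cell and the squared Euclidean distance between
two cells is `2·n_genes·(1 − ρ)` with ρ their Pearson correlation; distances
are therefore a monotone function of correlation, and the silhouette value
is invariant to the `√n_genes` scale factor. With tumors as the fixed
clustering, the silhouette of cell *i* is `s(i) = (b(i) − a(i)) / max(a(i),
b(i))`, where `a(i)` sums distances over *all* cells with the same tumor
label divided by the tumor size (the zero self-distance is included — the
divisor is `N_l`, not `N_l − 1`; with ~100 cells per tumor the difference is
negligible, but the include-self form is the one that reproduces the
package's reference simulation values, and an `exclude-self` variant is an
easy edit away in `silhouette_values`), and `b(i)` is the minimum over other
tumors of the mean distance to that tumor's cells. The per-tumor fraction of
strictly negative `s(i)`, averaged unweighted over tumors, is the index;
high values mean heterogeneous tumors.

**p_diff.** Pearson correlations between all unordered cell pairs are split
into intra-tumoral (X) and inter-tumoral (Y) pools. The statistic is
`p_diff = P(X > Y + ε) − P(X < Y − ε)` with margin ε = 0.05 by default.
Unlike Kolmogorov–Smirnov or Mann–Whitney tests, whose p-values collapse at
the 10⁴–10⁶ pair counts typical here, p_diff has a sample-size-free scale in
[−1, 1]; positive values indicate intra-tumoral homogeneity, and swapping
the pools negates the estimate. Estimation: a Gaussian KDE (Silverman
bandwidth) is fitted to each pool; N = 100 000 points per pool are drawn by
rejection sampling — uniform proposals on [−1, 1] accepted against the
density, with the acceptance bound taken as the maximum over a 1001-point
grid and the density linearly interpolated from that grid (the
interpolation error is far below the Monte-Carlo error at this resolution);
the two probabilities are then evaluated over all N × N cross pairs by
sorting, not enumeration. Correlations are computed on raw values; per-cell
z-scoring is affine per cell and leaves Pearson correlations unchanged.
For distributions on other scales (Cox coefficients), values and ε are
rescaled by the background's maximum absolute value, which leaves the
statistic unchanged while meeting the sampler's [−1, 1] domain.

**Entropy baseline.** Per tumor, each gene's marginal density is estimated
by a Gaussian KDE with the adaptive Silverman rule-of-thumb bandwidth
`0.9 · min(sd, IQR/1.34) · n^(−1/5)`; the tumor's entropy is the sum of the
per-gene differential entropies (gene-independence assumption), computed by
grid integration and reported in bits. The adaptive rule tracks multi-modal
marginals much better than the plain-sd rule, which can oversmooth a
mixture by a factor of five. It is still bandwidth-sensitive for *balanced*
mixtures, whose inter-quartile range spans both modes: this is why the
entropy ordering between the partially and fully mixed simulation cases is
not asserted at the lowest noise level (see below), and one of the reasons
the silhouette and p_diff indices are preferred.

## The three-case mixture simulation

Ten genes, five populations, 100 cells per population. Population *i*'s
centroid has `1/√2` in components `2i−1` and `2i` and zeros elsewhere (unit
norm, mutually orthogonal supports); a cell is its centroid plus i.i.d.
`N(0, σ²)` noise. Cells are allocated to five tumors deterministically:
case 1 — pure populations; case 2 — 60 home cells plus 10 from each other
population; case 3 — 20 cells from every population. Heterogeneity rises
from case 1 to 3 by construction. At σ ∈ {0.05, 0.5} the case-3 − case-1
gaps computed by this package are ≈ 8.1/1.9 bits for entropy, ≈ 0.64–0.67/
0.45 for NSV, and ≈ 1.02/0.54 for p_diff (case 1 − case 3), stable across
seeds; NSV and p_diff order the three cases correctly at every
σ ∈ {0.05, 0.1, 0.2, 0.3, 0.5}. Entropy separates case 1 from the mixtures
at every σ but its case-2/case-3 order flips at σ = 0.05 for the bandwidth
reason above.

## Gene-cluster hierarchies

**Consensus k-means.** For each k, genes (z-scored over cells) are
subsampled at 80% for 100 runs of seeded k-means++; pairwise consensus
values are the fraction of runs clustering two genes together among runs
sampling both; average-linkage agglomerative clustering of `1 − consensus`
is cut into k clusters. No further stability filtering is applied.

**The DAG.** Clusters are computed for k = 1..12 (the level-1 root is
included by default; `include_root=False` drops it). Cluster `c_j` at level
k+1 *inherits* `c_i` at level k when `|c_i ∩ c_j| ≥ 0.15·|c_j|`; edges are
stored from the coarser to the finer cluster with weight
`|c_i ∩ c_j|/|c_j|`, so directed paths run root → leaves and "downstream"
means larger k. A cluster may have several parents (joined from pieces) or
several children (split), so the structure is a DAG, not a dendrogram.

**Reduction.** *Linear* nodes have at most one parent and at most one
child. Maximal chains of linear nodes joined by consecutive edges are
extended at the bottom by the following node when it has several children
or none; each extended chain (*stump*) collapses to a single node carrying
the deepest cluster's gene set (`representative="union"` stores the union
instead). Edges are rewired through the collapse map, dropping self-loops;
the reduction is idempotent, and when two chains could absorb the same
bottom node the topologically earlier chain takes it (a deterministic
convention for an order the procedure leaves open). Annotations (p_diff,
NSV, density = observed fraction of the cluster's submatrix) survive the
collapse via the representative node.

## Enrichment and unique enrichment

Gene-set enrichment is the upper-tail hypergeometric probability, with the
universe defaulting to the genes that survived preprocessing in the
dataset. FDR adjustment is Benjamini–Hochberg, by default within each
cluster (one family per cluster — matching per-cluster reporting; a global
scope is available).

Unique enrichment resolves which single cluster a gene set's signal belongs
to. Scores are `−log10` adjusted p-values; clusters are visited in
descending score order (ties by cluster id) while they remain on a common
root-to-leaf path. Conventions where the procedure's prose is ambiguous:

* The sharp-drop stop (score below half of the last accepted cluster *and*
  below 5.0) takes precedence over the completes-a-path stop, so a weak
  leaf never joins the top-ranking list; a strong cluster that completes a
  root-leaf path is added and terminates the scan.
* An ambiguous sibling — the next sorted cluster sharing a parent with the
  last accepted one, scoring above half of it and above 5.0 — evicts that
  last member.
* When every candidate path has a *hole* (an on-path non-member scoring
  below the accepted minimum) the longest contiguous run of members is
  taken, ties resolved toward the better-ranked run; otherwise the subpath
  spanning all members on a hole-free path.
* The path is extended one node at a time, up- then downstream, while
  exactly one neighbour has rank below (max rank on the path + 5) and
  score ≥ 5.0 — the rank slack 5 and score threshold 5.0 are distinct
  parameters that happen to share a numeral.

The deepest node of the final path is reported if it scores ≥ 5.0. The
implementation is checked against an independently coded transcription of
the procedure on hundreds of random hierarchies.

## Cross-dataset alignment

Clusters of two datasets *overlap* when their Jaccard index exceeds 0.2,
or lies in [0.1, 0.2] while each ranks in the other dataset's top ten by
overlap ratio. Subpaths of root-to-leaf paths match when more than 90% of
**all** their cross cluster pairs overlap (the all-pairs reading is the one
under which a shared-but-uninformative top node is excluded from the
maximal match); maximally matched pairs are those contained in no larger
matched pair. Tops are trimmed iteratively: a path's top goes when the
sibling branches hanging from it (complementary root-leaf paths: same top,
disjoint below) are poorly overlapped — over half of the cross pairs
non-overlapping — with the path's partner-side matches below their tops.
Paths of one dataset whose tops coincide and whose partner-side matches
mutually overlap are mergeable; maximal cliques of the mergeable relation
span per-dataset subgraphs.

Each dataset's subgraphs form a binary subgraph × edge matrix that is
NMF-factorized (Frobenius objective, multiplicative updates) for K = 2..10.
Initialization is `nndsvdar` — an SVD-based start with random fill, still
randomized per trial — because plain uniform random starts fall into
union-of-components local minima on roughly half of restarts of the
reference two-component toy, while `nndsvdar` recovers the planted
decomposition essentially always; K values beyond the matrix's smaller
dimension fall back to random initialization. Component rows are quantized
at 10% of their maximum, deduplicated, and kept when they hold at least two
edges inducing a single connected piece of the hierarchy.

Components are merged into meta gene clusters by maximal cliques of the
mergeable relation "intersection ≥ 75% of each side", computed on the
*member-gene sets* induced by each component's edges. Gene sets — not edge
sets — are the only universe shared across datasets; edge-set overlap would
make cross-dataset merging impossible, and meta clusters spanning datasets
are the entire point of the alignment. A reduced cluster belongs to a meta
cluster when it is an endpoint of one of its edges; clusters touched by no
meta cluster are orphans. The NMF initialization is re-randomized over 100
trials (10 in the heavier tests); each trial's cluster co-occurrence matrix
is compared to the others by Hamming distance over the common cluster
universe, and the medoid trial is reported. Combining meta clusters after
the fact is a curation step, supported only through an explicit
user-supplied merge map.

Meta clusters are characterized by (i) enrichment scores — the geometric
mean of `−log10` adjusted p-values over the nodes of all maximal paths with
≥ 3 nodes, every node significant at 10⁻³, inside the meta cluster's
subgraph (made connected by minimal hierarchy paths; nodes claimed
exclusively by other meta clusters removed) — and (ii) homogeneity ranks:
per dataset, reduced clusters are ranked by descending p_diff (ties share
the average rank) and a meta cluster reports the unweighted mean rank of
its members pooled over datasets, which sidesteps the dataset-specific
scale of raw p_diff values.

## Bulk validation

Expression coherence of a cluster is the p_diff between its member genes'
pairwise bulk correlations and those of a background of 8000 genes sampled
once without replacement (all genes when fewer exist). Prognostic
association replaces correlations with per-gene univariate Cox
proportional-hazards coefficients (Breslow ties; non-converging fits
skipped and counted), fitted on CDF-transformed expression — per-gene
tie-averaged ranks scaled by the sample count, which bounds values in
(0, 1] and absorbs monotone distortions. Enrichment of a meta cluster near
the top of the p_diff-sorted cluster list is scored by the one-sided
Kolmogorov–Smirnov p-value `exp(−2 n D₊²)` comparing the normalized
member-count random walk to the straight line joining its endpoints, with
n the number of clusters — the classical asymptotic form on the
n-point curves, as the walk construction itself fixes the sample size.

## Subtype prediction

A marker panel is subdivided into three groups by consensus k-means on the
reference bulk data; every non-panel gene is ranked per bulk dataset by the
maximum over groups of its average correlation with the group's panel
genes, and genes in both datasets' top-200 lists form the extended panel.
Cells are assigned to the subtype of maximum average pairwise-complete
Pearson correlation with the subtype's reference samples (dropout entries
skipped; cells with under three observed panel genes unclassified), with
the full average-correlation vector retained so a minimum-correlation
filter (e.g. 0.1) can be applied; patients take the plurality subtype of
their classified cells, ties broken toward the higher mean correlation and
flagged.

## Synthetic data: what it shows and what it does not

`simulate_hierarchy_suite` plants hierarchically organized co-expression
blocks (block factor, half factors, quarter factors with variance shares
0.4/0.25/0.2) shared across datasets or private to one, and grants each
dataset its own measured-gene universe, with optional leftover genes
grouped into dataset-specific filler blocks. Both choices mirror real data:
co-expression modules have nested substructure, essentially every retained
gene carries some covariance, and different cohorts retain different gene
sets after filtering. They are also what makes the alignment benchmark
well-posed — flat blocks collapse to single hierarchy nodes that no edge
component can represent, and fully unstructured noise genes yield
cross-linked hierarchies with thousands of root-leaf paths. Under the
defaults the alignment recovers every shared block as a meta cluster with
gene-union Jaccard 1.0 and leaves all private-lineage clusters (clusters
contained in a private block) as orphans, across all seeds tried.

`simulate_bulk_survival` ties a coherent block (target pairwise correlation
0.6) to exponential survival through a latent factor, censored at the 80%
quantile. Under the null (zero hazard coefficient) a correlated block's Cox
coefficients shift *as a unit*, so single-realization p_diff values
fluctuate widely even though their expectation is zero — the tests
therefore check the null in expectation over seeds.

None of the generators model read-count noise, dropout-rate/expression
relationships, library-size effects, batch effects, or gene-gene
correlation beyond the planted factors; passing tests demonstrate the
correctness and internal consistency of the algorithms under their stated
models, not robustness to the full messiness of real single-cell data.

## Problem sizes and other numerical choices

The test suite and the acceptance script run the mixture simulation at the
full 500-cell design with 20 000–30 000 rejection samples per p_diff
(Monte-Carlo SE well below the assertion tolerances), the alignment
benchmark at 3 datasets × 144 genes × 60 cells with 30 consensus runs and
10 NMF trials, and the survival benchmark at 120–250 genes; these sizes
keep every statistic comfortably inside its tolerance while the whole
suite completes in a couple of minutes. Degenerate inputs are handled
explicitly: constant cells fail z-scoring with a named error, zero-variance
genes are skipped (with a warning) in the entropy sum, all-missing genes
make mean imputation fail loudly, single-point correlation pools collapse
the KDE to a point mass, and `−log10` transforms clip p-values at 1e-300.
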