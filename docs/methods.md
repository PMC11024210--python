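# Methods

This note documents the models and numerical choices behind each stage
of the cascade, what the synthetic data does and does not emulate, and
the design decisions taken where several implementations were defensible.

## Synthetic data

Counts are negative binomial with mean/dispersion parameterization
(variance μ + μ²/θ, θ = 2 by default), sampled as a gamma–Poisson
mixture. Per-cell library sizes are log-normal (sdlog 0.35) around a
default mean of 3,000, chosen so that the detected-gene (nGene)
distribution of good cells peaks near 900 genes — the shape droplet
data of this tissue shows. Relative gene abundances are log-normal
across genes. Cluster identity multiplies each cluster's marker genes
by exp(marker_logfc) (default e² ≈ 7.4-fold) in its own cells, with
per-cell renormalization so markers trade off against the background —
the composition effect real normalization sees.

Low-quality cells scale their libraries by 0.08 and draw their
mitochondrial fraction from a Beta with mean 0.25 (good cells: mean
0.03); both Betas use concentration 100, a realistic tightness that
keeps good cells' percent.mito almost entirely below 10%. The first
⌈2%⌉ of genes carry the "mt-" prefix so mitochondrial load is computed
by name convention, as with real annotation.

The trajectory generator draws a latent depth ~ Uniform(0, 1) per cell
and acts multiplicatively on NB means: a "deep" module scales by
exp(lfc·(depth − ½)), a "shallow" module mirrors it; with branching, two
arm modules activate proportionally to progress past the branch point
(default 0.6) on their own arm only. Multiplicative effects keep counts
integer-valued and overdispersed. Depth terciles (arms labelled
separately) double as the cluster labels the pruning stage consumes.

Doublets are exact gene-wise sums of two distinct cells — column sums
are conserved by construction. Clone tables are Bernoulli compositions
per clone, nested in hemispheres (4–11 clones each, matching the scale
of real clonal inductions). Ortholog tables put exactly
round(frac·n_groups) duplicated genes in the teleost species.

None of this emulates sequencing reads, UMI collisions, ambient RNA,
batch structure or doublet-specific library inflation; a passing test
shows the stage recovers the planted statistical structure, not that it
is robust to every artifact of real libraries.

## QC

The complexity filter regresses nGene on nUMI with a degree-2 loess
(tricube weights, span 0.5; above 300 points the curve is evaluated on a
quantile grid and interpolated) and removes cells beyond 3 SD of the
residuals, two-sided. The SD is the plain standard deviation, not a
robust MAD. When the fit is numerically exact (residual SD below 1e−8 of
the response scale) nothing is flagged — residuals are then pure
round-off. Threshold conventions: remove nGene < 200 strictly, remove
percent.mito > 10 strictly, keep genes expressed in ≥ 10 cells; cells
are filtered before genes. Filtering is idempotent.

Variable genes follow the VST recipe: loess of log10 variance on log10
mean over genes, standardization by the fitted SD, clipping at √n_cells,
ranking by the variance of the clipped values.

PC selection keeps components that explain > 1% of the variance among
the first n_max and pass a JackStraw test: each replicate permutes 1% of
genes across cells and re-runs PCA; the permuted genes' loadings pool
into a per-component null, and the component's p-value is a one-sided
two-sample KS test that observed |loadings| are stochastically larger,
BH-corrected across components. The count-against-a-null-quantile
variant was tried first and is anticonservative when the null pool is
small; the KS form holds its size on pure noise (≤ 1 false component of
20 at FDR 0.05).

## Ensemble clustering and consensus

kNN edges live between union-symmetrized kNN pairs. Phenograph weights
are Jaccard overlaps of the two k-neighbour sets; SNN-Cliq weights are
1 − s/k with s the smallest average rank of a shared list member (each
cell ranks 0 in its own list). Weights are invariant to embedding
rotation.

The base ensemble spans the published algorithm families: Leiden with
the modularity objective (the SLM family), multilevel Louvain, walktrap
(4 steps), optional spinglass (run per connected component; excluded
from the default set because Potts annealing is slow and fragments
near-cliques), density peaks on the embedding, and a diagonal Gaussian
mixture with BIC-selected component count. Density peaks automates the
decision graph with an outlier rule: centers are points whose
γ = ρ·δ exceeds mean + 3 SD (falling back to the single densest point),
with ρ a Gaussian kernel density at the 2% distance quantile.

CSPA averages co-clustering indicators over runs. Robust clusters come
from an average-linkage cut of 1 − M at height 0.2, i.e. cluster cores
must co-cluster in ≥ 80% of runs ("conservative" quantified; exposed as
config). Merging tests cluster pairs in ascending consensus distance
(the dendrogram-sibling order) with the package-wide DE test — Wilcoxon
rank-sum on CP10K·log1p values with tie and continuity corrections,
BH-FDR 0.05, |log2FC| ≥ 0.25 — and merges below 10 significant genes,
restarting until a fixed point; the cluster count never increases.
One-vs-one sibling testing was chosen over one-vs-rest (documented
open choice).

Marker gates are greedy conjunctions of (gene, direction, decile
threshold) terms maximizing F1 against cluster-vs-rest, stopping at
4 terms or an F1 gain < 0.01, with candidates restricted to the 200
genes of largest |signed AUROC|. Validation trains an L2 logistic score
on the gate genes only, 5-fold stratified CV (folds shrink with a
warning below 10 cells), and requires held-out AUROC > 0.7.

## Doublets

Mock doublets are depth-rescaled sums of random cell pairs, co-embedded
with the data (CP10K·log1p, top variable genes, scaled PCA); a cell's
score is the fraction of mocks among its 30 nearest neighbours. By
default the top round(0.075·n) scores are flagged — the usual practice
of flagging as many cells as the expected doublet load of the assay — or
a fixed score threshold can be supplied. The cluster-level test counts
genes DE between a cluster and a pooled parent pair that are not DE
between the parents, and requires the centroid to project inside the
parent segment (projection parameter in [0, 1]).

## Scoring, gating, GSEA

Module scores bin genes into 25 equal-frequency bins by mean expression;
each signature gene draws up to 100 distinct control genes from its bin
(the whole bin when smaller), and the score is mean(signature) −
mean(controls) per cell. With whole-bin controls the all-genes signature
scores zero up to float round-off; scores are invariant to adding a
constant to all genes of a cell. Gating uses score quantiles (high 0.7,
low 0.3) as explicit stand-ins for thresholds that were set visually on
real data; proliferating cells can be excluded via a mask computed from
any cell-cycle signature. Ribosomal genes are detected by the RPS/RPL
name convention across species capitalizations.

The signed AUROC is the rank-based Mann–Whitney AUC mapped to
2·AUC − 1; ties are mid-ranked. GSEA uses the weighted KS running sum
(weight |statistic|), a gene-label permutation null, NES = ES divided by
the mean |null ES| of matching sign, and a two-sided permutation p on
|ES| — the two-sided form is uniform under the null and reaches
1/(n_perm + 1) for extreme sets, while direction is carried by the ES
sign. Sets below 5 genes are skipped with a notice.

## Pseudo-ordering

Diffusion maps use a Gaussian kernel with locally adaptive bandwidth
(the 7th-neighbour distance), symmetric normalization and
eigenvalue-scaled components 2..m+1. Three components feed the MST
stage: on the planted fixtures, additional components carry mostly NB
sampling noise, which inflates along-tree distances (adding components
degraded pseudo-order fidelity monotonically).

Tree distances average Euclidean along-tree path lengths over 1,000
MSTs of ⌊2n/3⌋-cell subsamples (Euclidean path length rather than edge
count — an undocumented choice in the original description; both are
computable here). Pairs never co-sampled — practically impossible at
n_trees ≥ 50 — are imputed by shortest paths through the observed-entry
graph, a no-op in the large-tree limit. Classical MDS (double-centered
−D²/2, top-3 eigenvectors) embeds the averaged distances; negative
eigenvalues are truncated and rank deficits zero-padded with a warning.

The elastic principal tree minimizes data term + λ Σ edge² + μ Σ star
deviations with hard assignments, exact linear solves per coordinate,
and topology maintained as the MST over node positions; it grows one
node at a time halfway between the worst-approximated point and its
nearest node, to a 100-node budget. λ = 0.1 and μ = 0.5 on data
standardized to unit variance: weaker elasticity lets the skeleton
zigzag through the noise band of a 1-D manifold and sprout spurious
branches. After fitting, junction-attached leaf paths that are
geometrically short (< 10% of the skeleton's total edge length) or carry
fewer than 3 cells are dropped as density artifacts — genuine arms are
long and well-populated.

Same-cluster pruning removes leaf paths whose two end-halves project
majorities of the same cluster, but only minor paths (≤ 10% of cells):
the step targets noisy paths formed by uneven density, and with broad
cluster labels a majority path can legitimately begin and end in one
cluster. Pruning never disconnects the graph and always keeps every
cluster represented at some node; at least one path survives.

Cells project orthogonally onto their nearest edge; pseudo-order is the
along-tree distance from the root to the projection, scaled to [0, 1],
and the branch id is the maximal-path index of the supporting edge. The
root is a biological choice (the deep-quiescence end, e.g. highest glial
/ lowest ribosomal score); absent an anchor, `diameter_root` uses an
endpoint of the tree diameter, which fixes the order up to the reversal
the rank statistics are agnostic to. Depth-associated genes are Spearman
correlations against the pseudo-order (t-approximation p-values, BH
correction), rank-invariant under monotone transforms, and the signed
rho column feeds preranked GSEA directly.

## Cross-species mapping

Paralogs collapse onto ortholog groups by summation — preserving the
count nature of the data for downstream normalization — with an audit
listing every many-to-one collapse. Neighbour voting re-implements the
MetaNeighbor construction: Spearman correlations between all cells of
both datasets over shared variable groups (VST on the combined matrix),
rank-standardization of the whole network, row-normalization to voting
weights, votes from one species' labels onto the other's cells, AUROC
per test cluster, symmetric average of both directions. The procedure is
invariant to cell order and to monotone per-cell transforms. A single
cluster per species yields the degenerate 1×1 map with AUROC 1 by
contract.

The three-way species call formalizes a judgement the original analyses
made qualitatively: "co-expressed" needs one cluster whose mean module
score beats the 0.99 quantile of random same-size sets and that
individually hosts at least half the set's genes; a gene counts as
individually enriched only where the DE test finds it up at marker-level
fold change (log2FC ≥ 1) — the ordinary 0.25 threshold lets
normalization composition shifts qualify and miscalls random sets as
"spread". "Spread" requires marker-level genes across ≥ 2 clusters with
no single qualifying cluster; anything else is "absent", and sets
covering < 3 groups are "not evaluable".

## Clonal statistics

The RG-only proportion pools clones and bootstraps hemispheres first,
then clones within each sampled hemisphere (cluster bootstrap,
percentile CI, 10,000 reps). "RG-only" includes pure-glia clones of any
size. The exact binomial test sums P(x | n, p0) over outcomes no more
likely than the observed one (with the customary 1 + 1e−7 relative
tolerance), the minimum-likelihood convention rather than tail doubling.
Mann–Whitney U uses the exact distribution when nm ≤ 10,000 and the
data are tie-free, otherwise the tie-corrected normal approximation;
Cliff's delta = (#{x>y} − #{x<y})/nm satisfies delta = 2U/(nm) − 1 with
ties counted half, asserted as an identity test; its CI is a percentile
bootstrap (method for the CI was an open choice).

## Orchestration and determinism

One global seed fans out to per-stage seeds by a counter (stage i gets
seed + 1000·(i+1)); toggling a stage never shifts another's stream.
Every run writes a manifest with a hash of the scientific parameters
(the output directory is excluded), per-stage seeds and output
checksums; identical manifests imply bit-identical outputs. All
randomness flows through `numpy.random.default_rng`; igraph's global
RNG is re-seeded per call.

## Problem sizes

The test suite and the acceptance script run the stages at: 1,500-cell
atlas (6 clusters × 30 markers, natural-log FC 2); 1,000-cell QC fixture
with 10% low-quality cells; 5% injected doublets on 1,000 cells with one
mock per cell; 800-cell trajectory with 1,000 bootstrapped MSTs and a
100-node skeleton; 600-cell Y fixture; 500-cell duplicated-dataset
homology with 20 label shuffles; 200-draw GSEA null calibration at 500
permutations. Unit tests use smaller variants of the same generators.

## Known limitations

- The generators plant clean, disjoint marker programs; overlapping
  programs, batch effects and ambient RNA are out of scope.
- Density peaks' outlier rule and the GMM's BIC selection are tuned for
  well-separated planted structure; on continuous manifolds they
  over-segment (harmlessly — the consensus absorbs it).
- The principal tree assumes a tree-shaped trajectory; cycles and
  disconnected trajectories are out of scope.
- Branch assignment is the maximal-path id between non-degree-2 nodes;
  no attempt is made to label branches biologically.
- Spinglass is excluded from the default ensemble (slow, fragments
  near-cliques); it remains available by name.
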