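# Methods

`seedatlas` analyzes two complementary views of a developing seed: bulk
RNA-seq of laser-dissected subregions (spatial compartments of the embryo,
endosperm and seed coat, sampled across developmental stages with
biological replicates) and single-nucleus RNA-seq of whole seeds.  The
pipeline calls subregion-specific transcripts, builds weighted gene
coexpression modules, clusters nuclei, calls cluster markers, and then
integrates the two datasets: clusters are assigned to subregions by
marker/specific-set enrichment and modules are projected onto the cell
map.  This note records the models, the parameters that matter, and the
numerical choices behind each stage.

## Detection and prevalence (bulk)

A transcript is *detected* in a (subregion, stage) group when every
biological replicate has at least one raw count; whole-seed libraries use
a CPM threshold instead (default 0.0978 CPM — the average CPM equivalent
of one raw count in the subregion libraries).  Group-level prevalence is
the mean CPM over replicates (a `cpm_of_sums` switch computes CPM of the
summed counts instead; the two agree exactly when libraries are equal).
Prevalence comparisons between a gene subset (e.g. transcription factors)
and the rest use a two-sided Mann–Whitney rank test restricted to the
genes detected in that group — rank-based because prevalence spans five
to six orders of magnitude.

## Subregion- and regional-specific calling

A gene is subregion-specific at a stage when it accumulates at a fivefold
or higher level (BH FDR < 0.001) in one subregion relative to **every**
other subregion at the same stage; regional-specific calls compare only
against subregions of the *other* seed regions, so the subregion-scope
calls are nested inside the regional-scope calls by construction.  A
pooled one-vs-all contrast is available behind `contrast="pooled"`.

The differential test is a negative-binomial exact test in the edgeR
tradition, implemented here directly:

- Replicate counts are rescaled to the geometric-mean library size,
  summed per group, and rounded ("equal-library pseudodata").
- Under the null the two group sums are NB with a shared per-replicate
  mean and sizes `n_g / phi`; the p-value sums the probabilities of all
  conditional splits no more likely than the observed one.  This
  convention makes "identical groups → p = 1" exact and avoids tail
  doubling.
- Per-gene dispersion `phi` (in `var = mu + phi mu²`) is a
  method-of-moments estimate on within-group residuals, floored at 1e-4
  and shrunk toward a trended prior with weight proportional to the
  residual degrees of freedom (prior df 10).  The trend is a running
  **mean** of the raw estimates over 20 equal-count abundance bins: the
  moment estimator is right-skewed, and a median trend biases dispersion
  low enough to make the exact test visibly anticonservative (null
  fraction p<0.05 of 0.063 vs 0.052 with the mean trend).

Fold changes are ratios of mean CPM with a 0.25-CPM pseudocount; FDR is
BH within each pairwise comparison, and calls report the minimum fold and
maximum FDR across the comparison set.  Because the test conditions on
library-normalized totals, heavy planted structure compresses CPM fold
changes compositionally — a property to keep in mind when choosing
planted effect sizes (below).

Cross-species conservation: regional-specific TFs of two species are
joined through an ortholog map under a region pairing, ranked by the
soybean-side gene's maximum CPM in its focal subregion, and the top five
per region reported.

## Coexpression modules

Input expression is `log2(mean CPM per subregion × stage group + 1)` over
genes detected in at least one group (replicate-level input is available
via configuration).  The network is the standard weighted construction:

- **Soft threshold.** For each power on a grid (default 1–20), the
  unsigned adjacency `|cor|^power` is summarized by its scale-free fit:
  log10 p(k) regressed on log10 k over ≥10 connectivity bins, signed
  R² = sign(−slope)·R².  The smallest power with signed R² ≥ 0.8 wins;
  otherwise the argmax, flagged as a fallback.  A network with
  (near-)constant connectivity — e.g. all genes copies of one profile —
  has no defined regression and is scored R² = 1 (trivially degenerate).
- **TOM.** Topological overlap
  `TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, unit diagonal.
- **Tree cut.** Average-linkage clustering of `1 − TOM`; modules are the
  maximal branches fully merged below `0.9 ×` the 0.99-quantile of merge
  heights, of size ≥ 30.  Coexpressed blocks join internally at low
  dissimilarity while unstructured genes only merge near the dendrogram
  top, so pure noise yields *no* module rather than one loose blob.  This
  is deliberately a static, fully deterministic cut — module counts will
  not match an adaptive hybrid tree cut on real data.
- **Eigengene.** First principal component of the gene-standardized
  member submatrix (sample scores), scaled to unit variance (ddof 1) and
  sign-oriented so the mean correlation with member profiles is
  non-negative.  Zero-variance members are dropped with a warning.
- **Merging.** The most-correlated eigengene pair is merged first and
  eigengenes recomputed, while any correlation ≥ 1 − 0.25; best-pair-first
  makes the result order-independent when correlations are distinct.
- **Spatial class.** A module is *subregion-specific* when ≥50% of its
  members are subregion-specific for one common subregion **and** that
  subregion carries the maximal mean eigengene value; the same criterion
  at regional scope gives *regional*; otherwise *shared*.  The 50%
  threshold sits between the ~77% member-specificity of spatially
  restricted modules and the ~20% of all others.

The whole coexpression path is deterministic: no randomized step exists.

## Single-nucleus processing

Cells failing QC (detected-gene range, minimum counts) are removed.
Normalization is `log1p(count / cell library × median library)` — a
median-library log normalization standing in for regularized-NB
transforms; the marker filters downstream are robust to this choice.
Embedding: top 2000 genes by within-abundance-bin standardized
dispersion, z-scored across cells (clipped at ±10), full-SVD PCA to 30
components.  Clustering: shared-nearest-neighbor graph (k = 20 including
self, Jaccard edge weights over all pairs sharing a neighbor, pruned
below 1/15), Leiden modularity optimization (RB configuration) at
resolution 1.0 with a recorded seed; labels are size-ordered.  A
degenerate embedding (all cells identical) short-circuits to a single
cluster.  Subclustering re-runs Leiden on one cluster's cells over the
same embedding, labeling children `{id}a`, `{id}b`, … by size.

Markers are one-vs-rest: genes expressed in ≥25% of either group are
tested by a two-sided Wilcoxon rank-sum on normalized values (exact
enumeration when the pooled cell count is ≤14, normal approximation with
tie correction otherwise), BH-adjusted per cluster.  Emitted records
satisfy three filters exactly: `log2FC ≥ 1` computed on the de-logged
scale as `log2((mean expm1(in)+1)/(mean expm1(out)+1))`, adjusted
p < 0.05, and in-cluster expression fraction ≥ 0.25.  Clusters with fewer
than three cells are skipped with a warning.  Pseudobulk columns are raw
count sums per cluster (or globally).

## Integration

The background universe for all overlap tests is the intersection of
genes detected in bulk (any group) and genes expressed in at least one
cell — an explicit, conservative choice that is configurable.  Cluster →
subregion assignment computes the hypergeometric upper-tail enrichment of
each cluster's markers against each subregion's specific set (odds ratio
from the 2×2 table, Haldane +0.5 when any cell is zero), BH-adjusts
across subregions within the cluster, and assigns the subregion with the
highest −log10 q among those with q < 0.05 (ties broken by odds ratio,
then lexicographically; further qualifying subregions are reported as
secondary assignments, and a cluster with no qualifying subregion — or no
markers — is left unassigned with the reason recorded).  Confidence is
the ratio of the best to second-best −log10 q.

Module projection scores each cell by the mean normalized expression of
module genes; clusters are summarized by the z-score of their mean
against the per-cell score distribution and called enriched at z ≥ 1.5.
Note the arithmetic cap: with k clusters a single enriched cluster cannot
exceed z = sqrt(k−1), so the 1.5 default presumes ≥4 clusters.
Cluster/subregion agreement uses Spearman correlation of log2(CPM+1)
profiles over shared genes, as does the global pseudobulk-vs-whole-seed
comparison.

## Gene-set enrichment

Hypergeometric upper-tail per term over an explicit background, BH across
all terms with a nonempty background intersection, rows with q < 0.05
reported sorted by (q, p, term id), top-5 summaries.  The annotation is
used as given: no ontology-graph propagation.

## The synthetic seed

The generator states a small world with every structure the pipeline
should recover; all generators are pure functions of (config, seed), and
the standard fixture (2000 genes; 8 subregions in 3 regions — 2 embryo,
2 endosperm, 4 seed coat; stages glob and cot; 3 replicates; NB
dispersion 0.1; 6 identity clusters × 150 cells plus one ambiguous
cluster; seed 7) runs the full pipeline in well under a minute.

- **Bulk.** Baseline log2-abundances are Normal(5, 2) across genes
  (≈4 orders of magnitude).  One hundred "universal" genes sit high
  enough (log2 CPM 7.5–10) to be detected in every replicate.  Planted
  structure: 5 subregion-specific genes per subregion per stage and 3
  regional genes per region per stage at 12-fold; 5 modules (sizes
  40–60) whose members share an 8-fold boost in a focal subregion at
  both stages, with loadings jittered in [1.0, 1.1]; 20 cluster-exclusive
  marker genes per cluster (boosted only in cells).  Counts are NB per
  replicate with the configured dispersion at a 200k library.
- **Effect-size margins.** Planted abundance is high (log2 CPM 5.5–7.5
  for specific/marker genes, 4.5–6 for module members) — mirroring the
  elevated median abundance of spatially specific transcripts — but
  deliberately capped so all planted mass stays a small fraction of each
  library: CPM is compositional, and heavy planted mass would compress
  every realized fold change in the focal subregion.  The dedicated
  specific/regional fold is 12× rather than the 5× calling threshold
  because the caller takes the *minimum* fold over 7 pairwise
  comparisons of 3-replicate NB group means (CV ≈ 0.19, right-skewed):
  a 12× plant keeps ≈3σ of margin over the threshold, an 8× plant only
  ≈1.5σ.  Module members stay at 8× — their recovery criteria (ARI,
  ≥50% member specificity) are medians, not minima.
- **Cells.** Each identity cluster samples multinomially from the
  *latent* mean profile of its subregion at the cot stage (plus its
  marker boosts, 2³ = 8×) at lognormal library sizes (median 4000,
  σ 0.3); the ambiguous cluster samples the pure baseline with no boosts,
  so it genuinely belongs to no single subregion.  Using latent rather
  than realized bulk profiles makes non-planted genes exactly
  exchangeable across clusters, so marker precision/recall are well
  defined: recall is scored on the planted exclusive markers, precision
  against the set of genes whose latent one-vs-rest log2FC is ≥ 0.5
  (margin below the caller's threshold of 1, so estimation noise on
  genuinely elevated genes — e.g. regional genes shared by sibling
  clusters — is not miscounted as a false positive).  Five percent of
  barcodes are empty (all-zero) and must be removed by QC.
- **Annotation.** One true term per planted module and per planted
  specific set, plus 30 random 20-gene decoys; an ortholog map with
  identity pairs (`AT_` prefix) for 60% of TF genes supports the
  conservation analysis against a pseudo-species whose regional calls
  follow the planted truth.

What the generator does **not** emulate: gene length and GC biases,
ambient RNA, doublets, batch effects, stage-dependent baselines and
library-size trends.  A green recovery test therefore establishes that
the estimators are correct and calibrated under their own model
assumptions — not that they are robust to the technical artifacts of
real droplet or LCM data.

## Numerical choices and degenerate inputs

- BH adjustment via `scipy.stats.false_discovery_control`.
- Exact rank-sum enumeration for pooled n ≤ 14; two-sided p is the
  doubled smaller tail, capped at 1 (equal to the classic exact p in the
  tie-free case).
- The NB exact test enumerates split probabilities in flat vectorized
  chunks (≤2e6 pmf evaluations per chunk); a total of zero gives p = 1.
- Zero-variance genes: error in adjacency (listed), excluded with a
  warning in eigengenes, excluded from the coexpression input.
- Zero-library columns/cells error with the offending ids; QC must run
  before normalization.
- Counts are stored sparse below 50% density and dense above; all
  operations are representation-agnostic.

## Known limitations

- Module counts from the static tree cut will differ from adaptive
  hybrid tree cutting; the cut is chosen for determinism and testability.
- The exact test's equal-library pseudodata rounds group sums, which adds
  negligible noise at realistic depths but is not bit-identical to
  quantile-adjusted pseudodata.
- Specificity calls use per-comparison BH; a global FDR across all
  comparisons of a stage would be more conservative.
- Assignment assumes marker sets and specific sets live on a shared
  background; genes absent from either dataset are silently excluded
  from the universe.
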