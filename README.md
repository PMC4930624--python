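# giniclust

Rare cell-type detection from single-cell gene expression data using
Gini-index feature selection and density-based clustering.

## The problem

Rare subpopulations — stem cells, circulating tumor cells, transient
totipotent-like states — are invisible to standard single-cell clustering
because standard feature selection is variance-based. The usual statistic,
the Fano factor `Var(X)/E[X]`, separates differentially expressed genes well
when a population is split 50/50, but its contrast vanishes as the minor
population shrinks: at one cell in ten thousand, a rare-cell marker and a
flat housekeeping gene are indistinguishable by Fano factor.

The Gini index does not have this failure mode. For a gene, sort cells from
lowest to highest expression and plot the cumulative share of total
expression against the fraction of cells included (the Lorenz curve `L(p)`);
the Gini index is

```
G = 2 * area between L(p) and the diagonal
  = Σᵢⱼ |xᵢ − xⱼ| / (2 n² μ)      ∈ [0, 1)
```

`G = 0` for perfectly uniform expression and `G → 1` when all expression sits
in a handful of cells — exactly the signature of a rare-cell marker, at any
population imbalance.

## The pipeline

1. **Gini index per gene** on the count matrix (for qPCR panels, a
   *bidirectional* Gini on `2^x` and `2^−x` also catches genes specifically
   silenced in rare cells).
2. **Trend normalization**: raw Gini is strongly tied to expression level, so
   a two-pass LOESS of Gini on log2 maximum expression (fit, drop genes whose
   residual is above the 75th percentile, refit) yields a *normalized Gini*
   (residual from the refit). High-Gini genes are selected at `p < 1e-4`
   under a robust normal fit to the normalized Gini (RNA-seq) or at
   normalized Gini `> 0.05` (qPCR).
3. **Clustering** of cells on the selected genes with DBSCAN on a precomputed
   distance — Jaccard over binarized detection for RNA-seq
   (`eps = 0.5, MinPts = 3`), one-minus-correlation (rescaled to [0, 1]) for
   qPCR (`eps = 0.25, MinPts = 5`). Unassigned cells are *singletons*;
   clusters under 5 % of the population are flagged *rare*.
4. **t-SNE** for visualization only (perplexity 10, 3000 iterations, random
   initialization).
5. **Differential expression** of each rare cluster against the largest
   cluster: a two-part hurdle likelihood-ratio test (logistic detection model
   + Gaussian model on log2 expression among detected cells, both with a
   cellular-detection-rate covariate) for counts, Welch t-tests for qPCR,
   with `p < 1e-5` and fold change `> 2` cutoffs. Fisher exact tests
   quantify overlap between DE genes and high-Gini genes, and a weighted
   z-score signature (e.g. a 2C-embryo-like score) ranks individual cells
   against a published expression signature.

Built-in generators reproduce the method's two benchmark designs with ground
truth: the two-gene Poisson-mixture proportion sweep, and a five-cluster
negative-binomial count matrix (2 × 1000 major cells; rare clusters of 4, 6,
and 10 cells with disjoint planted marker sets), plus a resampling protocol
that checks a rare cluster is re-identified when the rest of the population
is subsampled.

## Worked example

Simulate a desk-scale benchmark (two major clusters of 150 cells, rare
clusters of 4, 6 and 10 cells), select high-Gini genes, and cluster:

```sh
giniclust simulate nb-clusters --n-genes 2000 --sizes 150,150,4,6,10 \
    --n-shuffle 30 --seed 3 --out sim.mtx --truth truth.tsv
giniclust select  --input sim.mtx --format mtx_triplet \
    --genes-file sim.genes.txt --cells-file sim.cells.txt --out gini.tsv
giniclust cluster --input sim.mtx --format mtx_triplet \
    --genes-file sim.genes.txt --cells-file sim.cells.txt \
    --gini-table gini.tsv --metric jaccard --eps 0.5 --min-pts 3 \
    --out clusters.tsv
```

which prints

```
selected 81 high Gini genes
 cluster  size  rare
       1   266 False
       2    10  True
       3     6  True
       4     4  True
singletons: 34
```

All three planted rare clusters are recovered intact (clusters 2–4, flagged
rare because each holds under 5 % of the 320 cells); the bulk forms cluster 1
and 34 cells are left as singletons. Differential expression of a rare
cluster against the bulk then recovers its planted markers:

```sh
giniclust de --input sim.mtx --format mtx_triplet \
    --genes-file sim.genes.txt --cells-file sim.cells.txt \
    --clusters clusters.tsv --cluster 2 --reference 1 --out de.tsv
# -> 28 significant genes
```

The same pipeline runs from a YAML config with `giniclust run --config
run.yaml` (writing all tables plus a JSON manifest with the config hash), or
from Python:

```python
from giniclust import simulate_nb_clusters, run_pipeline, RunConfig

matrix, truth = simulate_nb_clusters(seed=0)
result = run_pipeline(matrix, RunConfig(min_genes=0))
print(result.clusters.summary())
```

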