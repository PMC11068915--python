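# cnatraj

**CNA-aware single-cell trajectory analysis.** Tools for asking how an
ordered ladder of genomic lesions — arm-level copy-number gains (e.g.
chr17q, chr17q+chr1q) and oncogene overexpression — distorts a stem-cell
differentiation trajectory, in experiments that profile several engineered
genotypes side by side with scRNA-seq and ATAC-seq.

The package is aimed at computational biologists analysing multi-genotype
differentiation experiments (e.g. neural-crest models of neuroblastoma
initiation) who need the statistics, not another end-to-end framework:
everything is a plain function or a small scikit-learn-style estimator over
AnnData/DataFrame containers, composable with the scanpy ecosystem.

## What it computes

- **Mutation score** — encode genotypes by lineage order,
  G(WT)=0 … G(most altered)=max; per cell,
  `m = mean(G of K nearest transcriptomic neighbours) / max(G)` ∈ [0, 1],
  plus the Shannon entropy of the neighbour genotype mix. A genome-wide
  Bonferroni-controlled Pearson screen finds mutation-linked genes and
  clusters them into gene sets (`cnatraj.mutation`).
- **Reference mapping** — weighted-kNN label transfer in a shared PCA basis
  with a prediction score in [0, 1], glasswork layouts (random placement
  inside concave cluster hulls), binned-control module scores, and a
  rank-based single-sample (ssGSEA-type) signature score for bulk cohorts
  (`cnatraj.mapping`).
- **Pseudobulk differential testing** — negative-binomial Wald test with
  trend-moderated dispersions, median-of-ratios size factors that can
  *exclude aberrant chromosome arms* so dosage is not mistaken for depth,
  published significance thresholds, Ward chromatin modules, and
  hypergeometric overlap enrichment (`cnatraj.differential`).
- **Peak-gene links** — promoter overlap plus distal candidates within
  250 kb, scored by cross-modality sample correlation with an empirical
  shuffle FDR (10 sample-label permutations; links kept at FDR ≤ 0.05)
  (`cnatraj.links`).
- **Regulons** — cluster-balanced, repetition-averaged TF→gene importances
  (pluggable regressor, gradient-boosted trees by default), an exact
  mean-shift changepoint threshold per TF (top 1% outliers set aside),
  motif-support filtering, correlation sign splitting at |r| ≥ 0.1, regulon
  activity scores and gene-set enrichment (`cnatraj.grn`).
- **Synthetic data** — a generator that plants all of the above (trajectory
  block, dosage arms, coupled peaks, signed TF network with motif support)
  with full ground truth, so every stage is verifiable without downloads
  (`cnatraj.sim`).

## Worked example

```python
import cnatraj as ct
from scipy.stats import spearmanr

# four genotypes x 500 cells on a five-state trajectory, with a planted
# differentiation block (block_strength=1) and arm-level dosage gains
cfg = ct.SimConfig(seed=1)
cells, truth = ct.simulate_cells(cfg)
norm = ct.normalize_log1p(cells)

scorer = ct.MutationScorer(k=30, n_components=10,
                           genotype_order=list(cfg.genotypes))
scorer.fit(norm, cells.obs["genotype"])
g = scorer.encoding_.encode(cells.obs["genotype"])
print(f"Spearman(own genotype, m) = {spearmanr(g, scorer.scores_['m']).statistic:.3f}")
print(scorer.scores_.head(3))
```

prints

```
Spearman(own genotype, m) = 0.963
                   m   entropy   K
cell_00000  0.044444  0.566510  30
cell_00001  0.022222  0.353359  30
cell_00002  0.111111  0.918296  30
```

These first cells are wild type: `m` near 0 means their expression
neighbourhoods are almost purely wild type, and the entropy (in bits) says
how mixed the 30-neighbour genotype composition is. The Spearman correlation
of 0.96
between each cell's own genotype and its neighbourhood score says the
planted genotype-specific expression divergence is recovered almost
perfectly at these study conditions.

Downstream stages follow the same pattern; for instance peak-gene linking:

```python
peaks = ct.simulate_peaks(cfg, cells, truth)
linker = ct.PeakGeneLinker(max_dist=250_000, n_shuffles=10, fdr=0.05)
linker.fit(peaks.var[["chrom", "start", "end"]],
           cells.var[["chrom", "tss"]], atac_pseudobulk, rna_pseudobulk)
linker.links_          # promoter + retained distal links with r and FDR
```

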