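# Methods

`cnatraj` quantifies how an ordered ladder of genomic lesions (arm-level
copy-number gains, oncogene overexpression) distorts a stem-cell
differentiation trajectory in multi-genotype single-cell experiments. This
note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic benchmark does and does not show.

## Genotype-mixing ("mutation") score

Genotypes are encoded by lineage order as integers G (wild type = 0, most
altered = max). For each cell, the score is

    m = mean(G over the K nearest transcriptomic neighbours) / max(G),

a number in [0, 1] measuring whether the cell's expression neighbourhood
resembles wild-type or mutant cells, independent of the cell's own genotype.
K defaults to 30. Neighbourhood entropy is the Shannon entropy (base 2 — any
base is monotonically equivalent for downstream correlation) of the
neighbour genotype distribution; it is 0 exactly when the neighbourhood is
genotype-homogeneous and log2(#genotypes) at the uniform mixture.

Neighbourhoods are built on a pluggable embedding. The default is PCA with
10 components on median-depth-normalised, log1p counts; any callable
producing a cells × d matrix can be substituted (the score's definition only
needs *a* neighbourhood graph, so a trained generative embedding can be
plugged in where available). kNN is exact (brute force) with Euclidean
distance, ties broken by cell index, self excluded; determinism over speed
is deliberate at the ≤10⁴-cell scale the score targets.

The genome-wide screen correlates each gene's normalised expression with m
(all cells, or excluding the highest-G genotype to expose subtler
dosage-linked effects) or with the entropy, using Pearson r and a two-sided
t-test, Bonferroni-corrected over the tested genes. Zero-variance genes are
excluded with a recorded reason. Top Bonferroni-significant genes (ranked by
|r|, default 100) are clustered into mutation-linked gene sets on their
z-scored mean expression across genotype × cluster pseudo-groups (Ward
linkage, default 4 sets). Whether to screen per stage or pooled is exposed
(`per_stage`); per-stage is the default reporting convention.

## Reference mapping and signature scoring

`ReferenceMapper` is a weighted-kNN classifier in a shared PCA basis
(default 50 components, 30 neighbours): query cells are projected on the
gene intersection (error below 50% overlap), each query votes over its
reference neighbours with 1/distance weights, and the prediction score is
the winning vote fraction. Cells under the 0.4 score threshold are flagged,
never dropped — the threshold matters only where downstream marker discovery
needs unambiguous mappings. Anchor-based transfer is intentionally not
reproduced: downstream analysis consumes only (label, score), which this
contract provides.

Glasswork layouts place mapped cells uniformly at random inside the concave
hull of their assigned reference cluster in a 2-D layout (rejection
sampling, deterministic under seed), downsampled evenly per condition ×
stage (default 1000). Hulls use shapely's concave hull (`ratio` 0.4) with a
convex-hull fallback whenever the concave hull would cover <95% of the
cluster's points.

Two signature scores are provided. The single-cell **module score** ranks
genes by mean expression into 24 equal-frequency bins and scores each cell
as mean(signature) − mean(bin-matched controls, up to 100 per signature
gene, sampled without replacement); its expectation under exchangeable genes
is 0. The bulk **ssGSEA-type score** integrates, per sample, the difference
between the |rank|^α-weighted in-set ECDF and the uniform out-of-set ECDF
(α = 0.25), and is invariant to per-sample monotone transforms; scores are
normalised by their range across samples (a common convention — the
normalisation is a display choice, not part of the statistic). Refined
signatures are plain intersections of reference and mapped-query markers
(suffix `*`); empty intersections are legitimate and produce a warning, not
an error.

## Pseudobulk differential testing

Counts are summed per replicate × condition × stage group (groups with <10
cells dropped with a warning; column sums are conserved exactly). Size
factors are median-of-ratios; when chromosome arms carry known copy-number
gains they can be excluded from the factor computation so dosage-driven
signal is not mistaken for depth (`size_factors_excluding`). Note the
median-of-ratios estimator is itself robust: exclusion matters once the
aberrant arms carry a sizeable share of the features or the ratio noise is
wide; the verification scenario places 40% of features on the gained arm to
probe exactly that regime.

The per-feature test is a negative-binomial Wald test: method-of-moments
dispersions (pooled within sides) are shrunk in log space toward a fitted
a₀ + a₁/mean trend (trimmed least squares; prior weight 6 pseudo-replicates),
each feature is fit by IRLS with a log link and log size-factor offsets, and
the Wald statistic is referred to a t distribution with residual degrees of
freedom — the plug-in dispersion makes a normal reference anti-conservative
at typical replicate counts (6 vs 6 gave ~7.5% null rejections at the 5%
level with the normal reference, ~5% with the t). The implementation is
validated by calibration and power, not by coefficient equality with any
external tool. BH adjustment is per contrast. Published thresholds are
applied post hoc by `call_significant` (expression mode: p_adj ≤ 0.05,
|log2FC| > 0.25, expressed in ≥20% of cells on one side, computed on raw
counts > 0; accessibility mode: p_adj ≤ 0.005, |log2FC| ≥ log2 1.5; boundary
values on ≤/≥ comparisons count).

Chromatin modules are Ward-linkage clusters of z-scored region profiles;
time-wise and condition-wise significant regions are clustered separately
(defaults 6 + 3) and labels concatenated R1…R9-style. The cut heights are
exposed as parameters: no principled criterion for the module count is
claimed. Overlap enrichment is a one-sided hypergeometric tail with BH
across annotation sets and a Haldane-corrected log2 odds ratio; the default
significance profile is p_adj ≤ 0.005, the stricter motif profile
p_adj ≤ 1e-7 with |log2 odds| ≥ 1.

## Peak-gene links

Coordinates are 1-based inclusive in memory, 0-based half-open in BED files;
distances run from the nearest peak edge to the TSS. Promoter links are
peaks containing a TSS (configurable pad, default 0). Distal candidates are
non-promoter pairs within 250 kb. Candidates are scored by Pearson r between
normalised per-sample accessibility and expression on matched samples (≥4
required). The empirical FDR permutes the RNA sample labels relative to ATAC
(default 10 non-identity permutations; sample-level permutation keeps
within-modality structure intact, the conservative reading of "shuffling the
modality assignment"): FDR(|r₀|) = (null exceedances / #shuffles) /
(observed exceedances), ties inclusive on both counts, clipped to [0, 1] and
forced monotone non-increasing in |r|. Pooling nulls across shuffles and
averaging per-shuffle ratios are algebraically identical here since the
observed exceedance count is shared; both are exposed. Distal links with
FDR ≤ 0.05 are retained; promoter links always are.

## Regulon inference

Cells are subsampled to ≤500 per cluster so abundant states do not dominate;
per subsample, each gene is regressed on all TF expressions (a TF is
excluded from its own feature set) and per-TF importances are extracted,
then averaged over 10 repetitions. The regressor is a pluggable contract
(non-negative importances, deterministic under seed); the default is
gradient-boosted trees (LightGBM, 20 trees, 7 leaves — deliberately small:
with tens of TF features the signal saturates quickly and the extra trees
only cost time). TF-target correlations are averaged over the *same*
subsamples and repetition count as the importances.

Each TF gets its own importance threshold: importances sorted descending,
the top ceil(1%) set aside as outliers, and the single mean-shift
changepoint found by exact minimisation of the two-segment within-SSE (O(n)
with cumulative sums; equivalent to an exhaustive split search, against
which it is tested). The threshold is the importance at the end of the high
segment; trimmed outliers above it remain targets. A constant curve yields
an empty regulon with a warning. Candidate targets without a motif hit for
the TF in a peak linked to the target are discarded as indirect; the rest
split into activated (r > 0.1) and inhibited (r < −0.1), with |r| ≤ 0.1
dropped. Regulon activity per cell is the module score of the activated
targets. Regulon/gene-set enrichment reuses the hypergeometric machinery
and requires p_adj ≤ 0.05, |log2 odds| ≥ 2 and overlap ≥5% of the gene set.

## Synthetic data: what it emulates, and what it does not

`simulate_cells` draws ordered trajectory states on a 1-D latent path
(5 states; per-gene profiles = linear trend + one Gaussian bump), assigns
each cell a state from a stage-centred distribution (3 stages, 3 replicates;
each genotype × stage × replicate run jittered along the path, emulating
batch variability between differentiation experiments) reweighted by
exp(−block_strength · G · t) so mutant genotypes are progressively depleted
from late states. Dosage gains multiply state means on gained arms — default
log2(3/2), a single-copy gain on a diploid background, on chr17q-like and
chr1q-like arms, plus a stronger (+1 log2) oncogene programme in the most
altered genotype. A planted network of 10 TFs × 20 signed targets couples
target log-means to per-cell TF activities (activity N(0,1) i.i.d. per cell,
coupling ±0.8, 70% activating). Counts are negative binomial (dispersion
0.15) with log-normal depth factors (σ 0.25); 500 cells per genotype.

`simulate_peaks` generates per-sample (genotype × stage × replicate) peak
counts: each planted TF target gets a promoter peak and 200 distal peaks are
planted within 250 kb of genes chosen so their noise-free profile is
recoverable from the generated counts at sample resolution — a coupling that
could not be observed even in principle would test nothing about the linking
method. Coupled peaks track the gene's noise-free per-sample mean raised to
an amplification exponent (2.5) at mean depth 100 with low technical
dispersion (0.02); uncoupled peaks are independent noise placed >1 Mb from
any coupled gene on a synthetic genome of per-arm contigs (genes every
100 kb). `simulate_motifs` supports every true TF→target pair with a hit in
a planted peak for the target and adds decoy hits at 0.1× the true-hit count.

Not emulated: doublets, ambient RNA, batch effects on expression (only
composition), read-level noise, sequence content, trans-chromosomal
structure, and cluster-level manual curation. Passing tests therefore show
that each stage recovers the structure it is designed to detect under an
NB count model with honest noise — not that the defaults are optimal for any
particular real dataset.

## Verification scenarios (scripts/acceptance.py)

All metrics are recomputed from scratch per run, seeded from `--seed`:
mutation-score recovery (Spearman between own genotype and m at
block_strength 1.0; exactness of homogeneous-neighbourhood scores);
family-wise calibration of the Bonferroni screen (100 null replicates ×
5,000 genes); shuffle-FDR calibration (100 null replicates, 24 samples,
2,000 candidate pairs, 10 shuffles) and recall of pairs planted at r ≈ 0.9
(20 replicates); differential-test null calibration and power at the
accessibility thresholds (6 vs 6, 2,000 features, 300 planted 4-fold);
exact agreement of the hypergeometric tail, changepoint, kNN and module
score with brute-force oracles; regulon recovery on the planted network
(precision/recall/sign accuracy/AUPR against the random baseline); and
size-factor accuracy under a 2× arm gain + 1.5× depth shift. Problem sizes
match the synthetic study conditions above; the GRN stage is the slowest
(~3–4 minutes for 10 repetitions × 2,000 genes on one core).

## Known limitations

- The NB Wald test is a calibrated surrogate, not a reimplementation of any
  specific differential-expression package; coefficient-level agreement with
  such packages is out of scope by design.
- The changepoint model assumes a single mean shift on the sorted importance
  curve; multi-regime curves will be thresholded at the strongest shift only.
- The empirical FDR needs enough samples for non-trivial permutations; with
  few samples the null is coarse and the FDR quantised.
- Concave hulls can be non-unique for pathological layouts; the convex
  fallback guarantees coverage at the cost of looseness.
- The mapper assumes the query shares the reference's expression scale
  (same normalisation); no cross-platform correction is attempted.
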