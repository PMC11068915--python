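"""Synthetic multi-genotype single-cell data with planted structure.

The generator emulates a panel of engineered stem-cell lines carrying an
ordered ladder of lesions (e.g. WT -> chr17q gain -> chr17q+chr1q gains ->
+MYCN overexpression) profiled along a clustered differentiation trajectory:

* cells occupy ordered trajectory states; mutant genotypes are progressively
  depleted from late states (differentiation block), scaled by
  ``block_strength`` and the genotype's position in the ladder;
* genes on "gained" chromosome arms are dosage up-regulated in carrier
  genotypes (multiplicative log2 fold-changes on the state means);
* a planted TF->target network couples target genes to per-cell TF activity,
  with signed (activating/inhibiting) edges and motif support;
* ATAC-like peak counts are generated per pseudobulk sample
  (genotype x stage x replicate); "coupled" peaks track the expression of a
  nearby gene (within 250 kb of its TSS on a synthetic genome), the rest are
  independent noise placed far from any coupled gene.

Counts follow a negative-binomial model with log-normal per-cell depth
factors. Every planted feature is recorded in :class:`GroundTruth` so each
downstream stage of the pipeline has a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_cells",
    "simulate_peaks",
    "simulate_motifs",
    "simulate_null_pseudobulk",
]

# Synthetic genome: each chromosome arm is its own contig. Genes are spaced
# GENE_SPACING apart; uncoupled peaks are pushed >= UNCOUPLED_OFFSET past the
# last gene so they sit >1 Mb from any coupled gene.
ARMS = ("1p", "1q", "2p", "2q", "3q", "5q", "7q", "8q", "17p", "17q")
GENE_SPACING = 100_000
UNCOUPLED_OFFSET = 5_000_000


def _default_gains() -> dict[str, dict[str, float]]:
    # single-copy gain on a diploid background: log2(3/2); the MYCN-like
    # overexpression programme on 2p is stronger
    g = math.log2(3 / 2)
    return {
        "17q": {"17q": g},
        "17q1q": {"17q": g, "1q": g},
        "17q1qMYCN": {"17q": g, "1q": g, "2p": 1.0},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-genotype experiment.

    Defaults describe four genotypes x 500 cells on a five-state trajectory
    with arm-level dosage gains, a 10-TF planted network and 200 coupled
    peak-gene pairs.
    """

    n_cells_per_genotype: int = 500
    n_genes: int = 2000
    n_peaks: int = 1000
    n_clusters: int = 5
    genotypes: tuple[str, ...] = ("WT", "17q", "17q1q", "17q1qMYCN")
    stages: tuple[str, ...] = ("D9", "D14", "D19")
    n_replicates: int = 3
    gained_arm_genes: dict[str, dict[str, float]] = field(default_factory=_default_gains)
    block_strength: float = 1.0
    n_tfs: int = 10
    targets_per_tf: int = 20
    n_coupled_pairs: int = 200
    noise_dispersion: float = 0.15
    depth_sigma: float = 0.25
    decoy_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cells_per_genotype",
            "n_genes",
            "n_peaks",
            "n_clusters",
            "n_replicates",
            "n_tfs",
            "targets_per_tf",
        ):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n_cells_per_genotype <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells_per_genotype and n_genes must be positive")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2 (need an ordered trajectory)")
        if len(self.genotypes) == 0:
            raise ValueError("genotype list must not be empty")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype labels must be unique")
        for geno, arms in self.gained_arm_genes.items():
            if geno not in self.genotypes:
                raise ValueError(f"gained_arm_genes references unknown genotype {geno!r}")
            for arm, lfc in arms.items():
                if not np.isfinite(lfc):
                    raise ValueError(f"dosage log2 fold-change for {geno}/{arm} must be finite")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must be in [0, 1]")
        if self.block_strength < 0:
            raise ValueError("block_strength must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    cell_state: np.ndarray
    true_tf_targets: dict[str, dict[str, list[str]]]
    peak_gene_pairs: list[tuple[str, str]]  # distal coupled pairs
    dosage_genes: dict[str, list[str]]
    tf_names: list[str]
    tf_activity: np.ndarray  # cells x TFs latent activity
    state_logmeans: np.ndarray  # states x genes (log2 scale, pre-dosage)
    promoter_pairs: list[tuple[str, str]] = field(default_factory=list)

    def signed_targets(self, tf: str) -> dict[str, int]:
        """Map target gene -> +1 (activated) / -1 (inhibited) for one TF."""
        out = {g: 1 for g in self.true_tf_targets[tf]["activated"]}
        out.update({g: -1 for g in self.true_tf_targets[tf]["inhibited"]})
        return out


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _gene_annotation(n_genes: int) -> pd.DataFrame:
    """Lay genes along arm contigs, evenly split, spaced GENE_SPACING apart."""
    per_arm = int(np.ceil(n_genes / len(ARMS)))
    arms = np.repeat(ARMS, per_arm)[:n_genes]
    idx_within = np.concatenate([np.arange((arms == a).sum()) for a in ARMS if (arms == a).any()])
    tss = (idx_within + 1) * GENE_SPACING
    names = [f"G{i:04d}" for i in range(n_genes)]
    chrom = np.array([f"chr{a}" for a in arms])
    return pd.DataFrame({"arm": arms, "chrom": chrom, "tss": tss}, index=names)


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cells x genes count matrix with planted structure.

    Returns
    -------
    cells : AnnData
        Integer counts with per-cell ``obs`` columns ``genotype``, ``stage``,
        ``replicate``, ``cluster`` and per-gene ``var`` columns ``arm``,
        ``chrom``, ``tss``, ``is_tf``.
    truth : GroundTruth
        Planted trajectory states, TF network, and dosage genes.
    """
    rng = np.random.default_rng(config.seed)
    n_geno = len(config.genotypes)
    n_cells = config.n_cells_per_genotype * n_geno
    G = config.n_genes
    C = config.n_clusters

    var = _gene_annotation(G)
    gene_names = np.asarray(var.index)

    # --- per-gene trajectory profiles on a 1-D latent path -----------------
    t_states = np.linspace(0.0, 1.0, C)
    slope = rng.normal(0.0, 0.8, G)
    bump_amp = rng.normal(0.0, 0.8, G) * (rng.random(G) < 0.5)
    bump_pos = rng.random(G)
    base = rng.normal(0.0, 1.0, G)
    # states x genes, log2 scale
    prof = (
        base[None, :]
        + slope[None, :] * t_states[:, None]
        + bump_amp[None, :] * np.exp(-((t_states[:, None] - bump_pos[None, :]) ** 2) / 0.08)
    )

    # --- dosage genes -------------------------------------------------------
    dosage_log2 = np.zeros((n_geno, G))
    dosage_genes: dict[str, list[str]] = {g: [] for g in config.genotypes}
    gained_arms_all: set[str] = set()
    for gi, geno in enumerate(config.genotypes):
        for arm, lfc in config.gained_arm_genes.get(geno, {}).items():
            mask = (var["arm"] == arm).to_numpy()
            dosage_log2[gi, mask] += lfc
            dosage_genes[geno].extend(gene_names[mask])
            gained_arms_all.add(arm)

    # --- planted TF network -------------------------------------------------
    neutral = np.flatnonzero(~var["arm"].isin(gained_arms_all).to_numpy())
    needed = config.n_tfs * (1 + config.targets_per_tf)
    if config.n_tfs > 0 and len(neutral) < needed:
        raise ValueError("not enough genes outside gained arms for the requested TF network")
    picked = rng.choice(neutral, size=needed, replace=False) if config.n_tfs > 0 else np.array([], int)
    tf_idx = picked[: config.n_tfs]
    tgt_idx = picked[config.n_tfs :].reshape(config.n_tfs, -1) if config.n_tfs > 0 else picked
    tf_names = [str(gene_names[i]) for i in tf_idx]

    tf_activity = rng.normal(0.0, 1.0, (n_cells, config.n_tfs))
    coupling = np.zeros((config.n_tfs, G))  # signed log2 effect of activity on targets
    true_tf_targets: dict[str, dict[str, list[str]]] = {}
    for f in range(config.n_tfs):
        signs = np.where(rng.random(config.targets_per_tf) < 0.7, 1.0, -1.0)
        coupling[f, tgt_idx[f]] = 0.8 * signs
        true_tf_targets[tf_names[f]] = {
            "activated": [str(gene_names[i]) for i, s in zip(tgt_idx[f], signs) if s > 0],
            "inhibited": [str(gene_names[i]) for i, s in zip(tgt_idx[f], signs) if s < 0],
        }
    # --- cell metadata and state assignment ---------------------------------
    genotype = np.repeat(config.genotypes, config.n_cells_per_genotype)
    geno_idx = np.repeat(np.arange(n_geno), config.n_cells_per_genotype)
    stage = np.asarray(config.stages)[rng.integers(0, len(config.stages), n_cells)]
    stage_center = dict(zip(config.stages, np.linspace(0.35, 0.95, len(config.stages))))
    replicate = np.array([f"rep{r + 1}" for r in rng.integers(0, config.n_replicates, n_cells)])

    # replicate-level batch variability: each genotype x stage x replicate
    # differentiation run sits at a slightly different point of the path
    group_key = pd.Series([f"{g}|{s}|{r}" for g, s, r in zip(genotype, stage, replicate)])
    jitter_by_group = {k: rng.normal(0.0, 0.08) for k in sorted(group_key.unique())}
    jitter = group_key.map(jitter_by_group).to_numpy()

    centers = np.array([stage_center[s] for s in stage]) + jitter
    logw = (
        -((t_states[None, :] - centers[:, None]) ** 2) / (2 * 0.09)
        - config.block_strength * geno_idx[:, None] * t_states[None, :]
    )
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n_cells)
    cell_state = (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)

    # --- expected counts and sampling ---------------------------------------
    log2mu = prof[cell_state] + dosage_log2[geno_idx]
    if config.n_tfs > 0:
        log2mu += tf_activity @ coupling
        log2mu[:, tf_idx] += 1.0 * tf_activity
    depth = np.exp(rng.normal(0.0, config.depth_sigma, n_cells))
    mu = depth[:, None] * np.exp2(log2mu)
    counts = _nb_sample(rng, mu, config.noise_dispersion).astype(np.int64)

    obs = pd.DataFrame(
        {
            "genotype": pd.Categorical(genotype, categories=list(config.genotypes), ordered=True),
            "stage": pd.Categorical(stage, categories=list(config.stages), ordered=True),
            "replicate": replicate,
            "cluster": pd.Categorical([f"C{s}" for s in cell_state], categories=[f"C{s}" for s in range(C)], ordered=True),
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    var = var.copy()
    var["is_tf"] = False
    var.iloc[tf_idx, var.columns.get_loc("is_tf")] = True

    cells = ad.AnnData(X=counts, obs=obs, var=var)
    truth = GroundTruth(
        cell_state=cell_state,
        true_tf_targets=true_tf_targets,
        peak_gene_pairs=[],
        dosage_genes={g: v for g, v in dosage_genes.items() if v},
        tf_names=tf_names,
        tf_activity=tf_activity,
        state_logmeans=prof,
    )
    return cells, truth


def _sample_table(cells: ad.AnnData) -> pd.DataFrame:
    keys = ["genotype", "stage", "replicate"]
    groups = cells.obs.groupby(keys, observed=True).size().rename("n_cells").reset_index()
    groups.index = [f"{g}_{s}_{r}" for g, s, r in zip(groups["genotype"], groups["stage"], groups["replicate"])]
    return groups


def simulate_peaks(
    config: SimConfig,
    cells: ad.AnnData,
    truth: GroundTruth,
    mean_reads: float = 100.0,
    peak_dispersion: float = 0.02,
    amplification: float = 2.5,
) -> ad.AnnData:
    """Generate per-sample accessibility counts for a synthetic peak set.

    Samples are genotype x stage x replicate pseudobulks. For each planted
    peak-gene pair the peak's expected accessibility is proportional to the
    mean (noise-free) expression of its gene among the sample's cells;
    promoter peaks for planted TF targets behave the same. All remaining
    peaks are independent negative-binomial noise located >1 Mb from any
    coupled gene. Updates ``truth.peak_gene_pairs`` in place.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = _sample_table(cells)
    n_samples = len(samples)
    gene_names = np.asarray(cells.var_names)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}

    # promoter peaks for every planted TF target (guarantees motif support)
    target_genes: list[str] = []
    for tf in truth.tf_names:
        for key in ("activated", "inhibited"):
            target_genes.extend(truth.true_tf_targets[tf][key])
    target_genes = sorted(set(target_genes))

    # noise-free per-sample mean expression per gene
    prof_cells = np.exp2(truth.state_logmeans[truth.cell_state])
    group_ids = pd.MultiIndex.from_frame(cells.obs[["genotype", "stage", "replicate"]].astype(str))
    sample_keys = [f"{g}_{s}_{r}" for g, s, r in group_ids]
    sk = pd.Series(sample_keys, index=cells.obs_names)
    sample_mean = np.vstack([prof_cells[(sk == s).to_numpy()].mean(axis=0) for s in samples.index])

    # distal coupled peaks are planted on genes whose expression readout is
    # reliably measurable at sample resolution: the noise-free profile must be
    # recoverable from the generated counts (otherwise the planted coupling
    # would be unobservable by construction, not by method failure)
    counts_log = np.log1p(np.asarray(cells.X, dtype=float))
    rna_proxy = np.vstack([counts_log[(sk == s).to_numpy()].mean(axis=0) for s in samples.index])
    with np.errstate(invalid="ignore"):
        za = (rna_proxy - rna_proxy.mean(axis=0)) / rna_proxy.std(axis=0)
        lm = np.log(sample_mean)
        zb = (lm - lm.mean(axis=0)) / lm.std(axis=0)
        readout_r = np.nanmean(za * zb, axis=0)
    readout_r[~np.isfinite(readout_r)] = -np.inf
    order = np.argsort(-readout_r, kind="stable")
    distal_genes = [str(gene_names[i]) for i in order[: config.n_coupled_pairs]]

    n_planted = len(target_genes) + len(distal_genes)
    if config.n_peaks < n_planted:
        raise ValueError(
            f"n_peaks={config.n_peaks} is smaller than the number of planted pairs ({n_planted})"
        )

    peak_rows = []
    mu = np.zeros((n_samples, config.n_peaks))
    pairs: list[tuple[str, str]] = []
    promoter_pairs: list[tuple[str, str]] = []
    width = 500
    k = 0
    var_df = cells.var

    def _coupled_mu(gi: int) -> np.ndarray:
        prof = sample_mean[:, gi]
        rel = (prof / prof.mean()) ** amplification
        return mean_reads * rel / rel.mean()

    for g in target_genes:  # promoter peaks (motif support for TF targets)
        gi = name_to_idx[g]
        tss = int(var_df["tss"].iloc[gi])
        start = max(1, tss - width // 2)
        peak_rows.append((f"peak_{k:05d}", var_df["chrom"].iloc[gi], var_df["arm"].iloc[gi], start, start + width))
        mu[:, k] = _coupled_mu(gi)
        promoter_pairs.append((f"peak_{k:05d}", g))
        k += 1
    for g in distal_genes:  # distal coupled peaks within 250 kb
        gi = name_to_idx[g]
        tss = int(var_df["tss"].iloc[gi])
        off = int(rng.integers(5_000, 200_000)) * int(rng.choice([-1, 1]))
        start = max(1, tss + off)
        peak_rows.append((f"peak_{k:05d}", var_df["chrom"].iloc[gi], var_df["arm"].iloc[gi], start, start + width))
        mu[:, k] = _coupled_mu(gi)
        pairs.append((f"peak_{k:05d}", g))
        k += 1
    # uncoupled peaks: far past the last gene on a rotating arm
    arm_last = {a: (var_df["arm"] == a).sum() * GENE_SPACING for a in ARMS}
    j = 0
    while k < config.n_peaks:
        arm = ARMS[j % len(ARMS)]
        start = arm_last[arm] + UNCOUPLED_OFFSET + (j // len(ARMS)) * 10_000
        peak_rows.append((f"peak_{k:05d}", f"chr{arm}", arm, start, start + width))
        mu[:, k] = mean_reads
        k += 1
        j += 1

    depth = np.exp(rng.normal(0.0, config.depth_sigma, n_samples))
    counts = _nb_sample(rng, depth[:, None] * mu, peak_dispersion).astype(np.int64)

    var_peaks = pd.DataFrame(
        peak_rows, columns=["peak_id", "chrom", "arm", "start", "end"]
    ).set_index("peak_id")
    peaks = ad.AnnData(X=counts, obs=samples, var=var_peaks)
    truth.peak_gene_pairs = pairs
    truth.promoter_pairs = promoter_pairs
    return peaks


def simulate_motifs(
    config: SimConfig, truth: GroundTruth, peaks: ad.AnnData, decoy_rate: float | None = None
) -> pd.DataFrame:
    """Motif-hit table (TF, peak) supporting every planted TF->target pair.

    Each true pair gets a hit in a peak planted for the target gene; decoy
    hits in random other peaks are added at ``decoy_rate`` x the number of
    true hits.
    """
    rate = config.decoy_rate if decoy_rate is None else decoy_rate
    if not 0.0 <= rate <= 1.0:
        raise ValueError("decoy rate must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 2)
    gene_to_peaks: dict[str, list[str]] = {}
    for p, g in truth.promoter_pairs + truth.peak_gene_pairs:
        gene_to_peaks.setdefault(g, []).append(p)
    rows = []
    for tf in truth.tf_names:
        for key in ("activated", "inhibited"):
            for g in truth.true_tf_targets[tf][key]:
                if g not in gene_to_peaks:
                    raise ValueError(f"planted target {g} has no peak; run simulate_peaks first")
                rows.append((tf, gene_to_peaks[g][0]))
    n_decoys = int(round(rate * len(rows)))
    if n_decoys and truth.tf_names:
        true_set = set(rows)
        peak_ids = np.asarray(peaks.var_names)
        while n_decoys > 0:
            tf = truth.tf_names[int(rng.integers(len(truth.tf_names)))]
            pk = str(peak_ids[int(rng.integers(len(peak_ids)))])
            if (tf, pk) not in true_set:
                rows.append((tf, pk))
                true_set.add((tf, pk))
                n_decoys -= 1
    return pd.DataFrame(rows, columns=["tf", "peak_id"])


def simulate_null_pseudobulk(
    n_per_side: int = 6,
    n_features: int = 2000,
    n_planted: int = 0,
    fold: float = 4.0,
    mean_log: float = 5.0,
    mean_sd: float = 1.0,
    depth_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ad.AnnData, np.ndarray]:
    """Two-group pseudobulk counts for calibration and power studies.

    Feature means are log-normal (typical pseudobulk depth), dispersions
    uniform in [0.05, 0.2], per-sample depth factors log-normal. With
    ``n_planted`` > 0, that many features get a ``fold``-change on side B.
    Returns the AnnData (obs column ``condition`` in {A, B}) and the planted
    feature indices.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_side
    mean = np.exp(rng.normal(mean_log, mean_sd, n_features))
    disp = 0.05 + 0.15 * rng.random(n_features)
    sf = np.exp(rng.normal(0.0, depth_sd, n))
    mu = sf[:, None] * mean[None, :]
    planted = rng.choice(n_features, n_planted, replace=False) if n_planted else np.array([], int)
    mu[n_per_side:, planted] *= fold
    counts = rng.poisson(rng.gamma(1.0 / disp[None, :], mu * disp[None, :]))
    obs = pd.DataFrame(
        {"condition": ["A"] * n_per_side + ["B"] * n_per_side},
        index=[f"s{i:02d}" for i in range(n)],
    )
    var = pd.DataFrame(index=[f"f{j:05d}" for j in range(n_features)])
    return ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var), planted
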