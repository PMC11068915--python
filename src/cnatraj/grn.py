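"""Transcription-factor regulon construction.

For each gene, a feature-importance regressor (pluggable; default
gradient-boosted trees) predicts its expression from the expression of all
TFs. To avoid over-representing abundant cell states, cells are first
subsampled to at most 500 per cluster; importances are averaged over
repeated subsamples (default 10). Each TF then gets its own importance
threshold via a single mean-shift changepoint on the descending importance
curve (ignoring the top 1% of values, which are often outliers). Putative
targets without a motif hit for the TF in a peak linked to the target are
discarded as indirect, and the survivors are split into activated
(r > 0.1) and inhibited (r < -0.1) targets by the sign of the TF-target
Pearson correlation averaged over the same subsamples; |r| <= 0.1 edges are
dropped. Regulon activity per cell is the module score of the activated
targets, and regulons are tested for overlap with mutation-linked gene sets
by a hypergeometric test (significant: p_adj <= 0.05, |log2 odds| >= 2,
overlap >= 5% of the gene set).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator

from .differential import hypergeom_enrich
from .mapping import GeneSignature, module_score

__all__ = [
    "Regulon",
    "balanced_subsample",
    "importance_matrix",
    "changepoint_threshold",
    "derive_gene_support",
    "build_regulons",
    "regulon_score",
    "regulon_enrichment",
    "network_export",
    "GRNInference",
]


@dataclass
class Regulon:
    """A TF with signed target sets and the threshold that produced them."""

    tf: str
    activated: list[str] = field(default_factory=list)
    inhibited: list[str] = field(default_factory=list)
    threshold: float | None = None

    def __post_init__(self) -> None:
        if set(self.activated) & set(self.inhibited):
            raise ValueError(f"regulon {self.tf}: activated and inhibited sets overlap")

    @property
    def targets(self) -> list[str]:
        return list(self.activated) + list(self.inhibited)


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X, dtype=float)


def balanced_subsample(clusters, max_per_cluster: int = 500, seed: int = 0) -> np.ndarray:
    """Sorted cell indices with at most ``max_per_cluster`` per cluster."""
    labels = pd.Series(clusters).astype(str)
    if labels.isna().any():
        raise ValueError("cluster labels contain missing values")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _, idx in labels.groupby(labels, observed=True).groups.items():
        pos = np.flatnonzero(labels.index.isin(idx))
        if len(pos) > max_per_cluster:
            pos = rng.choice(pos, size=max_per_cluster, replace=False)
        keep.append(pos)
    return np.sort(np.concatenate(keep))


def _default_regressor(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Gradient-boosted tree gain importances (lightgbm)."""
    import lightgbm as lgb

    model = lgb.LGBMRegressor(
        n_estimators=20,
        num_leaves=7,
        max_depth=5,
        learning_rate=0.1,
        min_child_samples=10,
        subsample=0.9,
        subsample_freq=1,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )
    model.fit(X, y)
    return model.booster_.feature_importance(importance_type="gain").astype(float)


def importance_matrix(
    norm,
    tf_names: list[str],
    clusters,
    n_reps: int = 10,
    max_per_cluster: int = 500,
    regressor: Callable[[np.ndarray, np.ndarray, int], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean TF x gene importances and correlations over repeated subsamples.

    Per repetition, cells are balanced-subsampled, each gene is regressed on
    the TF expression matrix (the gene itself excluded from its own feature
    set when it is a TF), and per-TF importances are extracted. Importances
    and TF-target Pearson correlations are averaged across repetitions.

    Returns (importances, correlations), both TF x gene DataFrames.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(norm, ad.AnnData):
        X = _dense(norm.X)
        genes = list(norm.var_names)
    else:
        X = norm.to_numpy(dtype=float)
        genes = list(norm.columns)
    gene_pos = {g: i for i, g in enumerate(genes)}
    missing = [t for t in tf_names if t not in gene_pos]
    if missing:
        raise ValueError(f"TFs absent from the matrix: {missing[:5]}")
    reg = regressor or _default_regressor
    tf_idx = np.array([gene_pos[t] for t in tf_names])
    T, G = len(tf_names), len(genes)
    imp_sum = np.zeros((T, G))
    corr_sum = np.zeros((T, G))
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sub = balanced_subsample(clusters, max_per_cluster, seed=rep_seed)
        Xs = X[sub]
        Xtf = Xs[:, tf_idx]
        # correlations in one shot
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0, ddof=1)
        sd_safe = np.where(sd == 0, 1.0, sd)
        Z = (Xs - mu) / sd_safe
        Ztf = Z[:, tf_idx]
        C = (Ztf.T @ Z) / (len(sub) - 1)
        C[:, sd == 0] = 0.0
        C[sd[tf_idx] == 0, :] = 0.0
        corr_sum += np.clip(C, -1, 1)
        for j in range(G):
            y = Xs[:, j]
            if j in tf_idx:
                cols = tf_idx != j
                if not cols.any():
                    continue
                imp = np.zeros(T)
                imp[cols] = reg(Xtf[:, cols], y, rep_seed + j)
            else:
                imp = reg(Xtf, y, rep_seed + j)
            if np.any(imp < 0):
                raise ValueError("regressor returned negative importances")
            imp_sum[:, j] += imp
    imp = pd.DataFrame(imp_sum / n_reps, index=tf_names, columns=genes)
    corr = pd.DataFrame(corr_sum / n_reps, index=tf_names, columns=genes)
    return imp, corr


def changepoint_threshold(importances: np.ndarray, trim_frac: float = 0.01, min_candidates: int = 20):
    """TF-specific importance threshold via a single mean-shift changepoint.

    Values are sorted descending; the top ``ceil(trim_frac * n)`` are set
    aside as outliers; the remaining curve is split at the index minimising
    the pooled two-segment within-SSE (equivalently maximising the
    two-segment Gaussian likelihood). The threshold is the importance at the
    end of the first (high) segment. Returns None (with a warning) when the
    trimmed curve is constant.
    """
    vals = np.asarray(importances, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_candidates:
        raise ValueError(f"need >= {min_candidates} candidate importances, got {len(vals)}")
    s = np.sort(vals)[::-1]
    n_drop = math.ceil(trim_frac * len(s))
    seq = s[n_drop:]
    if len(seq) < 2 or np.allclose(seq, seq[0]):
        warnings.warn("importance curve has no changepoint (constant values)", stacklevel=2)
        return None
    n = len(seq)
    csum = np.cumsum(seq)
    csq = np.cumsum(seq**2)
    k = np.arange(1, n)  # first segment length
    sse1 = csq[k - 1] - csum[k - 1] ** 2 / k
    tail_sum = csum[-1] - csum[k - 1]
    tail_sq = csq[-1] - csq[k - 1]
    sse2 = tail_sq - tail_sum**2 / (n - k)
    best = int(k[np.argmin(sse1 + sse2)])
    return float(seq[best - 1])


def derive_gene_support(motif_hits: pd.DataFrame, links: pd.DataFrame) -> dict[str, set]:
    """TF -> set of genes supported by a motif hit in a linked peak."""
    peak_genes = links.groupby("peak_id")["gene"].agg(set)
    support: dict[str, set] = {}
    for tf, pk in zip(motif_hits["tf"], motif_hits["peak_id"]):
        if pk in peak_genes.index:
            support.setdefault(tf, set()).update(peak_genes[pk])
        else:
            support.setdefault(tf, set())
    return support


def build_regulons(
    importances: pd.DataFrame,
    correlations: pd.DataFrame,
    gene_support: dict[str, set],
    r_min: float = 0.1,
    trim_frac: float = 0.01,
) -> list[Regulon]:
    """Threshold, motif-filter, and sign-split importances into regulons.

    Per TF: the changepoint threshold selects candidate targets; targets
    lacking motif support in a linked peak are discarded as indirect; the
    rest are split by the sign of the mean correlation at +-``r_min``
    (|r| <= r_min discarded). TFs absent from the motif table yield an
    empty regulon with a warning.
    """
    regulons = []
    for tf in importances.index:
        row = importances.loc[tf].drop(labels=[tf], errors="ignore")
        if tf not in gene_support:
            warnings.warn(f"TF {tf!r} has no motif support; empty regulon", stacklevel=2)
            regulons.append(Regulon(tf=tf))
            continue
        thr = changepoint_threshold(row.to_numpy(), trim_frac=trim_frac)
        if thr is None:
            regulons.append(Regulon(tf=tf))
            continue
        cands = row.index[row.to_numpy() >= thr]
        supported = [g for g in cands if g in gene_support[tf]]
        act, inh = [], []
        for g in supported:
            r = correlations.loc[tf, g]
            if r > r_min:
                act.append(g)
            elif r < -r_min:
                inh.append(g)
        regulons.append(Regulon(tf=tf, activated=act, inhibited=inh, threshold=thr))
    return regulons


def regulon_score(norm, regulon: Regulon, **module_score_kwargs) -> np.ndarray:
    """Per-cell regulon activity: module score of the activated targets."""
    if not regulon.activated:
        raise ValueError(f"regulon {regulon.tf} has no activated targets")
    sig = GeneSignature(name=f"{regulon.tf}_targets", genes=list(regulon.activated))
    return module_score(norm, sig, **module_score_kwargs)


def regulon_enrichment(
    regulons: list[Regulon],
    gene_sets: dict[str, list[str]],
    background,
    p_adj_max: float = 0.05,
    min_abs_log2_odds: float = 2.0,
    min_frequency: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overlap of activated targets with each gene set.

    Significance requires p_adj <= 0.05, |log2 odds| >= log2(4), and an
    overlap covering >= 5% of the gene set (frequency rule).
    """
    bg = set(background)
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
    frames = []
    for reg in regulons:
        query = set(reg.activated) & bg
        if not query:
            continue
        tab = hypergeom_enrich(query, {k: set(v) & bg for k, v in gene_sets.items()}, bg)
        tab = tab.reset_index().rename(columns={"set": "gene_set"})
        tab.insert(0, "tf", reg.tf)
        tab["frequency"] = tab["overlap"] / tab["set_size"]
        tab["significant"] = (
            (tab["p_adj"] <= p_adj_max)
            & (tab["log2_odds"].abs() >= min_abs_log2_odds)
            & (tab["frequency"] >= min_frequency)
        )
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["tf", "gene_set", "overlap", "set_size", "p", "log2_odds", "p_adj", "frequency", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def network_export(
    regulons: list[Regulon],
    correlations: pd.DataFrame | None = None,
    condition_stats: pd.DataFrame | None = None,
    outdir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the TF->target network.

    Nodes carry is_tf plus any per-condition summary statistics passed in
    ``condition_stats`` (indexed by gene). Edge count equals the sum of
    regulon target-set sizes. If ``outdir`` is given, writes
    ``network_nodes.tsv`` and ``network_edges.tsv``.
    """
    edges = []
    for reg in regulons:
        for g in reg.activated:
            r = float(correlations.loc[reg.tf, g]) if correlations is not None else np.nan
            edges.append((reg.tf, g, "+", r))
        for g in reg.inhibited:
            r = float(correlations.loc[reg.tf, g]) if correlations is not None else np.nan
            edges.append((reg.tf, g, "-", r))
    edge_df = pd.DataFrame(edges, columns=["tf", "target", "sign", "r"])
    tf_set = {r.tf for r in regulons}
    node_ids = sorted(tf_set | set(edge_df["target"]))
    node_df = pd.DataFrame({"node": node_ids, "is_tf": [n in tf_set for n in node_ids]}).set_index("node")
    if condition_stats is not None:
        node_df = node_df.join(condition_stats, how="left")
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        node_df.to_csv(out / "network_nodes.tsv", sep="\t")
        edge_df.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    return node_df, edge_df


class GRNInference(BaseEstimator):
    """Regulon inference as a sklearn-style estimator.

    ``fit(X, y=None, *, tf_names, clusters, gene_support)`` runs the full
    pipeline on a normalised matrix (AnnData or DataFrame with gene
    columns). Fitted attributes: ``importances_``, ``correlations_``,
    ``regulons_``, ``thresholds_``.
    """

    def __init__(
        self,
        n_reps: int = 10,
        max_per_cluster: int = 500,
        r_min: float = 0.1,
        trim_frac: float = 0.01,
        regressor: Callable | None = None,
        random_state: int = 0,
    ):
        self.n_reps = n_reps
        self.max_per_cluster = max_per_cluster
        self.r_min = r_min
        self.trim_frac = trim_frac
        self.regressor = regressor
        self.random_state = random_state

    def fit(self, X, y=None, *, tf_names: list[str], clusters, gene_support: dict[str, set]):
        imp, corr = importance_matrix(
            X,
            tf_names,
            clusters,
            n_reps=self.n_reps,
            max_per_cluster=self.max_per_cluster,
            regressor=self.regressor,
            seed=self.random_state,
        )
        self.importances_ = imp
        self.correlations_ = corr
        self.regulons_ = build_regulons(imp, corr, gene_support, r_min=self.r_min, trim_frac=self.trim_frac)
        self.thresholds_ = {r.tf: r.threshold for r in self.regulons_}
        return self


def compare_networks(
    regulons: list[Regulon], true_targets: dict[str, dict[str, list[str]]]
) -> dict[str, float]:
    """Edge-level precision/recall and sign accuracy against a reference.

    ``true_targets`` maps TF -> {"activated": [...], "inhibited": [...]}.
    Sign accuracy is computed over recovered true edges only.
    """
    truth_sign: dict[tuple[str, str], int] = {}
    for tf, d in true_targets.items():
        for g in d.get("activated", []):
            truth_sign[(tf, g)] = 1
        for g in d.get("inhibited", []):
            truth_sign[(tf, g)] = -1
    pred_sign: dict[tuple[str, str], int] = {}
    for reg in regulons:
        for g in reg.activated:
            pred_sign[(reg.tf, g)] = 1
        for g in reg.inhibited:
            pred_sign[(reg.tf, g)] = -1
    pred = set(pred_sign)
    true = set(truth_sign)
    tp = pred & true
    precision = len(tp) / len(pred) if pred else 0.0
    recall = len(tp) / len(true) if true else 0.0
    sign_acc = float(np.mean([pred_sign[e] == truth_sign[e] for e in tp])) if tp else 0.0
    return {"precision": precision, "recall": recall, "sign_accuracy": sign_acc,
            "n_pred": len(pred), "n_true": len(true)}


def importance_aupr(
    importances: pd.DataFrame, true_targets: dict[str, dict[str, list[str]]]
) -> dict[str, float]:
    """Area under precision-recall of mean importances vs the true edge set.

    The random baseline is the positive-edge fraction; the ratio AUPR /
    baseline measures ranking skill independent of network density.
    """
    from sklearn.metrics import average_precision_score

    true = set()
    for tf, d in true_targets.items():
        true.update((tf, g) for g in d.get("activated", []))
        true.update((tf, g) for g in d.get("inhibited", []))
    y, s = [], []
    for tf in importances.index:
        row = importances.loc[tf]
        for g, v in row.items():
            if g == tf:
                continue
            y.append((tf, g) in true)
            s.append(float(v))
    baseline = float(np.mean(y))
    aupr = float(average_precision_score(y, s))
    return {"aupr": aupr, "baseline": baseline, "ratio": aupr / baseline if baseline else np.inf}
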