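"""Per-cell genotype-mixing ("mutation") score and downstream gene screens.

Each cell's genotype is encoded as an integer G following the engineering
lineage of the cell lines (WT=0 ... most-altered=max). The mutation score of
a cell is the mean G of its K nearest transcriptomic neighbours divided by
max(G), a number in [0, 1] measuring how phenotypically close the cell's
neighbourhood is to the mutant end of the ladder -- independent of the
cell's own genotype. The neighbourhood entropy (Shannon, base 2) measures
genotype mixing. Genes are screened genome-wide for Pearson correlation with
the score (or entropy) under Bonferroni control, and the top hits are
clustered into mutation-linked gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

from .preprocess import NeighborGraph, embed, knn_graph

__all__ = [
    "GenotypeEncoding",
    "encode_genotypes",
    "mutation_score",
    "correlate_genes",
    "extract_gene_sets",
    "MutationScorer",
    "MutationGeneSets",
]


@dataclass
class GenotypeEncoding:
    """Bijective genotype label -> consecutive integer G starting at 0."""

    mapping: dict[str, int]
    max_g: int

    def encode(self, labels) -> np.ndarray:
        return np.array([self.mapping[str(l)] for l in labels], dtype=np.int64)


def encode_genotypes(genotypes, ordering: list[str]) -> GenotypeEncoding:
    """Encode genotype labels by their position in ``ordering``.

    ``genotypes`` may be an AnnData (uses ``obs['genotype']``) or a sequence
    of labels. Unknown labels raise, listing the offenders.
    """
    if isinstance(genotypes, ad.AnnData):
        labels = genotypes.obs["genotype"].astype(str)
    else:
        labels = pd.Series(genotypes).astype(str)
    ordering = [str(o) for o in ordering]
    if len(set(ordering)) != len(ordering):
        raise ValueError("ordering contains duplicate labels")
    unknown = sorted(set(labels) - set(ordering))
    if unknown:
        raise ValueError(f"genotype labels not in ordering: {unknown}")
    mapping = {g: i for i, g in enumerate(ordering)}
    return GenotypeEncoding(mapping=mapping, max_g=len(ordering) - 1)


def mutation_score(
    graph: NeighborGraph, genotypes, encoding: GenotypeEncoding
) -> pd.DataFrame:
    """Mutation score m in [0,1] and neighbourhood entropy (bits) per cell.

    m(cell) = mean(G of the K neighbours) / max(G); entropy is the Shannon
    entropy (base 2) of the neighbour genotype distribution.
    """
    if encoding.max_g == 0:
        raise ValueError("mutation score undefined for a single-genotype dataset (max G = 0)")
    if isinstance(genotypes, ad.AnnData):
        index = list(genotypes.obs_names)
        labels = genotypes.obs["genotype"]
    else:
        labels = pd.Series(genotypes)
        index = list(labels.index)
    g = encoding.encode(labels)
    if len(g) != graph.neighbor_indices.shape[0]:
        raise ValueError("graph and genotype vector cover different numbers of cells")
    neigh_g = g[graph.neighbor_indices]  # cells x K
    m = neigh_g.mean(axis=1) / encoding.max_g
    n_levels = encoding.max_g + 1
    counts = np.stack([(neigh_g == lvl).sum(axis=1) for lvl in range(n_levels)], axis=1)
    p = counts / graph.K
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    return pd.DataFrame({"m": m, "entropy": ent, "K": graph.K}, index=index)


def _pearson_screen(X: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Pearson r and two-sided p of each column of X vs target."""
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    tc = target - target.mean()
    sx = xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    zero_var = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * tc[:, None]).sum(axis=0) / ((n - 1) * sx * st)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    p[~np.isfinite(t)] = 0.0
    return r, p, zero_var


def correlate_genes(
    norm: ad.AnnData,
    scores: pd.DataFrame,
    setting: str = "all_cells",
    encoding: GenotypeEncoding | None = None,
    per_stage: bool = False,
) -> pd.DataFrame:
    """Genome-wide Pearson screen of expression against the mutation score.

    Settings: ``all_cells`` (r of each gene vs m), ``exclude_top_genotype``
    (same, dropping cells of the highest-G genotype to expose subtler
    dosage-linked correlations), ``entropy`` (r vs neighbourhood entropy).
    Two-sided p-values are Bonferroni-corrected over the tested genes;
    zero-variance genes are excluded with a recorded reason. With
    ``per_stage=True`` the screen runs within each ``obs['stage']`` level.
    """
    if setting not in {"all_cells", "exclude_top_genotype", "entropy"}:
        raise ValueError(f"unknown setting {setting!r}")
    X = norm.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)

    target = scores["entropy"].to_numpy() if setting == "entropy" else scores["m"].to_numpy()
    keep = np.ones(X.shape[0], dtype=bool)
    if setting == "exclude_top_genotype":
        if encoding is None:
            raise ValueError("setting 'exclude_top_genotype' requires the genotype encoding")
        g = encoding.encode(norm.obs["genotype"])
        keep = g < encoding.max_g
        if not keep.any():
            raise ValueError("excluding the top genotype removed all cells")

    def _screen(mask: np.ndarray, stage) -> pd.DataFrame:
        if mask.sum() < 3:
            raise ValueError("fewer than 3 cells after filtering")
        r, p, zero_var = _pearson_screen(X[mask], target[mask])
        tested = ~zero_var
        m_tests = int(tested.sum())
        p_bonf = np.minimum(1.0, p * m_tests)
        out = pd.DataFrame(
            {
                "gene": list(norm.var_names),
                "r": np.where(tested, r, np.nan),
                "p": np.where(tested, p, np.nan),
                "p_bonferroni": np.where(tested, p_bonf, np.nan),
                "setting": setting,
                "excluded_reason": np.where(tested, None, "zero variance"),
            }
        )
        out["stage"] = stage
        return out

    if not per_stage:
        return _screen(keep, "all").reset_index(drop=True)
    frames = []
    for stage in norm.obs["stage"].cat.categories if hasattr(norm.obs["stage"], "cat") else sorted(norm.obs["stage"].unique()):
        mask = keep & (norm.obs["stage"] == stage).to_numpy()
        frames.append(_screen(mask, stage))
    return pd.concat(frames, ignore_index=True)


@dataclass
class MutationGeneSets:
    """Named mutation-linked gene sets plus the correlation table behind them."""

    sets: dict[str, list[str]]
    correlation_table: pd.DataFrame


def extract_gene_sets(
    correlation_table: pd.DataFrame,
    norm: ad.AnnData,
    top_n: int = 100,
    n_sets: int = 4,
    alpha: float = 0.05,
    group_keys: tuple[str, str] = ("genotype", "cluster"),
) -> MutationGeneSets:
    """Cluster top Bonferroni-significant genes into mutation-linked sets.

    Significant genes (p_bonferroni <= alpha) are ranked by |r|; the top
    ``top_n`` are clustered on their z-scored mean expression profile across
    genotype x cluster pseudo-groups (Ward linkage, cut at ``n_sets``).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    tab = correlation_table.dropna(subset=["p_bonferroni"])
    if tab["gene"].duplicated().any():
        raise ValueError("duplicate genes in correlation table; screen one setting/stage at a time")
    sig = tab[tab["p_bonferroni"] <= alpha].copy()
    if len(sig) < n_sets:
        raise ValueError(f"only {len(sig)} significant genes; need at least n_sets={n_sets}")
    sig = sig.reindex(sig["r"].abs().sort_values(ascending=False).index).head(top_n)
    genes = list(sig["gene"])

    X = norm[:, genes].X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    groups = norm.obs[list(group_keys)].astype(str).agg("|".join, axis=1)
    prof = pd.DataFrame(X, index=norm.obs_names, columns=genes).groupby(groups, observed=True).mean()
    z = prof.to_numpy().T  # genes x groups
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=1, keepdims=True)) / sd
    if n_sets == 1:
        labels = np.ones(len(genes), dtype=int)
    else:
        labels = fcluster(linkage(z, method="ward"), t=n_sets, criterion="maxclust")
    sets = {}
    for k in range(1, int(labels.max()) + 1):
        members = [g for g, l in zip(genes, labels) if l == k]
        if members:
            sets[f"M{k}"] = members
    sig = sig.assign(gene_set=[f"M{l}" for l in labels])
    return MutationGeneSets(sets=sets, correlation_table=sig.reset_index(drop=True))


class MutationScorer(BaseEstimator):
    """Genotype-mixing score as a sklearn-style estimator.

    fit(X, y) embeds the normalised matrix X (PCA, ``n_components``), builds
    the exact kNN graph (``k`` neighbours, Euclidean) and scores each cell
    against the genotype labels y ordered by ``genotype_order``.

    Attributes (after fit): ``scores_`` (DataFrame with m/entropy),
    ``encoding_``, ``graph_``, ``embedding_``.
    """

    def __init__(self, k: int = 30, n_components: int = 10, genotype_order: list[str] | None = None):
        self.k = k
        self.n_components = n_components
        self.genotype_order = genotype_order

    def fit(self, X, y):
        if isinstance(X, ad.AnnData):
            labels = X.obs["genotype"] if y is None else pd.Series(y)
            mat = X
        else:
            mat = np.asarray(X, dtype=float)
            labels = pd.Series(y)
        order = self.genotype_order
        if order is None:
            order = list(pd.unique(labels.astype(str)))
            warnings.warn("genotype_order not given; using order of appearance", stacklevel=2)
        self.encoding_ = encode_genotypes(labels, order)
        self.embedding_ = embed(mat, d=self.n_components)
        self.graph_ = knn_graph(self.embedding_, K=self.k)
        self.scores_ = mutation_score(self.graph_, labels, self.encoding_)
        return self

    def fit_transform(self, X, y) -> np.ndarray:
        """Fit and return the per-cell (m, entropy) array."""
        self.fit(X, y)
        return self.scores_[["m", "entropy"]].to_numpy()
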