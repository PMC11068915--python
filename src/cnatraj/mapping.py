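"""Reference mapping, glasswork layouts, and gene-signature scoring.

``ReferenceMapper`` transfers cluster labels from a reference dataset onto
query cells by projecting both into a shared PCA basis and taking a
distance-weighted vote over the K nearest reference neighbours; the winning
vote fraction is the prediction score in [0, 1]. Glasswork plots place
mapped cells at random positions inside the concave hull of their assigned
reference cluster in a 2-D layout.

Signature scoring comes in two flavours: a single-cell module score (mean
signature expression minus the mean of expression-bin-matched control
genes) and a bulk single-sample rank-weighted enrichment score (ssGSEA-type
running-sum statistic, alpha = 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA

__all__ = [
    "GeneSignature",
    "ReferenceMapper",
    "map_cells",
    "build_cluster_hulls",
    "glasswork_coordinates",
    "module_score",
    "ssgsea_score",
    "refine_signature",
]


@dataclass
class GeneSignature:
    """A named, non-empty gene list with optional direction."""

    name: str
    genes: list[str]
    direction: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            # empty signatures can arise from intersection refinement; warn
            warnings.warn(f"signature {self.name!r} is empty", stacklevel=3)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")


def _matrix_and_genes(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, ad.AnnData):
        X = data.X
        genes = list(data.var_names)
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy()
        genes = list(data.columns)
    else:
        raise TypeError("expected AnnData or DataFrame with named gene columns")
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    return np.asarray(X, dtype=float), genes


class ReferenceMapper(BaseEstimator, ClassifierMixin):
    """Weighted-kNN label transfer in a shared PCA embedding.

    Parameters
    ----------
    n_components : dimensionality of the shared PCA basis (default 50).
    n_neighbors : reference neighbours per query cell (default 30).
    min_gene_overlap : minimum fraction of reference genes the query must
        share (default 0.5); below this, mapping errors out.
    score_threshold : prediction-score cutoff used to flag ambiguous cells
        (flagged, never dropped; default 0.4).
    """

    def __init__(
        self,
        n_components: int = 50,
        n_neighbors: int = 30,
        min_gene_overlap: float = 0.5,
        score_threshold: float = 0.4,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.min_gene_overlap = min_gene_overlap
        self.score_threshold = score_threshold

    def fit(self, X, y):
        """Store the reference matrix (cells x named genes) and labels."""
        Xm, genes = _matrix_and_genes(X)
        y = np.asarray(pd.Series(y).astype(str))
        if len(y) != Xm.shape[0]:
            raise ValueError("labels do not match reference cells")
        if self.n_neighbors > Xm.shape[0]:
            raise ValueError("n_neighbors exceeds reference size")
        self.genes_ = genes
        self.X_ref_ = Xm
        self.labels_ = y
        self.classes_ = np.unique(y)
        return self

    def _shared_projection(self, query_genes: list[str]):
        shared = [g for g in self.genes_ if g in set(query_genes)]
        if len(shared) == 0:
            raise ValueError("no genes shared between query and reference")
        if len(shared) / len(self.genes_) < self.min_gene_overlap:
            raise ValueError(
                f"query shares only {len(shared)}/{len(self.genes_)} reference genes "
                f"(< {self.min_gene_overlap:.0%})"
            )
        ref_cols = [self.genes_.index(g) for g in shared]
        Xr = self.X_ref_[:, ref_cols]
        d = min(self.n_components, min(Xr.shape))
        pca = PCA(n_components=d, svd_solver="full" if min(Xr.shape) <= 1000 else "randomized",
                  random_state=0)
        ref_emb = pca.fit_transform(Xr)
        return shared, pca, ref_emb

    def predict_table(self, X) -> pd.DataFrame:
        """Map query cells; returns cluster, prediction_score, flagged."""
        Xq, q_genes = _matrix_and_genes(X)
        shared, pca, ref_emb = self._shared_projection(q_genes)
        q_cols = [q_genes.index(g) for g in shared]
        q_emb = pca.transform(Xq[:, q_cols])

        # distance-weighted vote over K reference neighbours
        from sklearn.metrics import pairwise_distances

        D = pairwise_distances(q_emb, ref_emb)
        k = self.n_neighbors
        nn = np.argpartition(D, k - 1, axis=1)[:, :k]
        rows = np.arange(D.shape[0])[:, None]
        w = 1.0 / (D[rows, nn] + 1e-12)
        labels = self.labels_[nn]
        clusters = []
        scores = []
        for i in range(D.shape[0]):
            vote = pd.Series(w[i]).groupby(labels[i]).sum()
            total = vote.sum()
            best = vote.idxmax()
            clusters.append(best)
            scores.append(float(vote.max() / total))
        index = list(X.obs_names) if isinstance(X, ad.AnnData) else (
            list(X.index) if isinstance(X, pd.DataFrame) else None)
        out = pd.DataFrame(
            {"cluster": clusters, "prediction_score": scores}, index=index
        )
        out["flagged"] = out["prediction_score"] < self.score_threshold
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_table(X)["cluster"].to_numpy()

    def prediction_score(self, X) -> np.ndarray:
        return self.predict_table(X)["prediction_score"].to_numpy()


def map_cells(reference, ref_labels, query, **kwargs) -> pd.DataFrame:
    """Functional wrapper: fit a ReferenceMapper and map ``query``."""
    return ReferenceMapper(**kwargs).fit(reference, ref_labels).predict_table(query)


def build_cluster_hulls(layout: np.ndarray, labels, ratio: float = 0.4, min_coverage: float = 0.95):
    """Concave hull polygon per cluster from a 2-D layout.

    Uses shapely's concave hull; falls back to the convex hull if the concave
    one covers fewer than ``min_coverage`` of the cluster's points (hulls are
    required to contain >=95% of their cluster).
    """
    import shapely
    from shapely.geometry import MultiPoint, Point

    layout = np.asarray(layout, dtype=float)
    if layout.shape[1] != 2:
        raise ValueError("layout must be 2-D")
    labels = np.asarray(pd.Series(labels).astype(str))
    hulls = {}
    for lab in np.unique(labels):
        pts = layout[labels == lab]
        mp = MultiPoint([tuple(p) for p in pts])
        hull = shapely.concave_hull(mp, ratio=ratio)
        if hull.geom_type != "Polygon" or not hull.is_valid:
            hull = mp.convex_hull
        if hull.geom_type == "Polygon":
            inside = np.mean([hull.covers(Point(*p)) for p in pts])
            if inside < min_coverage:
                hull = mp.convex_hull
        hulls[lab] = hull
    return hulls


def glasswork_coordinates(
    mapping: pd.DataFrame,
    hulls: dict,
    group_keys: list[str] | None = None,
    n_per_group: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random in-hull positions for mapped cells, evenly downsampled.

    ``mapping`` needs a ``cluster`` column plus any ``group_keys`` columns
    (e.g. condition, stage); each group is downsampled to ``n_per_group``
    cells (kept whole if smaller). Points are rejection-sampled uniformly
    inside the assigned cluster's hull. Deterministic under ``seed``.
    """
    from shapely.geometry import Point

    rng = np.random.default_rng(seed)
    df = mapping.copy()
    if group_keys:
        parts = []
        for _, grp in df.groupby(group_keys, observed=True, sort=True):
            if len(grp) > n_per_group:
                take = rng.choice(len(grp), size=n_per_group, replace=False)
                grp = grp.iloc[np.sort(take)]
            parts.append(grp)
        df = pd.concat(parts)
    rows = []
    for cell, rec in df.iterrows():
        hull = hulls[str(rec["cluster"])]
        if hull.geom_type != "Polygon" or hull.area == 0:
            raise ValueError(f"degenerate hull for cluster {rec['cluster']!r}")
        minx, miny, maxx, maxy = hull.bounds
        for _ in range(10_000):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if hull.covers(Point(x, y)):
                break
        else:  # pragma: no cover - pathological hull
            raise RuntimeError("rejection sampling failed")
        rows.append((cell, rec["cluster"], x, y))
    return pd.DataFrame(rows, columns=["cell", "cluster", "x", "y"]).set_index("cell")


def module_score(
    norm,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score per cell.

    Genes are ranked by mean expression and cut into ``n_bins``
    equal-frequency bins; each signature gene draws up to ``n_ctrl`` control
    genes from its bin (without replacement). The score is
    mean(signature expression) - mean(control expression) per cell.
    """
    X, genes = _matrix_and_genes(norm)
    gene_pos = {g: i for i, g in enumerate(genes)}
    present = [g for g in sig.genes if g in gene_pos]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    rng = np.random.default_rng(seed)

    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = (np.arange(len(genes)) * n_bins) // len(genes)

    sig_idx = np.array([gene_pos[g] for g in present])
    ctrl_idx: list[int] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.asarray(ctrl_idx)
    return X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def ssgsea_score(
    bulk: pd.DataFrame,
    sig: GeneSignature,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Single-sample rank-weighted enrichment score per sample.

    ``bulk`` is samples x genes. Per sample, genes are ranked by expression;
    the score integrates the difference between the |rank|^alpha-weighted
    in-set ECDF and the uniform out-of-set ECDF over the ranked list.
    With ``normalize=True`` scores are divided by their range across samples.
    """
    genes = list(bulk.columns)
    in_set = np.array([g in set(sig.genes) for g in genes])
    n_in = int(in_set.sum())
    if n_in < 2:
        raise ValueError("signature must share at least 2 genes with the matrix")
    if n_in == len(genes):
        raise ValueError("signature covers every gene; out-of-set is empty")
    X = bulk.to_numpy(dtype=float)
    n = len(genes)
    es = np.empty(X.shape[0])
    for s in range(X.shape[0]):
        order = np.argsort(-X[s], kind="stable")  # descending expression
        ranks = np.empty(n)
        ranks[order] = np.arange(n, 0, -1)  # highest expression -> rank n
        hit = in_set[order]
        w = np.where(hit, np.abs(ranks[order]) ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hit) / (n - n_in)
        es[s] = float(np.sum(p_in - p_out))
    out = pd.Series(es, index=bulk.index, name=sig.name)
    if normalize and len(out) > 1:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            out = out / rng_
    return out


def refine_signature(ref_markers: GeneSignature, mapped_query_markers: GeneSignature) -> GeneSignature:
    """Intersection of reference and mapped-query markers, name suffixed '*'.

    An empty intersection is allowed (with a warning): mapped populations may
    share no markers with their cognate reference cluster.
    """
    qset = set(mapped_query_markers.genes)
    genes = [g for g in ref_markers.genes if g in qset]
    if not genes:
        warnings.warn(
            f"no marker overlap between {ref_markers.name!r} and {mapped_query_markers.name!r}",
            stacklevel=2,
        )
    return GeneSignature(name=ref_markers.name + "*", genes=genes, direction=ref_markers.direction)
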