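"""Pseudobulk differential testing with CNA-aware size factors.

Counts are aggregated into replicate x condition x stage pseudobulks and
tested feature-by-feature with a negative-binomial Wald test: median-of-
ratios size factors (optionally computed excluding features on chromosome
arms carrying known copy-number aberrations, to avoid over-compensating for
dosage-driven global signal), method-of-moments dispersion per feature
shrunk toward a mean-dispersion trend, an NB GLM fit by IRLS, and
Benjamini-Hochberg adjustment per contrast.

Published significance thresholds are applied post hoc by
``call_significant``: RNA mode p_adj <= 0.05 and |log2FC| > 0.25 plus
expression in >=20% of cells on one side; ATAC mode p_adj <= 0.005 and
|log2FC| >= log2(1.5). Significant regions are grouped into chromatin
modules by Ward hierarchical clustering, and module/gene-set overlaps are
assessed with one-sided hypergeometric tests.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_pseudobulk",
    "size_factors",
    "size_factors_excluding",
    "test_differential",
    "expressed_fraction",
    "call_significant",
    "cluster_modules",
    "chromatin_modules",
    "hypergeom_enrich",
]

RNA_THRESHOLDS = {"p_adj": 0.05, "min_abs_lfc": 0.25, "lfc_inclusive": False, "min_expr_frac": 0.2}
ATAC_THRESHOLDS = {"p_adj": 0.005, "min_abs_lfc": np.log2(1.5), "lfc_inclusive": True, "min_expr_frac": None}


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def aggregate_pseudobulk(cells: ad.AnnData, grouping: list[str], min_cells: int = 10) -> ad.AnnData:
    """Sum single-cell counts per group defined by ``grouping`` obs keys.

    Groups with fewer than ``min_cells`` cells are dropped with a warning.
    Column sums of the result equal the summed counts of retained cells.
    """
    if not grouping:
        raise ValueError("grouping keys must not be empty")
    for key in grouping:
        if key not in cells.obs:
            raise ValueError(f"grouping key {key!r} not in cell table")
    X = _dense(cells.X)
    keys = cells.obs[grouping].astype(str).agg("|".join, axis=1)
    rows = []
    meta = []
    dropped = []
    for name, idx in keys.groupby(keys, observed=True).groups.items():
        mask = keys.index.isin(idx)
        if mask.sum() < min_cells:
            dropped.append(name)
            continue
        rows.append(X[mask].sum(axis=0))
        rec = dict(zip(grouping, name.split("|")))
        rec["n_cells"] = int(mask.sum())
        meta.append((name, rec))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} group(s) with < {min_cells} cells: {dropped[:5]}", stacklevel=2)
    if not rows:
        raise ValueError("no group passed the min_cells filter")
    obs = pd.DataFrame([r for _, r in meta], index=[n for n, _ in meta])
    return ad.AnnData(X=np.vstack(rows).astype(np.int64), obs=obs, var=cells.var.copy())


def size_factors(pb: ad.AnnData | np.ndarray, feature_mask: np.ndarray | None = None) -> np.ndarray:
    """Median-of-ratios size factors (computed on ``feature_mask`` features)."""
    X = _dense(pb.X) if isinstance(pb, ad.AnnData) else np.asarray(pb)
    X = X.astype(float)
    if feature_mask is not None:
        X = X[:, feature_mask]
    if X.shape[1] == 0:
        raise ValueError("no features available for size-factor estimation")
    with np.errstate(divide="ignore"):
        logs = np.log(X)
    ok = np.all(np.isfinite(logs), axis=0)
    if not ok.any():
        raise ValueError("no feature has nonzero counts in every sample")
    loggeo = logs[:, ok].mean(axis=0)
    sf = np.exp(np.median(logs[:, ok] - loggeo[None, :], axis=1))
    return sf


def size_factors_excluding(pb: ad.AnnData, excluded_arms, arm_key: str = "arm") -> pd.Series:
    """Size factors computed only on features outside ``excluded_arms``.

    Excluding arms with known copy-number gains prevents the dosage-driven
    signal on those arms from inflating the depth estimate.
    """
    arms = pb.var[arm_key].astype(str)
    mask = ~arms.isin([str(a) for a in excluded_arms]).to_numpy()
    if not mask.any():
        raise ValueError("no features remain after arm exclusion")
    return pd.Series(size_factors(pb, feature_mask=mask), index=pb.obs_names, name="size_factor")


def _fit_dispersion_trend(mean_: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Parametric trend a0 + a1/mean fitted to per-feature dispersions."""
    use = (mean_ > 0) & (disp > 1e-6)
    if use.sum() < 10:
        return np.full_like(disp, max(np.median(disp[disp > 0]) if (disp > 0).any() else 0.05, 1e-4))
    x = 1.0 / mean_[use]
    y = disp[use]
    for _ in range(5):  # trimmed refits for robustness to outliers
        A = np.vstack([np.ones_like(x), x]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = A @ coef
        resid = np.abs(y - pred)
        keep = resid <= 2.0 * np.median(resid) + 1e-12
        if keep.all():
            break
        x, y = x[keep], y[keep]
    a0 = max(coef[0], 1e-4)
    a1 = max(coef[1], 0.0)
    return a0 + a1 / np.maximum(mean_, 1e-8)


def _nb_irls(y: np.ndarray, design: np.ndarray, offset: np.ndarray, alpha: float,
             n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """NB log-link GLM by IRLS; returns (beta, se)."""
    n, p = design.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    for _ in range(n_iter):
        eta = design @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-12)
        WX = design * W[:, None]
        XtWX = design.T @ WX
        try:
            beta_new = np.linalg.solve(XtWX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    eta = design @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    W = mu / (1.0 + alpha * mu)
    cov = np.linalg.pinv(design.T @ (design * W[:, None]))
    se = np.sqrt(np.diag(cov))
    return beta, se


def test_differential(
    pb: ad.AnnData,
    condition_key: str,
    contrast: tuple[str, str],
    factors: pd.Series | np.ndarray | None = None,
    prior_df: float = 6.0,
) -> pd.DataFrame:
    """Per-feature NB Wald test between two condition levels.

    ``contrast = (treated, control)``; the reported log2 fold-change is
    treated over control. Dispersions are moderated by shrinking
    method-of-moments estimates toward a fitted mean-dispersion trend
    (weight ``prior_df`` pseudo-replicates). Requires >=2 replicates per
    side. All-zero features are excluded with a recorded reason.
    """
    cond = pb.obs[condition_key].astype(str)
    trt, ctl = str(contrast[0]), str(contrast[1])
    for level in (trt, ctl):
        if (cond == level).sum() == 0:
            raise ValueError(f"contrast level {level!r} missing from {condition_key!r}")
    mask = cond.isin([trt, ctl]).to_numpy()
    X = _dense(pb.X)[mask].astype(float)
    cond = cond[mask]
    if (cond == trt).sum() < 2 or (cond == ctl).sum() < 2:
        raise ValueError("need >= 2 replicates per side")
    if factors is None:
        sf = size_factors(X)
    else:
        sf = np.asarray(factors, dtype=float)
        sf = sf[mask] if len(sf) == len(mask) else sf
    n, G = X.shape
    group = (cond == trt).to_numpy().astype(float)
    design = np.column_stack([np.ones(n), group])
    offset = np.log(sf)

    norm = X / sf[:, None]
    base_mean = norm.mean(axis=0)
    nonzero = X.sum(axis=0) > 0

    # method-of-moments dispersion on normalised counts, pooled within sides
    disp = np.zeros(G)
    for side in (0.0, 1.0):
        m = group == side
        mu_s = norm[m].mean(axis=0)
        var_s = norm[m].var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (var_s - mu_s) / mu_s**2
        disp += np.where(np.isfinite(d), np.clip(d, 0.0, 10.0), 0.0) / 2.0
    trend = _fit_dispersion_trend(base_mean, disp)
    df_resid = n - 2
    log_shrunk = (df_resid * np.log(np.maximum(disp, 1e-8)) + prior_df * np.log(trend)) / (
        df_resid + prior_df
    )
    alpha = np.clip(np.exp(log_shrunk), 1e-8, 10.0)

    lfc = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    reason = np.full(G, None, dtype=object)
    for j in range(G):
        if not nonzero[j]:
            reason[j] = "all zero"
            continue
        beta, se = _nb_irls(X[:, j], design, offset, alpha[j])
        lfc[j] = beta[1] / np.log(2)
        if se[1] > 0:
            z = beta[1] / se[1]
            # t reference with residual df: the plug-in dispersion makes the
            # normal reference anti-conservative at few replicates
            pval[j] = 2.0 * stats.t.sf(abs(z), df_resid)
        else:
            pval[j] = 1.0
    padj = np.full(G, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pval,
            "padj": padj,
            "excluded_reason": reason,
        },
        index=pb.var_names,
    )


def expressed_fraction(cells: ad.AnnData, condition_key: str, contrast: tuple[str, str]) -> pd.DataFrame:
    """Fraction of cells with a raw count > 0 per feature, per contrast side."""
    X = _dense(cells.X)
    cond = cells.obs[condition_key].astype(str)
    out = {}
    for level in contrast:
        m = (cond == str(level)).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"no cells with {condition_key} == {level!r}")
        out[str(level)] = (X[m] > 0).mean(axis=0)
    return pd.DataFrame(out, index=cells.var_names)


def call_significant(res: pd.DataFrame, mode: str, expr_frac: pd.DataFrame | None = None) -> pd.Index:
    """Apply published significance thresholds; returns significant features.

    RNA: p_adj <= 0.05, |log2FC| > 0.25, expressed in >=20% of cells on at
    least one side (requires ``expr_frac``). ATAC: p_adj <= 0.005,
    |log2FC| >= log2(1.5). Boundary values on <=/>= comparisons count.
    """
    if mode == "rna":
        th = RNA_THRESHOLDS
    elif mode == "atac":
        th = ATAC_THRESHOLDS
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'rna' or 'atac'")
    ok = res["padj"].le(th["p_adj"]).fillna(False)
    abs_lfc = res["log2FoldChange"].abs()
    ok &= abs_lfc.ge(th["min_abs_lfc"]) if th["lfc_inclusive"] else abs_lfc.gt(th["min_abs_lfc"])
    if th["min_expr_frac"] is not None:
        if expr_frac is None:
            raise ValueError("RNA mode requires per-side expressed fractions")
        frac = expr_frac.reindex(res.index)
        ok &= frac.max(axis=1).ge(th["min_expr_frac"]).fillna(False)
    return res.index[ok]


def cluster_modules(
    profiles: pd.DataFrame, k: int, prefix: str = "R", start: int = 1
) -> pd.Series:
    """Ward-linkage modules over region accessibility profiles.

    ``profiles`` is regions x groups (normalised); rows are z-scored before
    clustering. Returns a region -> module-label Series (labels
    ``{prefix}{start}`` ...). The partition is invariant to row order; label
    numbering follows each module's first region in lexicographic region
    order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} regions, got {len(profiles)}")
    prof = profiles.sort_index()
    z = prof.to_numpy(dtype=float)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=1, keepdims=True)) / sd
    raw = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust") if k > 1 else np.ones(len(prof), int)
    relabel: dict[int, str] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = f"{prefix}{start + len(relabel)}"
        labels.append(relabel[r])
    return pd.Series(labels, index=prof.index, name="module").reindex(profiles.index)


def chromatin_modules(
    timewise: pd.DataFrame, conditionwise: pd.DataFrame, k_time: int = 6, k_cond: int = 3
) -> pd.Series:
    """Cluster time-wise and condition-wise significant regions separately
    (defaults 6 + 3 modules) and concatenate the labels R1..R{k_time+k_cond}."""
    a = cluster_modules(timewise, k_time, start=1)
    b = cluster_modules(conditionwise, k_cond, start=k_time + 1)
    return pd.concat([a, b])


def hypergeom_enrich(
    query,
    annotations: dict,
    background,
    p_adj_max: float = 0.005,
    min_abs_log2_odds: float = 0.0,
    min_set_size: int = 0,
) -> pd.DataFrame:
    """One-sided hypergeometric overlap enrichment of ``query`` in each set.

    All sets must be subsets of ``background``. Reports the upper-tail
    p-value P(X >= overlap), BH-adjusted across annotation sets, and a
    Haldane-corrected log2 odds ratio. The default profile calls
    p_adj <= 0.005 significant; a motif-style profile additionally requires
    |log2 odds| >= 1 (pass ``p_adj_max=1e-7, min_abs_log2_odds=1.0``).
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must not be empty")
    q = set(query)
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    rows = []
    M, N = len(bg), len(q)
    for name, members in annotations.items():
        s = set(members)
        if not s <= bg:
            raise ValueError(f"annotation set {name!r} is not a subset of the background")
        if len(s) < min_set_size:
            continue
        k = len(q & s)
        p = float(stats.hypergeom.sf(k - 1, M, len(s), N))
        a, b = k + 0.5, (N - k) + 0.5
        c, d = (len(s) - k) + 0.5, (M - len(s) - N + k) + 0.5
        rows.append((name, k, len(s), p, np.log2((a / b) / (c / d))))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p", "log2_odds"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = (out["p_adj"] <= p_adj_max) & (
            out["log2_odds"].abs() >= min_abs_log2_odds
        )
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out.set_index("set")
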