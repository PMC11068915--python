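"""Peak-to-gene linking with an empirical shuffle FDR.

Peaks are assigned to genes either by promoter overlap (peak interval
contains the TSS, optional pad) or as distal candidates whose interval lies
within 250 kb of the TSS. Distal candidates are scored by the Pearson
correlation between normalised per-sample accessibility and expression, and
an empirical FDR is computed by permuting the sample correspondence between
the two modalities (default 10 shuffles, nulls pooled): for each observed
|r|, FDR = (mean null exceedance count) / (observed exceedance count),
forced monotone non-increasing in |r|. Distal links with FDR <= 0.05 are
retained; promoter links are always retained.

Coordinates are 1-based inclusive internally (BED on disk is 0-based
half-open; see :mod:`cnatraj.io`). Distances are measured from the nearest
peak edge to the TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "assign_promoters",
    "candidate_distal",
    "correlate_links",
    "empirical_fdr",
    "PeakGeneLinker",
]


def _check_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in peaks.columns:
            raise ValueError(f"peaks table lacks column {col!r}")
    if (peaks["start"] > peaks["end"]).any():
        raise ValueError("peak start > end")
    return peaks


def _check_tss(tss: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "tss"):
        if col not in tss.columns:
            raise ValueError(f"TSS table lacks column {col!r}")
    return tss


def assign_promoters(peaks: pd.DataFrame, tss_table: pd.DataFrame, pad: int = 0) -> pd.DataFrame:
    """Promoter links: peak interval contains the TSS (+- ``pad`` bp).

    ``peaks`` is indexed by peak id with columns chrom/start/end (1-based
    inclusive); ``tss_table`` is indexed by gene with columns chrom/tss.
    """
    peaks = _check_peaks(peaks)
    tss_table = _check_tss(tss_table)
    shared = set(peaks["chrom"]) & set(tss_table["chrom"])
    if len(peaks) and len(tss_table) and not shared:
        raise ValueError("peaks and TSS table share no chromosome names")
    rows = []
    for chrom in sorted(shared):
        pk = peaks[peaks["chrom"] == chrom]
        gs = tss_table[tss_table["chrom"] == chrom]
        starts = pk["start"].to_numpy() - pad
        ends = pk["end"].to_numpy() + pad
        for gene, t in zip(gs.index, gs["tss"].to_numpy()):
            hit = (starts <= t) & (t <= ends)
            for pid in pk.index[hit]:
                rows.append((pid, gene, "promoter", 0))
    return pd.DataFrame(rows, columns=["peak_id", "gene", "kind", "distance"])


def candidate_distal(
    peaks: pd.DataFrame, tss_table: pd.DataFrame, max_dist: int = 250_000, pad: int = 0
) -> pd.DataFrame:
    """Distal candidates: peak-edge to TSS distance in (0, max_dist].

    Promoter-overlapping pairs are excluded (the kinds are disjoint).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    peaks = _check_peaks(peaks)
    tss_table = _check_tss(tss_table)
    rows = []
    for chrom in sorted(set(peaks["chrom"]) & set(tss_table["chrom"])):
        pk = peaks[peaks["chrom"] == chrom]
        gs = tss_table[tss_table["chrom"] == chrom]
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        for gene, t in zip(gs.index, gs["tss"].to_numpy()):
            dist = np.where(t < starts, starts - t, np.where(t > ends, t - ends, 0))
            promoter = (starts - pad <= t) & (t <= ends + pad)
            sel = (~promoter) & (dist > 0) & (dist <= max_dist)
            for pid, d in zip(pk.index[sel], dist[sel]):
                rows.append((pid, gene, "distal", int(d)))
    return pd.DataFrame(rows, columns=["peak_id", "gene", "kind", "distance"])


def _pair_correlations(
    candidates: pd.DataFrame, atac: pd.DataFrame, rna: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r per candidate pair on row-aligned sample matrices.

    Returns (r, zero_variance_mask); r is NaN where either feature is
    constant.
    """
    n = atac.shape[0]

    def _z(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        X = df.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        sd = np.where(zero, 1.0, sd)
        return (X - mu) / sd, zero

    za, zero_a = _z(atac)
    zr, zero_r = _z(rna)
    pi = atac.columns.get_indexer(candidates["peak_id"])
    gi = rna.columns.get_indexer(candidates["gene"])
    if (pi < 0).any() or (gi < 0).any():
        raise ValueError("candidate pair references a feature missing from the matrices")
    r = np.einsum("sp,sp->p", za[:, pi], zr[:, gi]) / (n - 1)
    zero = zero_a[pi] | zero_r[gi]
    r[zero] = np.nan
    return np.clip(r, -1, 1), zero


def correlate_links(
    candidates: pd.DataFrame, atac_pb: pd.DataFrame, rna_pb: pd.DataFrame
) -> pd.DataFrame:
    """Score candidate pairs by Pearson r across matched samples.

    ``atac_pb`` (samples x peaks) and ``rna_pb`` (samples x genes) are
    matched on their shared sample index (>=4 required). Zero-variance
    features are excluded with a recorded reason.
    """
    shared = atac_pb.index.intersection(rna_pb.index)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need >= 4")
    r, zero = _pair_correlations(candidates, atac_pb.loc[shared], rna_pb.loc[shared])
    out = candidates.copy()
    out["r"] = r
    out["excluded_reason"] = np.where(zero, "zero variance", None)
    return out


def _non_identity_permutations(n: int, n_shuffles: int, rng: np.random.Generator) -> list[np.ndarray]:
    if n < 2:
        raise ValueError("need at least 2 samples for a non-identity permutation")
    perms = []
    for _ in range(n_shuffles):
        for _ in range(1000):
            p = rng.permutation(n)
            if not np.array_equal(p, np.arange(n)):
                perms.append(p)
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to draw a non-identity permutation")
    return perms


def empirical_fdr(
    scored: pd.DataFrame,
    atac_pb: pd.DataFrame,
    rna_pb: pd.DataFrame,
    n_shuffles: int = 10,
    threshold: float = 0.05,
    pooled: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical shuffle FDR for scored distal candidates.

    The null is built by permuting the RNA sample labels relative to ATAC
    (``n_shuffles`` non-identity permutations) and recomputing r for every
    candidate. FDR(|r0|) = mean-per-shuffle null exceedances / observed
    exceedances (ties inclusive on both counts), clipped to [0, 1] and made
    monotone non-increasing in |r|. Adds ``empirical_fdr`` and ``retained``
    (FDR <= ``threshold``) columns. ``pooled=False`` averages per-shuffle
    FDR ratios instead of pooling the nulls (same estimator when observed
    exceedance counts are shared, kept for comparison).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(scored) < 10:
        raise ValueError("need >= 10 candidate pairs for a meaningful null")
    shared = atac_pb.index.intersection(rna_pb.index)
    atac = atac_pb.loc[shared]
    rna = rna_pb.loc[shared]
    rng = np.random.default_rng(seed)
    perms = _non_identity_permutations(len(shared), n_shuffles, rng)

    obs = scored["r"].abs().to_numpy()
    valid = np.isfinite(obs)
    null_abs = []
    for p in perms:
        rn = rna.iloc[p]
        rn.index = rna.index  # relabel: break the sample correspondence
        r_null, _ = _pair_correlations(scored, atac, rn)
        null_abs.append(np.abs(r_null[np.isfinite(r_null)]))

    obs_sorted = np.sort(obs[valid])
    m = valid.sum()

    def _exceed(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
        # count of values >= x (inclusive)
        return len(sorted_vals) - np.searchsorted(sorted_vals, x, side="left")

    n_obs_ge = _exceed(obs_sorted, obs[valid])
    if pooled:
        pool = np.sort(np.concatenate(null_abs))
        fdr_valid = (_exceed(pool, obs[valid]) / n_shuffles) / n_obs_ge
    else:
        acc = np.zeros(m)
        for na in null_abs:
            acc += _exceed(np.sort(na), obs[valid]) / n_obs_ge
        fdr_valid = acc / n_shuffles
    fdr_valid = np.clip(fdr_valid, 0.0, 1.0)

    # enforce monotone non-increase in |r|
    order = np.argsort(-obs[valid], kind="stable")
    fdr_mono = fdr_valid.copy()
    fdr_mono[order] = np.maximum.accumulate(fdr_valid[order])
    out = scored.copy()
    fdr = np.full(len(scored), np.nan)
    fdr[valid] = fdr_mono
    out["empirical_fdr"] = fdr
    out["retained"] = np.where(valid, fdr <= threshold, False)
    return out


class PeakGeneLinker(BaseEstimator):
    """End-to-end peak-to-gene linker (promoter + correlated distal).

    Parameters mirror the procedure: ``max_dist`` (250 kb), ``n_shuffles``
    (10), ``fdr`` threshold (0.05), ``pad`` for promoter overlap, and
    ``random_state`` for the shuffles.

    After ``fit(peaks, tss, atac_pb, rna_pb)``: ``links_`` holds the final
    table (promoter links plus retained distal links), ``candidates_`` the
    scored distal candidates with their empirical FDR.
    """

    def __init__(
        self,
        max_dist: int = 250_000,
        n_shuffles: int = 10,
        fdr: float = 0.05,
        pad: int = 0,
        pooled: bool = True,
        random_state: int = 0,
    ):
        self.max_dist = max_dist
        self.n_shuffles = n_shuffles
        self.fdr = fdr
        self.pad = pad
        self.pooled = pooled
        self.random_state = random_state

    def fit(
        self,
        peaks: pd.DataFrame,
        tss_table: pd.DataFrame,
        atac_pb: pd.DataFrame,
        rna_pb: pd.DataFrame,
    ):
        promoters = assign_promoters(peaks, tss_table, pad=self.pad)
        cand = candidate_distal(peaks, tss_table, max_dist=self.max_dist, pad=self.pad)
        if len(cand):
            cand = cand[cand["peak_id"].isin(atac_pb.columns) & cand["gene"].isin(rna_pb.columns)]
            cand = cand.reset_index(drop=True)
        if len(cand) >= 10:
            scored = correlate_links(cand, atac_pb, rna_pb)
            scored = empirical_fdr(
                scored, atac_pb, rna_pb, n_shuffles=self.n_shuffles,
                threshold=self.fdr, pooled=self.pooled, seed=self.random_state,
            )
        else:
            scored = cand.assign(r=np.nan, excluded_reason=None, empirical_fdr=np.nan, retained=False)
        self.candidates_ = scored
        promoters = promoters.assign(r=np.nan, empirical_fdr=0.0, retained=True)
        distal = scored[scored["retained"]].copy()
        cols = ["peak_id", "gene", "kind", "r", "empirical_fdr", "distance"]
        self.links_ = pd.concat(
            [promoters.reindex(columns=cols), distal.reindex(columns=cols)], ignore_index=True
        )
        return self
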