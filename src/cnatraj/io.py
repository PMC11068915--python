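"""On-disk formats: MTX + TSV tables, BED intervals, GMT gene sets.

Peak coordinates are 1-based inclusive in memory and 0-based half-open in
BED files.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_counts",
    "read_counts",
    "write_bed",
    "read_bed",
    "write_gmt",
    "read_gmt",
]


def write_counts(adata: ad.AnnData, outdir, prefix: str = "") -> None:
    """Write counts as ``matrix.mtx`` plus ``obs.tsv``/``var.tsv``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(str(out / f"{prefix}matrix.mtx"), X)
    adata.obs.to_csv(out / f"{prefix}obs.tsv", sep="\t")
    adata.var.to_csv(out / f"{prefix}var.tsv", sep="\t")


def read_counts(indir, prefix: str = "") -> ad.AnnData:
    ind = Path(indir)
    X = spio.mmread(str(ind / f"{prefix}matrix.mtx")).tocsr()
    obs = pd.read_csv(ind / f"{prefix}obs.tsv", sep="\t", index_col=0)
    var = pd.read_csv(ind / f"{prefix}var.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_bed(peaks: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    df = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int) - 1,
            "end": peaks["end"].astype(int),
            "name": peaks.index,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED into 1-based inclusive intervals indexed by name."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(dtype=int) + 1,
            "end": df["end"].to_numpy(dtype=int),
        },
        index=pd.Index(df["name"].astype(str).to_numpy(), name="peak_id"),
    )
    return out


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out
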