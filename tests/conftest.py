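import numpy as np
import pandas as pd
import pytest

import cnatraj as ct
from cnatraj.differential import size_factors


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated experiment for fast unit tests."""
    cfg = ct.SimConfig(
        n_cells_per_genotype=150,
        n_genes=500,
        n_peaks=400,
        n_coupled_pairs=60,
        n_tfs=5,
        targets_per_tf=10,
        seed=11,
    )
    cells, truth = ct.simulate_cells(cfg)
    peaks = ct.simulate_peaks(cfg, cells, truth)
    motifs = ct.simulate_motifs(cfg, truth, peaks)
    return cfg, cells, truth, peaks, motifs


@pytest.fixture(scope="session")
def default_sim():
    """The default-scale simulated experiment (study conditions)."""
    cfg = ct.SimConfig(seed=1)
    cells, truth = ct.simulate_cells(cfg)
    peaks = ct.simulate_peaks(cfg, cells, truth)
    motifs = ct.simulate_motifs(cfg, truth, peaks)
    norm = ct.normalize_log1p(cells)
    return cfg, cells, truth, peaks, motifs, norm


def make_pseudobulk_pair(cells, peaks, norm):
    """Matched per-sample RNA (mean normalised expression) and ATAC
    (depth-normalised log counts) matrices keyed by sample."""
    X = np.asarray(norm.X)
    keys = cells.obs[["genotype", "stage", "replicate"]].astype(str).agg("_".join, axis=1)
    rna_pb = (
        pd.DataFrame(X, index=cells.obs_names, columns=cells.var_names)
        .groupby(keys.values)
        .mean()
    )
    sf = size_factors(peaks)
    atac_pb = pd.DataFrame(
        np.log1p(np.asarray(peaks.X) / sf[:, None]),
        index=peaks.obs_names,
        columns=peaks.var_names,
    )
    return atac_pb, rna_pb.loc[atac_pb.index]


@pytest.fixture(scope="session")
def default_pb(default_sim):
    cfg, cells, truth, peaks, motifs, norm = default_sim
    return make_pseudobulk_pair(cells, peaks, norm)
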