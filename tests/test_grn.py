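import numpy as np
import pandas as pd
import pytest

from cnatraj import grn


class TestBalancedSubsample:
    def test_small_cluster_kept_whole(self):
        labels = ["a"] * 300
        idx = grn.balanced_subsample(labels, max_per_cluster=500, seed=0)
        assert len(idx) == 300

    def test_large_cluster_capped(self):
        labels = ["a"] * 2000 + ["b"] * 100
        idx = grn.balanced_subsample(labels, max_per_cluster=500, seed=0)
        labels = np.asarray(labels)
        assert (labels[idx] == "a").sum() == 500
        assert (labels[idx] == "b").sum() == 100

    def test_deterministic_under_seed(self):
        labels = ["a"] * 1000
        i1 = grn.balanced_subsample(labels, 100, seed=42)
        i2 = grn.balanced_subsample(labels, 100, seed=42)
        np.testing.assert_array_equal(i1, i2)


def _brute_force_changepoint(seq):
    """Exhaustive two-segment SSE minimisation over all split points."""
    seq = np.asarray(seq, dtype=float)
    best, best_sse = None, np.inf
    for k in range(1, len(seq)):
        a, b = seq[:k], seq[k:]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if sse < best_sse:
            best, best_sse = k, sse
    return best


class TestChangepoint:
    def test_two_level_sequence(self):
        vals = np.array([10.0] * 10 + [1.0] * 20)
        thr = grn.changepoint_threshold(vals, trim_frac=0.0)
        assert thr == 10.0  # split after the 10 high values

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(25, 200))
            vals = np.sort(rng.exponential(1.0, n))[::-1] + rng.normal(0, 0.01, n)
            thr = grn.changepoint_threshold(vals, trim_frac=0.0)
            seq = np.sort(vals)[::-1]
            k = _brute_force_changepoint(seq)
            assert thr == seq[k - 1]

    def test_linear_ramp_matches_oracle(self):
        ramp = np.linspace(100, 1, 50)
        thr = grn.changepoint_threshold(ramp, trim_frac=0.0)
        k = _brute_force_changepoint(np.sort(ramp)[::-1])
        assert thr == np.sort(ramp)[::-1][k - 1]

    def test_top_percent_trimmed(self):
        # one huge outlier would otherwise dominate the split
        vals = np.array([1000.0] + [10.0] * 20 + [1.0] * 80)
        thr = grn.changepoint_threshold(vals)  # trims ceil(1%)=2 values
        assert thr <= 10.0

    def test_constant_sequence_warns_none(self):
        with pytest.warns(UserWarning, match="constant"):
            assert grn.changepoint_threshold(np.ones(30)) is None

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            grn.changepoint_threshold(np.arange(10.0))


class TestImportanceMatrix:
    def _toy(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        tf_a = rng.normal(size=n)
        tf_b = rng.normal(size=n)
        gene = tf_a + rng.normal(0, 0.05, n)
        X = pd.DataFrame({"TFA": tf_a, "TFB": tf_b, "target": gene, "noise": rng.normal(size=n)})
        return X

    def test_copied_tf_dominates_importance(self):
        X = self._toy()
        imp, corr = grn.importance_matrix(X, ["TFA", "TFB"], ["c"] * len(X), n_reps=1, seed=0)
        assert imp.loc["TFA", "target"] > imp.loc["TFB", "target"]
        assert corr.loc["TFA", "target"] > 0.9

    def test_deterministic_regressor_average_equals_single_run(self):
        X = self._toy(1)

        def det_reg(Xm, y, seed):
            return np.abs(Xm.T @ y)

        i1, _ = grn.importance_matrix(X, ["TFA", "TFB"], ["c"] * len(X), n_reps=1,
                                      regressor=det_reg, seed=5)
        i3, _ = grn.importance_matrix(X, ["TFA", "TFB"], ["c"] * len(X), n_reps=3,
                                      regressor=det_reg, seed=5)
        pd.testing.assert_frame_equal(i1, i3)  # no subsampling occurs (small cluster)

    def test_negative_importances_rejected(self):
        X = self._toy(2)
        with pytest.raises(ValueError, match="negative"):
            grn.importance_matrix(X, ["TFA"], ["c"] * len(X), n_reps=1,
                                  regressor=lambda Xm, y, s: -np.ones(Xm.shape[1]), seed=0)

    def test_averaging_reduces_variance(self):
        """var(mean of 10 reps) < var(single rep) for a stochastic regressor."""
        X = self._toy(3, n=2000)

        def noisy_reg(Xm, y, seed):
            rng = np.random.default_rng(seed)
            return np.abs(Xm.T @ y) + rng.exponential(5.0, Xm.shape[1])

        singles, means = [], []
        for s in range(8):
            i1, _ = grn.importance_matrix(X, ["TFA", "TFB"], ["c"] * len(X), n_reps=1,
                                          max_per_cluster=300, regressor=noisy_reg, seed=s)
            i10, _ = grn.importance_matrix(X, ["TFA", "TFB"], ["c"] * len(X), n_reps=10,
                                           max_per_cluster=300, regressor=noisy_reg, seed=s)
            singles.append(i1.loc["TFB", "noise"])
            means.append(i10.loc["TFB", "noise"])
        assert np.var(means) < np.var(singles)


class TestBuildRegulons:
    def _inputs(self):
        genes = [f"g{i}" for i in range(40)] + ["TF1"]
        imp = pd.DataFrame(
            [np.concatenate([[10.0] * 5, np.ones(35), [0.0]])], index=["TF1"], columns=genes
        )
        corr_vals = np.zeros(41)
        corr_vals[:5] = [0.8, 0.5, -0.4, 0.05, -0.05]
        corr = pd.DataFrame([corr_vals], index=["TF1"], columns=genes)
        support = {"TF1": {f"g{i}" for i in range(40)}}
        return imp, corr, support

    def test_sign_split_and_r_filter(self):
        imp, corr, support = self._inputs()
        regs = grn.build_regulons(imp, corr, support, trim_frac=0.0)
        reg = regs[0]
        assert set(reg.activated) == {"g0", "g1"}  # r > 0.1
        assert set(reg.inhibited) == {"g2"}  # r < -0.1
        # |r| <= 0.1 discarded: g3 (0.05), g4 (-0.05)

    def test_motif_filter_is_sound(self):
        imp, corr, support = self._inputs()
        support = {"TF1": {"g0", "g2"}}  # only two supported
        regs = grn.build_regulons(imp, corr, support, trim_frac=0.0)
        assert set(regs[0].activated) | set(regs[0].inhibited) <= {"g0", "g2"}

    def test_tf_without_motifs_warns_empty(self):
        imp, corr, _ = self._inputs()
        with pytest.warns(UserWarning, match="no motif support"):
            regs = grn.build_regulons(imp, corr, {}, trim_frac=0.0)
        assert regs[0].targets == []

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            grn.Regulon(tf="X", activated=["a"], inhibited=["a"])


class TestRegulonScore:
    def test_planted_shift_raises_score_in_carrier_cells(self):
        rng = np.random.default_rng(0)
        baseline = rng.normal(5, 1.0, 500)  # varied abundances populate the bins
        X = baseline[None, :] + rng.normal(0, 0.3, (100, 500))
        targets = [f"g{i}" for i in range(10)]
        X[:40, :10] += 1.0  # "mutant" cells with the programme on
        df = pd.DataFrame(X, columns=[f"g{i}" for i in range(500)])
        reg = grn.Regulon(tf="TF1", activated=targets)
        s = grn.regulon_score(df, reg, seed=0)
        assert s[:40].mean() > s[40:].mean() + 0.5

    def test_constant_matrix_zero(self):
        df = pd.DataFrame(np.ones((10, 50)), columns=[f"g{i}" for i in range(50)])
        s = grn.regulon_score(df, grn.Regulon(tf="T", activated=["g0", "g1"]), seed=0)
        np.testing.assert_allclose(s, 0.0)
        assert len(s) == 10 and np.isfinite(s).all()

    def test_empty_activated_errors(self):
        df = pd.DataFrame(np.ones((4, 5)), columns=list("abcde"))
        with pytest.raises(ValueError, match="activated"):
            grn.regulon_score(df, grn.Regulon(tf="T"), seed=0)


class TestRegulonEnrichment:
    def test_exact_match_is_significant(self):
        bg = [f"g{i}" for i in range(500)]
        targets = bg[:25]
        regs = [grn.Regulon(tf="T", activated=targets)]
        tab = grn.regulon_enrichment(regs, {"S1": targets}, bg)
        row = tab.iloc[0]
        assert row["significant"]
        assert row["frequency"] == 1.0

    def test_frequency_rule_blocks_small_overlap(self):
        bg = [f"g{i}" for i in range(500)]
        gene_set = bg[:100]
        regs = [grn.Regulon(tf="T", activated=bg[:2])]  # overlap 2% of the set
        tab = grn.regulon_enrichment(regs, {"S1": gene_set}, bg, min_frequency=0.05)
        assert not tab.iloc[0]["significant"]

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        bg = [f"g{i}" for i in range(1000)]
        flagged = 0
        trials = 0
        for rep in range(30):
            regs = [grn.Regulon(tf="T", activated=list(rng.choice(bg, 30, replace=False)))]
            sets = {f"S{j}": list(rng.choice(bg, 50, replace=False)) for j in range(4)}
            tab = grn.regulon_enrichment(regs, sets, bg)
            flagged += int(tab["significant"].sum())
            trials += len(tab)
        assert flagged / trials <= 0.05

    def test_empty_gene_set_errors(self):
        regs = [grn.Regulon(tf="T", activated=["g1"])]
        with pytest.raises(ValueError, match="empty"):
            grn.regulon_enrichment(regs, {"S": []}, ["g1", "g2"])


class TestNetworkExport:
    def test_edge_count_conservation_and_roundtrip(self, tmp_path):
        regs = [
            grn.Regulon(tf="T1", activated=["a", "b"], inhibited=["c"]),
            grn.Regulon(tf="T2", activated=["b"]),
        ]
        corr = pd.DataFrame(0.5, index=["T1", "T2"], columns=["a", "b", "c"])
        nodes, edges = grn.network_export(regs, corr, outdir=tmp_path)
        assert len(edges) == 4
        assert nodes.loc["T1", "is_tf"] and not nodes.loc["a", "is_tf"]
        back = pd.read_csv(tmp_path / "network_edges.tsv", sep="\t")
        pd.testing.assert_frame_equal(back, edges)

    def test_no_regulons_headers_only(self, tmp_path):
        nodes, edges = grn.network_export([], outdir=tmp_path)
        assert len(edges) == 0 and len(nodes) == 0
        assert (tmp_path / "network_nodes.tsv").exists()
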