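import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from cnatraj import differential as dd
from cnatraj.sim import simulate_null_pseudobulk


def _cells(X, groups, arms=None):
    X = np.asarray(X)
    var = pd.DataFrame(index=[f"f{j}" for j in range(X.shape[1])])
    if arms is not None:
        var["arm"] = arms
    return ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame({"grp": groups}, index=[f"c{i}" for i in range(X.shape[0])]),
        var=var,
    )


class TestAggregatePseudobulk:
    def test_exact_summation(self):
        a = _cells([[1, 2], [3, 4]], ["g1", "g1"])
        pb = dd.aggregate_pseudobulk(a, ["grp"], min_cells=1)
        np.testing.assert_array_equal(np.asarray(pb.X), [[4, 6]])

    def test_identity_when_each_cell_own_group(self):
        a = _cells([[1, 2], [3, 4], [5, 6]], ["a", "b", "c"])
        pb = dd.aggregate_pseudobulk(a, ["grp"], min_cells=1)
        np.testing.assert_array_equal(np.sort(np.asarray(pb.X), axis=0), [[1, 2], [3, 4], [5, 6]])

    def test_count_conservation_and_min_cells(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2, (40, 6))
        groups = ["big"] * 35 + ["tiny"] * 5
        a = _cells(X, groups)
        with pytest.warns(UserWarning, match="tiny"):
            pb = dd.aggregate_pseudobulk(a, ["grp"], min_cells=10)
        assert list(pb.obs.index) == ["big"]
        np.testing.assert_array_equal(np.asarray(pb.X)[0], X[:35].sum(axis=0))

    def test_empty_grouping_errors(self):
        a = _cells([[1]], ["x"])
        with pytest.raises(ValueError):
            dd.aggregate_pseudobulk(a, [])


class TestSizeFactors:
    def test_doubled_sample(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, (1, 100)) + 1
        X = np.vstack([base, base * 2])
        sf = dd.size_factors(X)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_exclusion_semantics(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(50, 100) + 1
        arms = np.array(["17q"] * 40 + ["5q"] * 60)
        X = np.vstack([base, base.copy()])
        X[1, arms == "17q"] *= 4  # gain only on the excluded arm
        pb = _cells(X, ["a", "b"], arms=arms)
        sf = dd.size_factors_excluding(pb, ["17q"])
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(1.0)

    def test_recovers_depth_despite_arm_gain(self):
        """2x gain on one arm + 1.5x global depth: exclusion recovers 1.5."""
        rng = np.random.default_rng(3)
        G = 1000
        arms = np.array(["17q"] * 400 + ["5q"] * 600)
        mean = np.exp(rng.normal(4, 0.7, G))
        disp = 0.05
        a = rng.poisson(rng.gamma(1 / disp, mean * disp))
        gained = mean.copy()
        gained[arms == "17q"] *= 2.0
        b = rng.poisson(rng.gamma(1 / disp, 1.5 * gained * disp))
        pb = _cells(np.vstack([a, b]), ["a", "b"], arms=arms)
        excl = dd.size_factors_excluding(pb, ["17q"])
        ratio = excl.iloc[1] / excl.iloc[0]
        assert abs(ratio - 1.5) / 1.5 < 0.05
        naive = dd.size_factors(pb)
        assert abs(naive[1] / naive[0] - 1.5) / 1.5 > 0.10

    def test_no_features_left_errors(self):
        pb = _cells([[1, 2], [3, 4]], ["a", "b"], arms=["17q", "17q"])
        with pytest.raises(ValueError):
            dd.size_factors_excluding(pb, ["17q"])


class TestDifferentialTest:
    def test_null_calibration(self):
        pb, _ = simulate_null_pseudobulk(seed=10)
        res = dd.test_differential(pb, "condition", ("B", "A"))
        frac = (res["pvalue"] <= 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_power_on_planted_fold_changes(self):
        pb, planted = simulate_null_pseudobulk(n_planted=300, fold=4.0, seed=11)
        res = dd.test_differential(pb, "condition", ("B", "A"))
        sig = dd.call_significant(res, "atac")
        hits = set(pb.var_names[planted])
        assert len(set(sig) & hits) / len(hits) >= 0.8
        # and the fold change is estimated near log2(4)
        assert res.loc[list(hits), "log2FoldChange"].median() == pytest.approx(2.0, abs=0.3)

    def test_all_zero_feature_excluded(self):
        pb, _ = simulate_null_pseudobulk(n_features=50, seed=12)
        X = np.asarray(pb.X)
        X[:, 7] = 0
        pb2 = ad.AnnData(X=X, obs=pb.obs.copy(), var=pb.var.copy())
        res = dd.test_differential(pb2, "condition", ("B", "A"))
        assert res["excluded_reason"].iloc[7] == "all zero"
        assert np.isnan(res["pvalue"].iloc[7])

    def test_missing_level_errors(self):
        pb, _ = simulate_null_pseudobulk(n_features=20, seed=13)
        with pytest.raises(ValueError, match="missing"):
            dd.test_differential(pb, "condition", ("C", "A"))


class TestCallSignificant:
    def _res(self, padj, lfc):
        return pd.DataFrame(
            {"padj": [padj], "log2FoldChange": [lfc], "pvalue": [padj], "baseMean": [10.0]},
            index=["f0"],
        )

    def test_rna_mode_thresholds(self):
        frac = pd.DataFrame({"A": [0.25], "B": [0.05]}, index=["f0"])
        assert list(dd.call_significant(self._res(0.01, 0.3), "rna", frac)) == ["f0"]
        # fails the expressed-fraction rule
        low = pd.DataFrame({"A": [0.1], "B": [0.15]}, index=["f0"])
        assert len(dd.call_significant(self._res(0.01, 0.3), "rna", low)) == 0

    def test_atac_mode_stricter_lfc(self):
        assert len(dd.call_significant(self._res(0.01, 0.3), "atac")) == 0
        assert list(dd.call_significant(self._res(0.005, np.log2(1.5)), "atac")) == ["f0"]

    def test_boundary_padj_inclusive(self):
        assert list(dd.call_significant(self._res(0.005, 1.0), "atac")) == ["f0"]
        assert len(dd.call_significant(self._res(0.0051, 1.0), "atac")) == 0

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(4)
        res = pd.DataFrame(
            {
                "padj": rng.random(100),
                "log2FoldChange": rng.normal(0, 1, 100),
                "pvalue": rng.random(100),
                "baseMean": np.ones(100),
            },
            index=[f"f{j}" for j in range(100)],
        )
        sig = dd.call_significant(res, "atac")
        assert list(dd.call_significant(res.loc[sig], "atac")) == list(sig)
        # strengthening the evidence never de-selects
        stronger = res.copy()
        stronger["padj"] /= 2
        stronger["log2FoldChange"] *= 2
        assert set(sig) <= set(dd.call_significant(stronger, "atac"))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            dd.call_significant(self._res(0.1, 0.1), "chip")


class TestClusterModules:
    def _archetypes(self, seed=0):
        rng = np.random.default_rng(seed)
        up = np.tile(np.linspace(0, 1, 8), (30, 1)) + rng.normal(0, 0.05, (30, 8))
        down = np.tile(np.linspace(1, 0, 8), (30, 1)) + rng.normal(0, 0.05, (30, 8))
        prof = pd.DataFrame(np.vstack([up, down]),
                            index=[f"r{i}" for i in range(60)],
                            columns=[f"s{j}" for j in range(8)])
        truth = ["up"] * 30 + ["down"] * 30
        return prof, truth

    def test_planted_archetypes_recovered(self):
        prof, truth = self._archetypes()
        labels = dd.cluster_modules(prof, k=2)
        a = set(labels.index[labels == labels.iloc[0]])
        up = {f"r{i}" for i in range(30)}
        down = set(prof.index) - up
        jac = max(
            len(a & up) / len(a | up),
            len(a & down) / len(a | down),
        )
        assert jac >= 0.9

    def test_k_equals_n_gives_singletons(self):
        prof, _ = self._archetypes(1)
        prof = prof.iloc[:5]
        labels = dd.cluster_modules(prof, k=5)
        assert labels.nunique() == 5

    def test_row_order_invariance(self):
        prof, _ = self._archetypes(2)
        l1 = dd.cluster_modules(prof, k=2)
        l2 = dd.cluster_modules(prof.sample(frac=1, random_state=3), k=2)
        # identical partition as sets
        p1 = {frozenset(l1.index[l1 == m]) for m in l1.unique()}
        p2 = {frozenset(l2.index[l2 == m]) for m in l2.unique()}
        assert p1 == p2

    def test_combined_time_and_condition_labels(self):
        prof, _ = self._archetypes(3)
        combined = dd.chromatin_modules(prof.iloc[:40], prof.iloc[40:], k_time=6, k_cond=3)
        labs = set(combined.unique())
        assert labs <= {f"R{i}" for i in range(1, 10)}
        assert {"R7", "R8", "R9"} & labs

    def test_k_validation(self):
        prof, _ = self._archetypes(4)
        with pytest.raises(ValueError):
            dd.cluster_modules(prof, k=0)
        with pytest.raises(ValueError):
            dd.cluster_modules(prof.iloc[:3], k=5)


def _hypergeom_tail_oracle(M, K, N, k):
    """P(X >= k) by exhaustive enumeration over overlap counts."""
    total = comb(M, N, exact=True)
    return sum(
        comb(K, x, exact=True) * comb(M - K, N - x, exact=True) for x in range(k, min(K, N) + 1)
    ) / total


class TestHypergeomEnrich:
    def test_matches_enumeration_oracle_small_backgrounds(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            M = int(rng.integers(8, 26))
            bg = [f"x{i}" for i in range(M)]
            K = int(rng.integers(1, M))
            N = int(rng.integers(1, M))
            ann = set(rng.choice(bg, K, replace=False))
            query = set(rng.choice(bg, N, replace=False))
            k = len(ann & query)
            tab = dd.hypergeom_enrich(query, {"s": ann}, bg)
            assert tab.loc["s", "p"] == pytest.approx(_hypergeom_tail_oracle(M, K, N, k), rel=1e-12)

    def test_query_equals_annotation_is_minimal_p(self):
        bg = [f"x{i}" for i in range(100)]
        ann = set(bg[:10])
        tab = dd.hypergeom_enrich(ann, {"s": ann}, bg)
        assert tab.loc["s", "p"] == pytest.approx(_hypergeom_tail_oracle(100, 10, 10, 10), rel=1e-12)
        assert tab.loc["s", "significant"]

    def test_overlap_at_expectation_not_significant(self):
        bg = [f"x{i}" for i in range(100)]
        ann = set(bg[:20])
        query = set(bg[:2]) | set(bg[50:58])  # overlap 2 = 10*20/100
        tab = dd.hypergeom_enrich(query, {"s": ann}, bg)
        assert tab.loc["s", "p"] >= 0.05

    def test_worked_example(self):
        # background 100, annotated 20, query 10, overlap 5
        bg = [f"x{i}" for i in range(100)]
        ann = set(bg[:20])
        query = set(bg[:5]) | set(bg[60:65])
        tab = dd.hypergeom_enrich(query, {"s": ann}, bg)
        assert tab.loc["s", "overlap"] == 5
        assert tab.loc["s", "p"] == pytest.approx(_hypergeom_tail_oracle(100, 20, 10, 5), rel=1e-12)

    def test_subset_violations_error(self):
        with pytest.raises(ValueError):
            dd.hypergeom_enrich({"z"}, {"s": {"a"}}, {"a", "b"})
        with pytest.raises(ValueError):
            dd.hypergeom_enrich({"a"}, {"s": {"z"}}, {"a", "b"})
        with pytest.raises(ValueError):
            dd.hypergeom_enrich(set(), {"s": set()}, set())
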