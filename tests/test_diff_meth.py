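import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio.tree import TreeNode

from msdaflp import anova_bh, subtle_filter, tukey_hsd, zscore_pca_cluster


def study_matrix(rows, groups=("A", "A", "A", "B", "B", "B", "C", "C", "C")):
    samples = [f"s{i}" for i in range(len(groups))]
    matrix = pd.DataFrame(rows, columns=samples)
    return matrix, dict(zip(samples, groups))


def bh_oracle(pvals):
    """Hand step-up BH: q_i = min over j>=i of m*p_(j)/j, in original order."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, m * pvals[i] / (rank + 1))
        q[i] = running
    return q


class TestAnovaBH:
    def test_identical_groups_give_null_result(self):
        matrix, groups = study_matrix(
            [[1, 2, 3, 1, 2, 3]], groups=("A", "A", "A", "B", "B", "B")
        )
        res = anova_bh(matrix, groups)
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert not res["significant"].iloc[0]

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        matrix, groups = study_matrix(rng.normal(50, 5, size=(30, 9)))
        res = anova_bh(matrix, groups)
        a = matrix.iloc[:, :3].to_numpy()
        b = matrix.iloc[:, 3:6].to_numpy()
        c = matrix.iloc[:, 6:].to_numpy()
        F, p = stats.f_oneway(a, b, c, axis=1)
        np.testing.assert_allclose(res["F"], F, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p, rtol=1e-10)

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(1)
        matrix, groups = study_matrix(rng.normal(50, 5, size=(200, 9)))
        res = anova_bh(matrix, groups)
        np.testing.assert_allclose(res["q"], bh_oracle(res["p"].to_numpy()),
                                   rtol=1e-12)
        # BH monotonicity after step-up: q non-decreasing in p order
        q_sorted = res["q"].to_numpy()[np.argsort(res["p"].to_numpy())]
        assert np.all(np.diff(q_sorted) >= -1e-15)

    def test_maximal_separation_with_zero_within_variance(self):
        matrix, groups = study_matrix(
            [[0, 0, 0, 100, 100, 100]], groups=("A", "A", "A", "B", "B", "B")
        )
        res = anova_bh(matrix, groups)
        assert res["significant"].iloc[0]
        assert not res["constant"].iloc[0]

    def test_constant_rows_flagged(self):
        matrix, groups = study_matrix(
            [[7.0] * 6, [1, 2, 3, 4, 5, 6]], groups=("A",) * 3 + ("B",) * 3
        )
        res = anova_bh(matrix, groups)
        assert res["constant"].iloc[0]
        assert res["p"].iloc[0] == 1.0

    def test_single_group_rejected(self):
        matrix, groups = study_matrix([[1, 2, 3]], groups=("A", "A", "A"))
        with pytest.raises(ValueError):
            anova_bh(matrix, groups)

    def test_null_pvalues_uniform(self):
        # Kolmogorov-Smirnov check on a complete-null simulation
        rng = np.random.default_rng(7)
        matrix, groups = study_matrix(rng.normal(30, 2, size=(10_000, 9)))
        res = anova_bh(matrix, groups)
        ks = stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.05


class TestTukey:
    def test_three_group_example(self):
        matrix, groups = study_matrix([[1, 2, 3, 2, 3, 4, 10, 11, 12]])
        tk = tukey_hsd(matrix, groups)
        sig = {
            tuple(sorted((r.group1, r.group2))): r.significant
            for r in tk.itertuples()
        }
        assert sig[("A", "C")] and sig[("B", "C")]
        assert not sig[("A", "B")]

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(3)
        matrix, groups = study_matrix(rng.normal(40, 8, size=(20, 9)))
        tk = tukey_hsd(matrix, groups)
        for row_id in range(20):
            a, b, c = (matrix.iloc[row_id, i : i + 3].to_numpy() for i in (0, 3, 6))
            ref = stats.tukey_hsd(a, b, c)
            sub = tk[tk["row"] == row_id]
            pairs = {("A", "B"): (0, 1), ("A", "C"): (0, 2), ("B", "C"): (1, 2)}
            for (g1, g2), (i, j) in pairs.items():
                mine = sub[(sub.group1 == g1) & (sub.group2 == g2)]["p_adj"].iloc[0]
                assert mine == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_identical_groups_pair_p_one(self):
        matrix, groups = study_matrix(
            [[5, 6, 7, 5, 6, 7, 20, 21, 22]]
        )
        tk = tukey_hsd(matrix, groups)
        ab = tk[(tk.group1 == "A") & (tk.group2 == "B")]
        assert ab["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_effect_sizes(self):
        matrix, groups = study_matrix(
            [[40, 40, 40, 42, 42, 42]], groups=("A",) * 3 + ("B",) * 3
        )
        tk = tukey_hsd(matrix, groups)
        assert tk["delta"].iloc[0] == pytest.approx(2.0)
        assert tk["rho"].iloc[0] == pytest.approx(1.05)

    def test_ratio_floor_avoids_division_blowup(self):
        matrix, groups = study_matrix(
            [[0, 0, 0, 3, 3, 3]], groups=("A",) * 3 + ("B",) * 3
        )
        tk = tukey_hsd(matrix, groups)
        assert tk["rho"].iloc[0] == pytest.approx(3.0 / 0.1)


class TestSubtleFilter:
    def frame(self, delta, rho, significant=True):
        return pd.DataFrame(
            {"row": [0], "group1": ["A"], "group2": ["B"], "q_stat": [5.0],
             "p_adj": [0.01 if significant else 0.5], "delta": [delta],
             "rho": [rho], "significant": [significant]}
        )

    def test_small_difference_retained(self):
        assert len(subtle_filter(self.frame(4.0, 1.08))) == 1

    @pytest.mark.parametrize("delta,rho", [(4.0, 1.2), (8.0, 1.05)])
    def test_large_difference_excluded(self, delta, rho):
        assert len(subtle_filter(self.frame(delta, rho))) == 0

    def test_non_significant_excluded(self):
        assert len(subtle_filter(self.frame(4.0, 1.05, significant=False))) == 0


class TestZscorePcaCluster:
    def test_zscore_convention(self):
        matrix = pd.DataFrame([[10.0, 20.0, 30.0]], columns=["a", "b", "c"])
        res = zscore_pca_cluster(matrix)
        np.testing.assert_allclose(res.zmatrix.iloc[0], [-1.0, 0.0, 1.0])

    def test_identical_samples_join_first(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=20)
        matrix = pd.DataFrame(
            {"x1": base, "x2": base, "y": base + rng.normal(0, 3, size=20)}
        )
        res = zscore_pca_cluster(matrix)
        tree = TreeNode.read(io.StringIO(res.newick))
        x1 = tree.find("x1")
        assert {t.name for t in x1.parent.tips()} == {"x1", "x2"}

    def test_pc1_separates_two_groups(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0, 0.1, size=(30, 3))
        g2 = rng.normal(5, 0.1, size=(30, 3))
        matrix = pd.DataFrame(
            np.vstack([np.hstack([g1, g2])]),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        res = zscore_pca_cluster(matrix)
        pc1 = res.pca_scores["PC1"]
        a = pc1[["a1", "a2", "a3"]].to_numpy()
        b = pc1[["b1", "b2", "b3"]].to_numpy()
        assert a.max() < b.min() or b.max() < a.min()

    def test_three_planted_signatures_cluster_monophyletically(self):
        rng = np.random.default_rng(8)
        n = 300
        signatures = rng.normal(0, 5, size=(n, 3))
        cols = {}
        tissue_of = {}
        for t, tissue in enumerate(["liver", "kidney", "hippo"]):
            for r in range(3):
                name = f"{tissue}_{r}"
                cols[name] = 50 + signatures[:, t] + rng.normal(0, 1, size=n)
                tissue_of[name] = tissue
        res = zscore_pca_cluster(pd.DataFrame(cols))
        tree = TreeNode.read(io.StringIO(res.newick))
        for tissue in ["liver", "kidney", "hippo"]:
            members = [n_ for n_, t_ in tissue_of.items() if t_ == tissue]
            lca = tree.lca(members)
            assert {t.name for t in lca.tips()} == set(members)

    def test_zero_variance_rows_dropped(self):
        matrix = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], columns=["a", "b", "c"]
        )
        res = zscore_pca_cluster(matrix)
        assert res.dropped_rows == [0]

    def test_all_constant_rejected(self):
        matrix = pd.DataFrame([[2.0, 2.0, 2.0]], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            zscore_pca_cluster(matrix)
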