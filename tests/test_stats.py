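"""Group statistics: parametric tests, FDR, and permutation cluster FWE."""

import numpy as np
import pytest
from scipy import stats as sps

from brainheart.stats import (
    cluster_inference,
    fdr_bh,
    label_clusters,
    one_sample_t,
    paired_t,
    posthoc_pairwise,
    regress_covariate,
    rm_anova,
)


class TestOneSampleT:
    def test_known_example(self):
        # [DERIVED] x=[1,2,3]: mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641, df 2
        res = one_sample_t(np.array([1.0, 2.0, 3.0]))
        assert res.stat_map[0] == pytest.approx(2.0 * np.sqrt(3.0))
        assert res.df == (2,)

    def test_matches_scipy(self, rng):
        x = rng.standard_normal((12, 7))
        res = one_sample_t(x, null_mean=0.3)
        oracle = sps.ttest_1samp(x, 0.3, axis=0)
        np.testing.assert_allclose(res.stat_map, oracle.statistic, atol=1e-12)
        np.testing.assert_allclose(res.p_map, oracle.pvalue, atol=1e-12)

    def test_zero_variance_conventions(self):
        x = np.column_stack([np.zeros(5), np.full(5, 2.0)])
        res = one_sample_t(x)
        assert res.stat_map[0] == 0.0  # exactly at the null
        assert np.isnan(res.stat_map[1])  # off the null: undefined
        assert res.flagged.all()

    def test_min_subjects(self):
        with pytest.raises(ValueError, match="3 observations"):
            one_sample_t(np.array([1.0, 2.0]))


class TestPairedT:
    def test_matches_scipy(self, rng):
        a = rng.standard_normal((10, 4))
        b = rng.standard_normal((10, 4))
        res = paired_t(a, b)
        oracle = sps.ttest_rel(a, b, axis=0)
        np.testing.assert_allclose(res.stat_map, oracle.statistic, atol=1e-12)
        np.testing.assert_allclose(res.p_map, oracle.pvalue, atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatched"):
            paired_t(rng.standard_normal(10), rng.standard_normal(9))


class TestRMAnova:
    def test_matches_statsmodels(self, rng):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        x = rng.standard_normal((9, 3)) + np.array([0.0, 0.4, -0.2])
        res = rm_anova(x)
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(9), 3),
                "cond": np.tile(np.arange(3), 9),
                "y": x.ravel(),
            }
        )
        oracle = AnovaRM(long, "y", "subj", within=["cond"]).fit()
        f_o = float(oracle.anova_table["F Value"].iloc[0])
        p_o = float(oracle.anova_table["Pr > F"].iloc[0])
        assert res.stat_map[0] == pytest.approx(f_o, rel=1e-10)
        assert res.p_map[0] == pytest.approx(p_o, rel=1e-10)
        assert res.df == (2, 16)

    def test_subject_shift_invariance(self, rng):
        x = rng.standard_normal((8, 3))
        shifted = x + rng.standard_normal(8)[:, None]
        np.testing.assert_allclose(
            rm_anova(x).stat_map, rm_anova(shifted).stat_map, atol=1e-9
        )

    def test_missing_cells_rejected(self, rng):
        x = rng.standard_normal((8, 3))
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(x)


class TestPosthoc:
    def test_bonferroni_times_three(self, rng):
        x = rng.standard_normal((10, 3))
        out = posthoc_pairwise(x)
        assert set(out) == {(0, 1), (0, 2), (1, 2)}
        for (i, j), res in out.items():
            raw = sps.ttest_rel(x[:, i], x[:, j]).pvalue
            assert res.p_map[0] == pytest.approx(min(3.0 * raw, 1.0))

    def test_requires_three_conditions(self, rng):
        with pytest.raises(ValueError, match="3 conditions"):
            posthoc_pairwise(rng.standard_normal((10, 4)))


class TestRegressCovariate:
    def test_matches_linregress(self, rng):
        y = rng.standard_normal(15)
        s = rng.standard_normal(15)
        res = regress_covariate(y, s)
        oracle = sps.linregress(s, y)
        t_o = oracle.slope / oracle.stderr
        assert res.stat_map[0] == pytest.approx(t_o, rel=1e-10)
        assert res.p_map[0] == pytest.approx(oracle.pvalue, rel=1e-10)
        assert res.df == (13,)

    def test_perfect_fit_flagged_inf(self):
        s = np.arange(6.0)
        res = regress_covariate(2.0 * s + 1.0, s)
        assert np.isinf(res.stat_map[0])
        assert res.flagged[0]

    def test_validation(self, rng):
        with pytest.raises(ValueError, match="constant"):
            regress_covariate(rng.standard_normal(8), np.ones(8))
        with pytest.raises(ValueError, match="4 subjects"):
            regress_covariate(np.ones(3), np.arange(3.0))


class TestLabelClusters:
    def _brute_force(self, mask, connectivity):
        # [DERIVED] BFS flood fill with explicit neighbour offsets
        offsets = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    o = (dx, dy, dz)
                    order = sum(abs(v) for v in o)
                    if order == 0:
                        continue
                    if connectivity == 6 and order > 1:
                        continue
                    if connectivity == 18 and order > 2:
                        continue
                    offsets.append(o)
        seen = np.zeros_like(mask, bool)
        sizes = []
        for start in map(tuple, np.argwhere(mask)):
            if seen[start]:
                continue
            queue, size = [start], 0
            seen[start] = True
            while queue:
                v = queue.pop()
                size += 1
                for o in offsets:
                    w = tuple(np.add(v, o))
                    if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                        if mask[w] and not seen[w]:
                            seen[w] = True
                            queue.append(w)
            sizes.append(size)
        return sorted(sizes)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs(self, rng, connectivity):
        mask = rng.random((7, 7, 5)) > 0.7
        _, sizes = label_clusters(mask, connectivity)
        assert sorted(sizes) == self._brute_force(mask, connectivity)

    def test_diagonal_rule(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True  # in-plane diagonal: order 2
        assert len(label_clusters(mask, 6)[1]) == 2
        assert len(label_clusters(mask, 18)[1]) == 1

    def test_validation(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_clusters(np.zeros((2, 2, 2), bool), 10)
        with pytest.raises(ValueError, match="3D"):
            label_clusters(np.zeros((2, 2), bool))


class TestFDR:
    def test_matches_manual_step_up(self, rng):
        # [DERIVED] brute-force BH: largest k with p_(k) <= k q / m
        p = rng.random(20)
        out = fdr_bh(p, q=0.1)
        m = p.size
        order = np.argsort(p)
        thresh = 0.1 * (np.arange(1, m + 1)) / m
        passing = np.flatnonzero(p[order] <= thresh)
        expected = np.zeros(m, bool)
        if passing.size:
            expected[order[: passing.max() + 1]] = True
        np.testing.assert_array_equal(out.significant, expected)

    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_bh(np.array([]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestClusterInference:
    def _blob_data(self, rng, grid=(6, 6, 5), n=12, amp=1.5):
        vol = np.zeros(grid)
        vol[1:4, 1:4, 1:3] = amp
        base = vol.ravel()
        return base + 0.5 * rng.standard_normal((n, base.size))

    def test_detects_planted_blob(self, rng):
        grid = (6, 6, 5)
        data = self._blob_data(rng)
        table = cluster_inference(data, grid, cdt_p=0.01, n_perm=199, seed=0)
        assert table.significant(alpha=0.05)
        biggest = table.clusters[0]
        assert biggest.peak_stat > 0
        assert biggest.n_voxels >= 10

    def test_p_fwe_floor(self, rng):
        grid = (6, 6, 5)
        data = self._blob_data(rng)
        table = cluster_inference(data, grid, cdt_p=0.01, n_perm=99, seed=1)
        for c in table.clusters:
            assert c.p_fwe >= 1.0 / 100.0

    def test_negative_clusters_labelled(self, rng):
        grid = (6, 6, 5)
        data = -self._blob_data(rng)
        table = cluster_inference(data, grid, cdt_p=0.01, n_perm=99, seed=2)
        assert table.clusters[0].peak_stat < 0

    def test_condition_swap_two_groups(self, rng):
        grid = (5, 5, 4)
        n_vox = int(np.prod(grid))
        a = rng.standard_normal((10, n_vox)) + 1.2
        b = rng.standard_normal((10, n_vox))
        table = cluster_inference(
            a, grid, cdt_p=0.01, n_perm=99, scheme="condition_swap",
            data_b=b, seed=3,
        )
        assert table.n_permutations == 99

    def test_score_permute_runs(self, rng):
        grid = (4, 4, 4)
        data = rng.standard_normal((12, 64))
        score = rng.standard_normal(12)
        table = cluster_inference(
            data, grid, cdt_p=0.05, n_perm=99, scheme="score_permute",
            score=score, seed=4,
        )
        assert table.connectivity_rule == 18

    def test_mask_restricts_columns(self, rng):
        grid = (5, 5, 4)
        mask = np.zeros(grid, bool)
        mask[1:4, 1:4, 1:3] = True
        data = rng.standard_normal((10, int(mask.sum())))
        table = cluster_inference(data, grid, mask=mask, cdt_p=0.05,
                                  n_perm=99, seed=5)
        assert table.labels.shape == grid
        assert not table.labels[~mask].any()

    def test_argument_validation(self, rng):
        data = rng.standard_normal((8, 27))
        with pytest.raises(ValueError, match="99"):
            cluster_inference(data, (3, 3, 3), n_perm=50)
        with pytest.raises(ValueError, match="data_b"):
            cluster_inference(data, (3, 3, 3), scheme="condition_swap", n_perm=99)
        with pytest.raises(ValueError, match="score"):
            cluster_inference(data, (3, 3, 3), scheme="score_permute", n_perm=99)
        with pytest.raises(ValueError, match="scheme"):
            cluster_inference(data, (3, 3, 3), scheme="bogus", n_perm=99)
        with pytest.raises(ValueError, match="columns"):
            cluster_inference(rng.standard_normal((8, 20)), (3, 3, 3), n_perm=99)

    def test_multi_condition_uses_rm_anova(self, rng):
        grid = (4, 4, 3)
        data = rng.standard_normal((9, 3, 48))
        data[:, 1, :10] += 1.5
        table = cluster_inference(
            data, grid, cdt_p=0.05, n_perm=99, scheme="condition_swap", seed=6
        )
        assert isinstance(table.clusters, list)
        with pytest.raises(ValueError, match="condition_swap"):
            cluster_inference(data, grid, n_perm=99, scheme="sign_flip")
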