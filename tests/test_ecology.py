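"""Community-ecology statistics: distances, clustering, CCA, PERMANOVA, bins."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from mgii import ecology as ec


class TestBrayCurtis:
    def test_identical_and_disjoint_vectors(self):
        m = pd.DataFrame({"s1": [2, 0], "s2": [2, 0], "s3": [0, 5]},
                         index=["t1", "t2"])
        d = ec.bray_curtis(m, axis="samples")
        assert d[("s1", "s2")] == 0.0
        assert d[("s1", "s3")] == 1.0

    def test_hand_computed_value(self):
        m = pd.DataFrame({"s1": [2, 1], "s2": [1, 3]}, index=["t1", "t2"])
        d = ec.bray_curtis(m, axis="samples")
        assert d[("s1", "s2")] == pytest.approx(3 / 7)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ec.bray_curtis(pd.DataFrame({"s": [-1.0, 2.0]}), axis="taxa")

    def test_all_zero_pair_defined_as_zero(self, caplog):
        m = pd.DataFrame({"s1": [0, 0], "s2": [0, 0], "s3": [1, 2]},
                         index=["t1", "t2"])
        d = ec.bray_curtis(m, axis="samples")
        assert d[("s1", "s2")] == 0.0

    def test_range_and_symmetry(self, rng):
        m = pd.DataFrame(rng.random((6, 8)) * 5)
        d = ec.bray_curtis(m, axis="taxa")
        assert ((d.data >= 0) & (d.data <= 1)).all()
        assert np.allclose(d.data, d.data.T)


class TestAverageLinkage:
    def test_two_items(self):
        d = ec.DistanceMatrix(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        dend = ec.average_linkage(d)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.4)

    def test_three_item_forced_order(self):
        data = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dend = ec.average_linkage(ec.DistanceMatrix(data, ["A", "B", "C"]))
        assert dend.merges[0][2] == pytest.approx(0.1)
        assert dend.merges[1][2] == pytest.approx(0.9)
        assert set(dend.merges[0][3]) == {"A", "B"}

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_scipy_average_linkage(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 7))
        pts = rng.random((n, 3))
        from scipy.spatial.distance import pdist
        condensed = pdist(pts)
        labels = [f"x{i}" for i in range(n)]
        dend = ec.average_linkage(ec.DistanceMatrix(squareform(condensed), labels))
        ref = linkage(condensed, method="average")
        assert np.allclose(sorted(h for _, _, h, _ in dend.merges),
                           sorted(ref[:, 2]), atol=1e-12)
        for h in np.linspace(0.05, 1.2, 7):
            mine = {frozenset(c) for c in dend.cut(h)}
            flat = fcluster(ref, t=h - 1e-12, criterion="distance")
            theirs = {}
            for lab, cid in zip(labels, flat):
                theirs.setdefault(cid, set()).add(lab)
            assert mine == {frozenset(v) for v in theirs.values()}

    def test_heights_non_decreasing(self, rng):
        pts = rng.random((8, 4))
        from scipy.spatial.distance import pdist
        d = squareform(pdist(pts))
        dend = ec.average_linkage(ec.DistanceMatrix(d, [f"x{i}" for i in range(8)]))
        heights = [h for _, _, h, _ in dend.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            ec.average_linkage(ec.DistanceMatrix(np.zeros((1, 1)), ["a"]))


class TestCutDendrogram:
    def _dend(self):
        data = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        return ec.average_linkage(ec.DistanceMatrix(data, ["a", "b", "c"]))

    def test_above_root_single_cluster(self):
        dend = self._dend()
        assert dend.cut(dend.root_height + 0.01) == [{"a", "b", "c"}]

    def test_zero_height_all_singletons(self):
        assert sorted(map(sorted, self._dend().cut(0.0))) == [["a"], ["b"], ["c"]]

    def test_intermediate_cut(self):
        assert {frozenset(c) for c in self._dend().cut(0.5)} == \
            {frozenset({"a", "b"}), frozenset({"c"})}


def _planted_block_matrix(rng, n_taxa=12, n_samples=20, block_taxa=4,
                          block_samples=8, level=1.0, background=0.2,
                          sparsity=0.5, second_block=False):
    """Sparse background with one (or two) dense high-RPKM blocks."""
    m = rng.uniform(0, background, size=(n_taxa, n_samples))
    m[rng.random((n_taxa, n_samples)) < sparsity] = 0.0
    m[:block_taxa, :block_samples] = rng.uniform(0.9, 1.1, (block_taxa, block_samples)) * level
    if second_block:
        m[-block_taxa:, -block_samples:] = rng.uniform(0.9, 1.1,
                                                       (block_taxa, block_samples)) * level
    return pd.DataFrame(m, index=[f"t{i:02d}" for i in range(n_taxa)],
                        columns=[f"s{j:02d}" for j in range(n_samples)])


class TestEcologicalClusters:
    def test_single_hot_block_recovered(self, rng):
        m = _planted_block_matrix(rng)
        clusters = ec.ecological_clusters(m)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.taxa == {f"t{i:02d}" for i in range(4)}
        assert c.samples == {f"s{j:02d}" for j in range(8)}
        assert c.elevation >= 4.0

    def test_uniform_matrix_yields_nothing(self):
        m = pd.DataFrame(np.ones((6, 10)), index=[f"t{i}" for i in range(6)])
        assert ec.ecological_clusters(m) == []

    def test_two_disjoint_blocks(self, rng):
        m = _planted_block_matrix(rng, second_block=True)
        clusters = ec.ecological_clusters(m)
        assert len(clusters) == 2
        assert clusters[0].taxa.isdisjoint(clusters[1].taxa)

    def test_all_zero_matrix(self):
        m = pd.DataFrame(np.zeros((4, 4)))
        assert ec.ecological_clusters(m) == []


class TestCCA:
    def _data(self):
        rng = np.random.default_rng(42)
        y = rng.poisson(5, size=(10, 6)).astype(float)
        env = pd.DataFrame({"temp": rng.uniform(5, 25, 10),
                            "oxy": rng.uniform(100, 250, 10)})
        ab = pd.DataFrame(y, index=[f"s{i}" for i in range(10)],
                          columns=[f"t{j}" for j in range(6)])
        env.index = ab.index
        return ab, env

    def test_matches_independent_reference_values(self):
        # reference eigenvalues computed with vegan::cca on the same matrix
        ab, env = self._data()
        res = ec.cca(ab, env)
        assert res.eigenvalues == pytest.approx([0.01141002, 0.00304998], abs=1e-6)
        assert res.total_inertia == pytest.approx(0.1344755, abs=1e-5)

    def test_eigenvalues_non_increasing_and_fractions_sum_to_one(self):
        ab, env = self._data()
        res = ec.cca(ab, env)
        assert all(a >= b for a, b in zip(res.eigenvalues, res.eigenvalues[1:]))
        assert res.axis_fractions.sum() == pytest.approx(1.0)

    def test_collinear_variable_dropped(self):
        ab, env = self._data()
        env = env.copy()
        env["temp2"] = env["temp"] * 2 + 1
        res = ec.cca(ab, env)
        assert "temp2" not in res.variables

    def test_incomplete_samples_dropped(self):
        ab, env = self._data()
        env = env.copy()
        env.iloc[0, 0] = np.nan
        res = ec.cca(ab, env)
        assert len(res.site_scores) == 9

    def test_requires_two_variables(self):
        ab, env = self._data()
        with pytest.raises(ValueError):
            ec.cca(ab, env[["temp"]])


class TestPermanova:
    def _toy(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.0, 1, (3, 2))])
        from scipy.spatial.distance import pdist
        d = squareform(pdist(pts))
        labels = [f"o{i}" for i in range(6)]
        groups = {l: ("g1" if i < 3 else "g2") for i, l in enumerate(labels)}
        return ec.DistanceMatrix(d, labels), groups

    def test_p_matches_exhaustive_enumeration(self):
        dist, groups = self._toy()
        d2 = dist.data ** 2
        f_obs = None
        fs = []
        for combo in itertools.combinations(range(6), 3):
            idx1 = np.array(combo)
            idx2 = np.array([i for i in range(6) if i not in combo])
            f = ec._pseudo_f(d2, [idx1, idx2])
            fs.append(f)
            if combo == (0, 1, 2):
                f_obs = f
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        res = ec.permanova(dist, groups, n_perm=4999, seed=0)
        assert res.pseudo_f == pytest.approx(f_obs)
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_p_floor_and_seed_reproducibility(self):
        dist, groups = self._toy()
        r1 = ec.permanova(dist, groups, n_perm=99, seed=3)
        r2 = ec.permanova(dist, groups, n_perm=99, seed=3)
        assert r1.p == r2.p
        assert r1.p >= 1 / 100

    def test_perfect_separation_gives_minimal_p(self):
        d = np.ones((6, 6)) - np.eye(6)
        d[:3, :3] = 0; d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        dist = ec.DistanceMatrix(d, [f"o{i}" for i in range(6)])
        groups = {f"o{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = ec.permanova(dist, groups, n_perm=999, seed=1)
        assert res.p == pytest.approx(0.1, abs=0.03)  # 2/20 assignments tie the max F

    def test_small_group_rejected(self):
        dist, groups = self._toy()
        groups = dict(groups)
        groups["o5"] = "g3"
        with pytest.raises(ValueError):
            ec.permanova(dist, groups, n_perm=9)


class TestPairwisePermanova:
    def test_three_groups_three_pairs_with_bonferroni(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(i * 2, 0.5, (4, 2)) for i in range(3)])
        from scipy.spatial.distance import pdist
        d = squareform(pdist(pts))
        labels = [f"o{i}" for i in range(12)]
        groups = {l: f"g{i // 4}" for i, l in enumerate(labels)}
        out = ec.pairwise_permanova(ec.DistanceMatrix(d, labels), groups,
                                    n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["p_bonferroni"] <= 1.0).all()
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, out["p"] * 3))


class TestBHFDR:
    def test_closed_form_example(self):
        assert ec.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert ec.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 15)))
            mine = ec.bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, ref)
            assert (mine >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ec.bh_fdr([0.5, 1.5])


class TestEnvironmentalBins:
    def test_printed_bin_examples(self):
        meta = pd.DataFrame({
            "temperature": [15.0, 10.0, 20.0, 9.9, 20.1],
            "oxygen": [110.0, 159.0, 160.0, 159.4, 159.6],
            "phosphate": ["BDL", 0.4, 0.5, 2.0, 2.1],
            "nitrate": [0.3, 1.9, 1.95, 2.0, 6.0],
        })
        bins = ec.bin_environment(meta)
        assert list(bins["temperature"]) == ["10-20", "10-20", "10-20", "<10", ">20"]
        assert list(bins["oxygen"]) == ["110-159", "110-159", "160-200",
                                        "110-159", "160-200"]
        assert list(bins["phosphate"]) == ["BDL", "<0.5", "0.5-2.0", "0.5-2.0", ">2.0"]
        assert list(bins["nitrate"]) == ["<0.5", "0.5-1.9", "0.5-1.9", "2.0-5.0", ">5.0"]

    def test_gap_tie_goes_to_lower_bin(self):
        meta = pd.DataFrame({"oxygen": [159.5]})
        assert ec.bin_environment(meta)["oxygen"].iloc[0] == "110-159"

    def test_missing_left_unbinned(self):
        meta = pd.DataFrame({"temperature": [np.nan, 12.0]})
        bins = ec.bin_environment(meta)
        assert pd.isna(bins["temperature"].iloc[0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ec.bin_environment(pd.DataFrame({"phosphate": [-0.1]}))

    def test_bdl_on_nonnutrient_rejected(self):
        with pytest.raises(ValueError):
            ec.bin_environment(pd.DataFrame({"temperature": ["BDL"]}))


class TestWelchT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = ec.welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_manual_satterthwaite_df(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 9.0]
        t, df, p = ec.welch_t(x, y)
        vx, vy = np.var(x, ddof=1) / 4, np.var(y, ddof=1) / 3
        df_manual = (vx + vy) ** 2 / (vx ** 2 / 3 + vy ** 2 / 2)
        assert df == pytest.approx(df_manual)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ec.welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ec.welch_t([2.0, 2.0], [3.0, 3.0])
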