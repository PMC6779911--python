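"""Distance conventions, UPGMA correctness, dendrogram cuts, RT summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from nitrosense import design
from nitrosense.rtbin import (
    assign_rts,
    average_linkage,
    cut_to_k,
    label_ns_rts,
    pattern_distance_matrix,
    summarize_rts,
    to_newick,
)


def brute_force_upgma_heights(d):
    """Quadratic reference: recompute all cross-pair means at every step."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                m = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if m < best[0] - 1e-15:
                    best = (m, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestDistance:
    def test_identical_nonconstant_zero(self):
        d = pattern_distance_matrix([[1, 0, -1], [1, 0, -1]])
        assert d[0, 1] == pytest.approx(0.0)

    def test_antipodal_two(self):
        d = pattern_distance_matrix([[1, 0, -1, 0], [-1, 0, 1, 0]])
        assert d[0, 1] == pytest.approx(2.0)

    def test_hand_computed_pearson(self):
        u = np.array([1.0, 0.0, -1.0, 0.0])
        v = np.array([0.0, 1.0, 0.0, -1.0])
        uc, vc = u - u.mean(), v - v.mean()
        r = (uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc))
        d = pattern_distance_matrix([u, v])
        assert d[0, 1] == pytest.approx(1.0 - r)

    def test_constant_conventions(self):
        d = pattern_distance_matrix([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 0, -1]])
        assert d[0, 1] == 0.0        # identical constants
        assert d[0, 2] == 1.0        # different constants
        assert d[0, 3] == 1.0        # constant vs responder

    def test_shift_scale_invariance(self, rng):
        x = rng.normal(size=(6, 10))
        d1 = pattern_distance_matrix(x)
        d2 = pattern_distance_matrix(3.5 * x + 2.0)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pattern_distance_matrix(np.array([1, 2, 3]))


class TestUPGMA:
    def test_forced_merge_order(self):
        d = np.array([[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]])
        dendro = average_linkage(d)
        assert dendro.merges[0][2] == pytest.approx(0.1)
        assert set(dendro.merges[0][:2]) == {0, 1}
        assert dendro.merges[1][2] == pytest.approx(1.0)

    def test_duplicates_merge_first_at_zero(self):
        d = pattern_distance_matrix([[1, 0, -1], [1, 0, -1], [0, 1, 0]])
        dendro = average_linkage(d)
        assert dendro.merges[0][2] == pytest.approx(0.0, abs=1e-12)
        assert set(dendro.merges[0][:2]) == {0, 1}

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            n = 8
            x = rng.random((n, 5))
            d = squareform(squareform(np.abs(x[:, None, :] - x[None, :, :]).sum(-1)))
            np.fill_diagonal(d, 0)
            dendro = average_linkage(d)
            np.testing.assert_allclose(
                dendro.merges[:, 2], brute_force_upgma_heights(d), rtol=1e-10
            )

    def test_matches_scipy_linkage(self, rng):
        d = squareform(rng.random(28))
        dendro = average_linkage(d)
        z = linkage(squareform(d), method="average")
        np.testing.assert_allclose(dendro.merges[:, 2], z[:, 2], rtol=1e-10)

    def test_multiplicity_weights_equal_duplicated_points(self, rng):
        """Weighted UPGMA on unique items == plain UPGMA on duplicates."""
        base = rng.random((4, 3))
        mult = [3, 1, 2, 1]
        full = np.repeat(base, mult, axis=0)
        d_full = squareform(squareform(
            np.abs(full[:, None, :] - full[None, :, :]).sum(-1)))
        d_base = np.abs(base[:, None, :] - base[None, :, :]).sum(-1)
        np.fill_diagonal(d_base, 0)
        weighted = average_linkage(d_base, sizes=mult)
        plain = average_linkage(d_full)
        nonzero = plain.merges[plain.merges[:, 2] > 1e-12, 2]
        np.testing.assert_allclose(weighted.merges[:, 2], nonzero, rtol=1e-10)

    def test_nan_errors(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            average_linkage(d)


class TestCut:
    @pytest.fixture
    def dendro(self, rng):
        d = squareform(rng.random(45))
        return average_linkage(d)

    def test_every_k_yields_exactly_k(self, dendro):
        n = dendro.n_leaves
        for k in range(1, n + 1):
            labels = cut_to_k(dendro, k)
            assert len(np.unique(labels)) == k

    def test_extremes(self, dendro):
        assert len(np.unique(cut_to_k(dendro, 1))) == 1
        n = dendro.n_leaves
        assert len(np.unique(cut_to_k(dendro, n))) == n

    def test_k_out_of_range(self, dendro):
        with pytest.raises(ValueError):
            cut_to_k(dendro, dendro.n_leaves + 1)

    def test_identical_patterns_never_split(self):
        pats = pd.DataFrame(
            [[1, 0, -1]] * 5 + [[0, 1, 0]] * 3 + [[-1, -1, 1]] * 2,
            index=[f"g{i}" for i in range(10)],
        )
        for k in (1, 2, 3):
            rt = assign_rts(pats, k=k)
            for pattern, grp in pats.groupby(list(pats.columns)):
                assert rt.loc[grp.index].nunique() == 1


class TestAssign:
    def test_order_invariance_up_to_relabel(self, rng):
        pats = pd.DataFrame(
            rng.integers(-1, 2, (60, 12)), index=[f"g{i}" for i in range(60)]
        )
        rt1 = assign_rts(pats, k=8)
        perm = rng.permutation(60)
        rt2 = assign_rts(pats.iloc[perm], k=8).reindex(rt1.index)
        # same partition: co-membership matrices agree
        m1 = rt1.to_numpy()[:, None] == rt1.to_numpy()[None, :]
        m2 = rt2.to_numpy()[:, None] == rt2.to_numpy()[None, :]
        assert (m1 == m2).all()

    def test_k_larger_than_unique_patterns(self):
        pats = pd.DataFrame([[1, 0], [0, 1], [1, 0]], index=["a", "b", "c"])
        rt = assign_rts(pats, k=10)
        assert rt.nunique() == 2


class TestSummaries:
    def _cond_frame(self, rows, genes):
        return pd.DataFrame(rows, index=genes, columns=list(design.CONDITIONS))

    def test_single_gene_rt_is_its_zscore(self, rng):
        x = rng.normal(size=(1, 15))
        cond = self._cond_frame(x, ["g1"])
        prof = summarize_rts(cond, pd.Series({"g1": 1}))
        z = (x[0] - x[0].mean()) / x[0].std()
        np.testing.assert_allclose(prof.loc[1, list(design.CONDITIONS)], z, atol=1e-12)

    def test_constant_gene_zero_profile(self):
        cond = self._cond_frame(np.ones((1, 15)), ["g1"])
        prof = summarize_rts(cond, pd.Series({"g1": 1}))
        assert (prof.loc[1, list(design.CONDITIONS)] == 0).all()

    def test_two_gene_rt_is_elementwise_mean(self, rng):
        x = rng.normal(size=(2, 15))
        cond = self._cond_frame(x, ["g1", "g2"])
        prof = summarize_rts(cond, pd.Series({"g1": 1, "g2": 1}))
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        np.testing.assert_allclose(
            prof.loc[1, list(design.CONDITIONS)], z.mean(0), atol=1e-12
        )


class TestNSRTLabels:
    def _profile(self, no3=0.0, nh4=0.0, no2=0.0, non=0.0):
        row = {c: 0.0 for c in design.CONDITIONS}
        for tp in ("15min", "45min"):
            row[f"NO3_{tp}"] = no3
            row[f"NH4_{tp}"] = nh4
            row[f"NO2_{tp}"] = no2
            row[f"noN_{tp}"] = non
        return pd.DataFrame([row], index=[1])

    def test_nitrate_elevated_flagged(self):
        assert label_ns_rts(self._profile(no3=2.0, nh4=-0.5, no2=0.0, non=-1.0)).loc[1]

    def test_flat_not_flagged(self):
        assert not label_ns_rts(self._profile()).loc[1]

    def test_margin(self):
        prof = self._profile(no3=0.3)
        assert label_ns_rts(prof, margin=0.0).loc[1]
        assert not label_ns_rts(prof, margin=0.5).loc[1]

    def test_missing_condition_errors(self):
        with pytest.raises(ValueError):
            label_ns_rts(pd.DataFrame([[1.0]], columns=["NO3_15min"]))

    def test_planted_genes_concentrate_in_flagged_rts(self, small_dataset, small_transcriptome):
        truth = small_dataset.truth.set_index("gene_id")
        planted = truth.index[truth["archetype"] == "nitrate_specific"]
        flags = small_transcriptome["ns_rt_flags"]
        assert flags.any()
        rt = small_transcriptome["rt"]
        in_flagged = rt.loc[planted].isin(flags[flags].index)
        assert in_flagged.mean() >= 0.8


def test_newick_export_is_parseable(rng):
    import io as _io

    from Bio import Phylo

    d = squareform(rng.random(10))
    dendro = average_linkage(d)
    nwk = to_newick(dendro, [f"g{i}" for i in range(5)])
    tree = Phylo.read(_io.StringIO(nwk), "newick")
    assert tree.count_terminals() == 5
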