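"""Distances, Ward trees, bootstrap support and projection of new samples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tascore as tc
from tascore.errors import InvalidConfigError, UndefinedDistanceError


def frame(rows, index=None):
    arr = np.asarray(rows, dtype=float)
    idx = index or [f"o{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=idx)


class TestCosangle:
    def test_scale_invariance_orthogonality_antipode(self):
        d = tc.cosangle_distance(frame([[1, 0], [2, 0], [0, 1], [-1, 0]]))
        m = d.to_frame()
        assert m.at["o0", "o1"] == pytest.approx(0.0, abs=1e-12)
        assert m.at["o0", "o2"] == pytest.approx(1.0)
        assert m.at["o0", "o3"] == pytest.approx(2.0)

    @given(
        arrays(np.float64, (4, 6), elements=st.floats(-50, 50)),
        st.floats(0.1, 20),
    )
    def test_bounded_and_rescale_invariant(self, x, alpha):
        norms = np.linalg.norm(x, axis=1)
        if np.any(norms < 1e-6):
            return
        d1 = tc.cosangle_distance(frame(x)).values
        scaled = x.copy()
        scaled[0] *= alpha
        d2 = tc.cosangle_distance(frame(scaled)).values
        assert np.all(d1 >= 0) and np.all(d1 <= 2)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_pairwise_complete_missing(self):
        x = frame([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        x.iloc[0, 0] = np.nan
        d = tc.cosangle_distance(x)
        # rows 0 and 1 agree on their 3 shared coordinates
        assert d.to_frame().at["o0", "o1"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_shared_coordinates(self):
        x = frame([[np.nan, np.nan, 1, 2], [3, 4, np.nan, np.nan], [1, 1, 1, 1]])
        with pytest.raises(UndefinedDistanceError):
            tc.cosangle_distance(x)

    def test_zero_norm_row_named(self):
        with pytest.raises(UndefinedDistanceError, match="o1"):
            tc.cosangle_distance(frame([[1, 2], [0, 0]]))


def test_binary_label_distance_matches_label_identity():
    d = tc.binary_label_distance(pd.Series({"a": "lung", "b": "lung", "c": "blood"}))
    m = d.to_frame()
    assert m.at["a", "b"] == 0.0 and m.at["a", "c"] == 1.0
    same = tc.binary_label_distance(pd.Series({"a": "x", "b": "x"}))
    assert same.values.sum() == 0.0
    distinct = tc.binary_label_distance(pd.Series({"a": "x", "b": "y", "c": "z"}))
    assert distinct.values.sum() == 6.0  # all off-diagonal ones


def test_profile_distance_labels_dispatch(small_tas):
    tas, _, _ = small_tas
    for label in ("cosangle", "euclidean", "manhattan", "pearson", "spearman"):
        d = tc.profile_distance(tas.data, label)
        assert d.label == label
        assert np.allclose(d.values, d.values.T)


class TestWard:
    def test_two_objects_single_merge(self):
        d = tc.cosangle_distance(frame([[1, 0], [0, 1]]))
        tree = tc.ward_cluster(d)
        assert tree.linkage.shape == (1, 4)
        assert tree.root_height == pytest.approx(1.0)

    def test_nearest_pair_merges_first(self):
        x = frame([[1.0, 0.01], [1.0, 0.02], [0.0, 5.0]])
        tree = tc.ward_cluster(tc.cosangle_distance(x))
        assert tree.clades()[0] == frozenset({"o0", "o1"})

    def test_heights_nondecreasing(self, small_tas):
        tas, _, _ = small_tas
        tree = tc.ward_cluster(tc.cosangle_distance(tas.data))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_newick_round_trips_leaves(self, small_tas):
        import dendropy

        tas, _, _ = small_tas
        tree = tc.ward_cluster(tc.cosangle_distance(tas.data))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
            tree.leaf_ids
        )


class TestCut:
    def test_extreme_cuts(self, small_tas):
        tas, _, _ = small_tas
        tree = tc.ward_cluster(tc.cosangle_distance(tas.data))
        n = tree.n_leaves
        assert tc.cut_clusters(tree, 1).nunique() == 1
        assert tc.cut_clusters(tree, n).nunique() == n
        with pytest.raises(InvalidConfigError):
            tc.cut_clusters(tree, 0)

    def test_planted_clusters_recovered(self, small_tas):
        from sklearn.metrics import adjusted_rand_score

        tas, truth, _ = small_tas
        tree = tc.ward_cluster(tc.cosangle_distance(tas.data))
        labels = tc.cut_clusters(tree, truth.cluster_labels.nunique())
        assert adjusted_rand_score(truth.cluster_labels[labels.index], labels) == 1.0


class TestBootstrap:
    def test_duplicated_blocks_fully_supported(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(4, 10))
        x = frame(np.vstack([block + 10, block - 10]))
        sup = tc.bootstrap_support(x, "euclidean", n_boot=50, seed=1)
        top = frozenset({"o0", "o1", "o2", "o3"}), frozenset({"o4", "o5", "o6", "o7"})
        tab = sup.table.set_index("members")
        for t in top:
            assert tab.at[";".join(sorted(t)), "probability"] == 1.0

    def test_seed_determinism(self, small_tas):
        tas, _, _ = small_tas
        a = tc.bootstrap_support(tas.data, n_boot=25, seed=7).table
        b = tc.bootstrap_support(tas.data, n_boot=25, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_noise_has_weak_midtree_support(self):
        rng = np.random.default_rng(3)
        x = frame(rng.normal(size=(12, 30)))
        sup = tc.bootstrap_support(x, "euclidean", n_boot=200, seed=0)
        mid = sup.table.iloc[1:-1]  # exclude first merge and root
        assert mid["probability"].mean() < 0.5

    def test_single_feature_rejected(self):
        with pytest.raises(InvalidConfigError):
            tc.bootstrap_support(frame([[1.0], [2.0]]), n_boot=10)

    def test_probabilities_within_unit_interval(self, small_tas):
        tas, _, _ = small_tas
        sup = tc.bootstrap_support(tas.data, n_boot=30, seed=2)
        assert sup.table["probability"].between(0, 1).all()
        # the root contains all leaves in every replicate
        assert sup.table.iloc[-1]["probability"] == 1.0


class TestWeightedRobustness:
    def test_height_weighting_formula(self):
        leaf_ids = ["a", "b", "c"]
        linkage = np.array([[0.0, 1.0, 0.0, 2.0], [2.0, 3.0, 2.0, 3.0]])
        tree = tc.Dendrogram(leaf_ids=leaf_ids, linkage=linkage)
        vals = tc.weighted_robustness([0.8, 0.9], tree)
        assert vals[0] == pytest.approx(0.8 * 0.1)  # h = 0 floor
        assert vals[1] == pytest.approx(0.9 * 1.0)  # root
        linkage_mid = np.array([[0.0, 1.0, 1.0, 2.0], [2.0, 3.0, 2.0, 3.0]])
        tree_mid = tc.Dendrogram(leaf_ids=leaf_ids, linkage=linkage_mid)
        assert tc.weighted_robustness([0.8, 1.0], tree_mid)[0] == pytest.approx(0.44)


class TestProjection:
    def test_identical_sample_maximal_similarity(self):
        rng = np.random.default_rng(2)
        ref = pd.DataFrame(
            rng.normal(5, 1, size=(8, 6)), index=[f"R{i}" for i in range(8)]
        )
        new = ref.iloc[[0]].rename(index={"R0": "N0"})
        aux = pd.DataFrame(
            rng.normal(size=(9, 20)), index=list(ref.index) + ["N0"]
        )
        aux.loc["N0"] = aux.loc["R0"]
        # k = n-1: the duplicated pair is the only non-singleton cluster
        res = tc.project_and_correlate(ref, new, aux, k=8)
        assert res.at["N0", "n_comembers"] == 1
        assert res.at["N0", "mean_spearman"] == pytest.approx(1.0)
        n_pairs = 8 * 7 // 2
        assert res.at["N0", "p_value"] <= 2.0 / (1.0 + n_pairs)

    def test_planted_aux_structure_beats_background(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(2, 30))
        ref_rows, aux_rows, ids = [], [], []
        for g in range(2):
            for i in range(6):
                ids.append(f"R{g}{i}")
                ref_rows.append(np.concatenate([np.full(5, 10.0 * (g == j)) for j in range(2)]) + rng.normal(0, 0.3, 10))
                aux_rows.append(base[g] + rng.normal(0, 0.4, 30))
        new_ids = ["N0", "N1"]
        for g, n in enumerate(new_ids):
            ref_rows.append(np.concatenate([np.full(5, 10.0 * (g == j)) for j in range(2)]) + rng.normal(0, 0.3, 10))
            aux_rows.append(base[g] + rng.normal(0, 0.4, 30))
        ref = pd.DataFrame(ref_rows[:12], index=ids)
        new = pd.DataFrame(ref_rows[12:], index=new_ids)
        aux = pd.DataFrame(aux_rows, index=ids + new_ids)
        res = tc.project_and_correlate(ref, new, aux, k=2)
        background = []
        from scipy.stats import spearmanr

        rho = spearmanr(aux.loc[ids].to_numpy(), axis=1)[0]
        iu = np.triu_indices(len(ids), 1)
        background = rho[iu].mean()
        # within-cluster aux similarity beats the background mean (which
        # itself mixes same- and different-group pairs, so p is judged only
        # against chance level)
        assert (res["mean_spearman"] > background).all()
        assert (res["p_value"] < 0.5).all()
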