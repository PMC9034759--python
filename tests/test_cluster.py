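"""Ward clustering, summaries, layer annotation, embedding, Newick export."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lobtype import cluster as cl
from lobtype.exceptions import InvalidArgumentError


class TestWard:
    def test_first_merge_of_1d_points_at_unit_height(self):
        """Lance-Williams hand check: on {0, 1, 10} the first merge joins 0 and 1 at height 1."""
        X = np.array([[0.0], [1.0], [10.0]])
        a = cl.ward_cluster(X, K=1)
        first = a.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(1.0)

    def test_heights_non_decreasing(self, rng):
        X = rng.normal(0, 1, (60, 5))
        a = cl.ward_cluster(X, K=3)
        assert np.all(np.diff(a.linkage[:, 2]) >= -1e-12)

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(0, 1, (12, 3))
        a = cl.ward_cluster(X, K=12)
        assert sorted(a.labels.values()) == list(range(1, 13))

    def test_k_one_gives_single_cluster(self, rng):
        X = rng.normal(0, 1, (12, 3))
        a = cl.ward_cluster(X, K=1)
        assert set(a.labels.values()) == {1}

    def test_two_separated_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (30, 4)), rng.normal(20, 0.5, (25, 4))])
        a = cl.ward_cluster(X, K=2)
        labels = a.label_array()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_labels_numbered_by_dendrogram_leaf_order(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(20, 0.5, (10, 2))])
        a = cl.ward_cluster(X, K=2)
        from scipy.cluster.hierarchy import leaves_list

        first_leaf = leaves_list(a.linkage)[0]
        assert a.label_array()[first_leaf] == 1

    def test_permutation_invariance_of_partition(self, rng):
        X = rng.normal(0, 1, (40, 6))
        a = cl.ward_cluster(X, K=5).label_array()
        perm = rng.permutation(40)
        b = cl.ward_cluster(X[perm], K=5).label_array()
        assert adjusted_rand_score(a[perm], b) == pytest.approx(1.0)

    @pytest.mark.parametrize("K", [0, 13])
    def test_k_out_of_range_rejected(self, rng, K):
        X = rng.normal(0, 1, (12, 3))
        with pytest.raises(InvalidArgumentError):
            cl.ward_cluster(X, K=K)

    def test_cut_to_k_extremes(self, rng):
        X = rng.normal(0, 1, (10, 2))
        a = cl.ward_cluster(X, K=2)
        assert set(cl.cut_to_k(a.linkage, 1)) == {1}
        assert sorted(cl.cut_to_k(a.linkage, 10)) == list(range(1, 11))


class TestFixtureRecovery:
    def test_default_fixture_ari_at_true_k(self, fixture_sc, fitted_frame):
        """Full feature pipeline at K = number of generated types recovers them."""
        from lobtype import features as ft
        from lobtype.geometry import frame_points

        coi = sorted(fixture_sc.ground_truth)
        syn = fixture_sc.synapses
        pre = syn[(syn["polarity"] == "pre") & syn["cell_id"].isin(coi)]
        framed = frame_points(pre[["x", "y", "z"]].to_numpy(), fitted_frame)
        framed["cell_id"] = pre["cell_id"].to_numpy()
        idx = pd.Index(coi, name="cell_id")
        spreads, hists = [], []
        for cid in coi:
            g = framed[framed["cell_id"] == cid]
            spreads.append(ft.synapse_spread(g))
            hists.append(ft.smooth_depth_hist(ft.innervation_depth_hist(g["depth"].to_numpy())))
        fm = ft.assemble_feature_matrix(
            ft.connectivity_matrix(coi, fixture_sc.edges),
            pd.DataFrame(spreads, index=idx),
            pd.DataFrame(hists, index=idx),
        )
        a = cl.ward_cluster(fm, K=8)
        truth = [fixture_sc.ground_truth[c] for c in coi]
        assert adjusted_rand_score(truth, a.label_array()) >= 0.9

    def test_recovery_degrades_monotonically_with_noise(self):
        """Median ARI is non-increasing as generator scatter doubles."""
        from lobtype.bench import recover_types

        medians = []
        for scale in (1.0, 4.0, 16.0):
            aris = [recover_types(seed, K=8, noise_scale=scale).ari for seed in (1, 2, 3)]
            medians.append(float(np.median(aris)))
        assert medians[0] >= medians[1] >= medians[2]
        assert medians[0] >= 0.9


class TestSummaries:
    def test_mean_synapses_per_cell_arithmetic(self):
        edges = pd.DataFrame(
            {"source_id": [1, 2], "target_id": [9, 9], "target_type": ["LC17", "LC17"], "weight": [10, 4]}
        )
        hists = pd.DataFrame(np.ones((2, 14)), index=pd.Index([1, 2], name="cell_id"))
        spreads = pd.DataFrame(np.ones((2, 3)), index=hists.index, columns=["e1", "e2", "e3"])
        a = cl.ClusterAssignment(labels={1: 1, 2: 1}, linkage=np.zeros((1, 4)), K=1, cell_ids=[1, 2])
        s = cl.cluster_summary(a, hists, spreads, edges)[0]
        assert s["top_targets"] == [("LC17", 7.0)]
        assert s["n_cells"] == 2

    def test_cluster_without_edges_has_empty_targets(self):
        edges = pd.DataFrame(columns=["source_id", "target_id", "target_type", "weight"])
        hists = pd.DataFrame(np.ones((2, 14)), index=pd.Index([1, 2], name="cell_id"))
        spreads = pd.DataFrame(np.ones((2, 3)), index=hists.index, columns=["e1", "e2", "e3"])
        a = cl.ClusterAssignment(labels={1: 1, 2: 1}, linkage=np.zeros((1, 4)), K=1, cell_ids=[1, 2])
        s = cl.cluster_summary(a, hists, spreads, edges)[0]
        assert s["top_targets"] == []

    def test_top_targets_sorted_descending(self, fixture_sc, fitted_frame):
        ids = sorted(fixture_sc.ground_truth)[:60]  # one generated type
        hists = pd.DataFrame(np.ones((60, 14)), index=pd.Index(ids, name="cell_id"))
        spreads = pd.DataFrame(np.ones((60, 3)), index=hists.index, columns=["e1", "e2", "e3"])
        a = cl.ClusterAssignment(
            labels={c: 1 for c in ids}, linkage=np.zeros((59, 4)), K=1, cell_ids=ids
        )
        s = cl.cluster_summary(a, hists, spreads, fixture_sc.edges)[0]
        values = [v for _, v in s["top_targets"]]
        assert values == sorted(values, reverse=True)


class TestLayerAnnotation:
    def test_all_mass_in_one_layer(self):
        h = np.zeros(14)
        h[1] = 5.0  # [-15, -10) -> Lo1 with default boundaries
        fractions, dominant = cl.annotate_layers(h)
        assert fractions["Lo1"] == pytest.approx(1.0)
        assert dominant == ["Lo1"]

    def test_split_mass_reports_both_dominant(self):
        h = np.zeros(14)
        h[4] = 6.0   # [0, 5) -> Lo3
        h[1] = 4.0   # [-15, -10) -> Lo1
        fractions, dominant = cl.annotate_layers(h, dominance_threshold=0.25)
        assert fractions["Lo3"] == pytest.approx(0.6)
        assert set(dominant) == {"Lo1", "Lo3"}

    def test_uniform_histogram_fractions_proportional_to_widths(self):
        h = np.ones(14)
        fractions, _ = cl.annotate_layers(h)
        # layers spanning [-20,-10),[-10,0),[0,10),[10,20),[20,30),[30,50)
        assert fractions["Lo2"] == pytest.approx(10 / 70)
        assert fractions["Lo6"] == pytest.approx(20 / 70)

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cl.annotate_layers(np.ones(14), layer_boundaries=(0.0, -10.0, 10.0, 20.0, 30.0))


class TestEmbedding:
    def test_shape_determinism_and_separation(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (25, 5)), rng.normal(8, 0.3, (25, 5))])
        e1 = cl.embed_2d(X, seed=3)
        e2 = cl.embed_2d(X, seed=3)
        assert e1.shape == (50, 2)
        assert np.allclose(e1, e2)
        intra = np.linalg.norm(e1[:25] - e1[:25].mean(axis=0), axis=1).mean()
        inter = np.linalg.norm(e1[:25].mean(axis=0) - e1[25:].mean(axis=0))
        assert inter > intra

    def test_too_few_cells_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cl.embed_2d(np.zeros((3, 4)), seed=0)


class TestNewick:
    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        X = rng.normal(0, 1, (10, 3))
        a = cl.ward_cluster(X, K=2)
        names = [f"c{i}" for i in range(10)]
        nwk = cl.linkage_to_newick(a.linkage, names)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(names)
        # root-to-leaf distance equals the root merge height for every leaf
        root_h = a.linkage[-1, 2]
        for leaf in tree.leaf_node_iter():
            dist = leaf.distance_from_root()
            assert dist == pytest.approx(root_h, rel=1e-9)
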