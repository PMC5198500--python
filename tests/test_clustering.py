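"""Flat and hierarchical clustering heuristics, cutting, and evaluation."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from profclust import (ClusteringParams, ProfileSet, cut_dendrogram,
                       evaluate_selection, generate_profile_set, hash_cluster,
                       jury_rank, kmedoids_cluster, pairwise_hamming_matrix,
                       rand_index, rpart_cluster, tree_cluster)
from profclust.clustering import Dendrogram, initial_radius, write_clusters
from profclust.profiles import FrequencyProfile


def _labels_vs_truth(solution, ids, truth):
    lab = solution.labels(ids)
    mask = lab >= 0
    return rand_index(lab[mask], np.asarray(truth)[mask])


class TestHashCluster:
    def test_zero_noise_recovers_planted_groups_exactly(self):
        ps, truth = generate_profile_set(30, 50, 4, 3, 0.0, seed=2)
        sol = hash_cluster(ps, ClusteringParams(K=3, F=100))
        assert sol.coverage == 100.0
        assert not sol.unassigned
        assert rand_index(sol.labels(ps.ids), truth) == 1.0

    def test_k_equals_n_distinct_keys_gives_singletons(self):
        rng = np.random.default_rng(3)
        X = np.unique(rng.integers(0, 2, size=(20, 30)), axis=0)
        ps = ProfileSet.from_matrix(X, _binary())
        sol = hash_cluster(ps, ClusteringParams(K=len(X), F=100))
        assert sol.coverage == 100.0
        assert sorted(len(m) for m, _c in sol.clusters) == [1] * len(X)

    def test_planted_recovery_at_operating_coverage(self, planted_profiles):
        ps, truth = planted_profiles
        sol = hash_cluster(ps, ClusteringParams(K=3, F=60))
        assert sol.coverage >= 59.5
        assert _labels_vs_truth(sol, ps.ids, truth) >= 0.95

    def test_clusters_disjoint_and_coverage_exact(self, planted_profiles):
        ps, _ = planted_profiles
        sol = hash_cluster(ps, ClusteringParams(K=3, F=60))
        members = [m for ms, _c in sol.clusters for m in ms]
        assert len(members) == len(set(members))
        assert sol.coverage == pytest.approx(100.0 * len(members) / len(ps))
        for ms, cent in sol.clusters:
            assert cent in ms

    def test_largest_group_monotone_under_position_removal(self):
        """Coarsening the key by dropping any position can only merge
        groups, so the largest group never shrinks."""
        from profclust.hashing import group_by_key, make_hash_keys

        ps, _ = generate_profile_set(60, 20, 3, 3, 0.1, seed=8)
        ref = ps.profiles[ps.ids.index(jury_rank(ps).reference_id)]
        keys = make_hash_keys(ps, ref)
        all_pos = np.arange(ps.length)
        base = max(group_by_key(keys).sizes)
        for drop in range(ps.length):
            kept = np.delete(all_pos, drop)
            assert max(group_by_key(keys, positions=kept).sizes) >= base

    def test_k_exceeding_n_rejected(self, tiny_profiles):
        with pytest.raises(ValueError):
            hash_cluster(tiny_profiles, ClusteringParams(K=4, F=100))


def _binary():
    from profclust import Alphabet
    return Alphabet("binary", ("0", "1"))


class TestRpartCluster:
    def test_all_identical_profiles_single_cluster(self):
        ps = ProfileSet.from_matrix(np.zeros((6, 10), dtype=int), _binary())
        sol = rpart_cluster(ps, ClusteringParams(K=3, F=100))
        assert len(sol.clusters) == 1
        assert sol.coverage == 100.0

    def test_initial_radius_is_quarter_of_max_distance(self):
        assert initial_radius(40) == 10
        assert initial_radius(1) == 1

    def test_planted_centroids_in_distinct_clusters(self, planted_binary_profiles):
        ps, truth = planted_binary_profiles
        sol = rpart_cluster(ps, ClusteringParams(K=3, F=90))
        idx = {m: i for i, m in enumerate(ps.ids)}
        centroid_labels = {int(truth[idx[c]]) for c in sol.centroid_ids}
        assert centroid_labels == {0, 1, 2}
        assert _labels_vs_truth(sol, ps.ids, truth) >= 0.95

    def test_coverage_reaches_target(self, planted_binary_profiles):
        ps, _ = planted_binary_profiles
        sol = rpart_cluster(ps, ClusteringParams(K=3, F=90))
        assert sol.coverage >= 89.5


class TestTreeCluster:
    def test_degenerate_limit_equals_full_average_linkage(self):
        """With k_micro >= N and all-distinct binary profiles every model is
        its own leaf and the tree must equal direct average-linkage
        agglomeration (same partition at every cut, same heights)."""
        rng = np.random.default_rng(9)
        X = np.unique(rng.integers(0, 2, size=(25, 40)), axis=0)
        ps = ProfileSet.from_matrix(X, _binary())
        tree = tree_cluster(ps, distance="hamming", k_micro=1000, seeding="hash")
        assert tree.n_leaves == len(X)
        D = pairwise_hamming_matrix(X)
        Z = sch.linkage(squareform(D, checks=False), method="average")
        assert np.allclose(sorted(h for _a, _b, h in tree.merges),
                           sorted(Z[:, 2]), rtol=1e-9)
        for k in (2, 5, len(X) - 1):
            ours = cut_dendrogram(tree, k)
            a = np.asarray([ours[m] for m in ps.ids])
            b = sch.fcluster(Z, t=k, criterion="maxclust")
            assert rand_index(a, b) == 1.0

    def test_ensemble_cut_recovers_planted_conformers(self, small_ensemble):
        from profclust import ca_cm_profile, extract_trace

        ens, truth = small_ensemble
        profs = [ca_cm_profile(extract_trace(m, "CA")) for m in ens]
        ps = ProfileSet(profs[0].alphabet, profs)
        tree = tree_cluster(ps, distance="hamming", k_micro=1000, seeding="rpart")
        labels = cut_dendrogram(tree, 3)
        a = np.asarray([labels[m] for m in ps.ids])
        assert rand_index(a, truth) == 1.0

    def test_ensemble_concordance_with_full_hierarchical(self, small_ensemble):
        from profclust import ca_cm_profile, extract_trace

        ens, _ = small_ensemble
        profs = [ca_cm_profile(extract_trace(m, "CA")) for m in ens]
        ps = ProfileSet(profs[0].alphabet, profs)
        tree = tree_cluster(ps, distance="hamming", k_micro=1000, seeding="rpart")
        D = pairwise_hamming_matrix(ps.matrix())
        Z = sch.linkage(squareform(D, checks=False), method="average")
        full = sch.fcluster(Z, t=5, criterion="maxclust")
        ours = cut_dendrogram(tree, 5)
        a = np.asarray([ours[m] for m in ps.ids])
        assert rand_index(a, full) >= 0.99

    def test_frequency_profiles_with_cosine(self):
        rng = np.random.default_rng(10)
        centers = rng.random(size=(2, 8)) * 10
        vecs = [FrequencyProfile(f"m{i}", centers[i % 2] + rng.random(8) * 0.2)
                for i in range(20)]
        tree = tree_cluster(vecs, distance="cosine", k_micro=100, seeding="hash")
        labels = cut_dendrogram(tree, 2)
        a = np.asarray([labels[v.model_id] for v in vecs])
        assert rand_index(a, np.arange(20) % 2) == 1.0

    def test_rmsd_distance_requires_coordinates(self, planted_profiles):
        ps, _ = planted_profiles
        with pytest.raises(ValueError):
            tree_cluster(ps, distance="rmsd")

    def test_cosine_rejects_state_profiles(self, planted_profiles):
        ps, _ = planted_profiles
        with pytest.raises(ValueError):
            tree_cluster(ps, distance="cosine")

    def test_size_weighted_equals_unweighted_on_singletons(self):
        rng = np.random.default_rng(12)
        X = np.unique(rng.integers(0, 2, size=(12, 25)), axis=0)
        ps = ProfileSet.from_matrix(X, _binary())
        a = tree_cluster(ps, k_micro=100, seeding="hash")
        b = tree_cluster(ps, k_micro=100, seeding="hash", size_weighted=True)
        assert np.allclose(sorted(h for *_x, h in a.merges),
                           sorted(h for *_x, h in b.merges), rtol=1e-9)


class TestKMedoids:
    def test_k_equals_n_zero_cost(self, tiny_profiles):
        sol = kmedoids_cluster(tiny_profiles, K=3, seed=0)
        assert sorted(len(m) for m, _c in sol.clusters) == [1, 1, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_separated_clouds_recovered_from_any_seed(self, seed):
        ps, truth = generate_profile_set(40, 40, 4, 2, 0.02, seed=6)
        sol = kmedoids_cluster(ps, K=2, seed=seed)
        assert rand_index(sol.labels(ps.ids), truth) == 1.0

    def test_deterministic_for_fixed_seed(self, planted_profiles):
        ps, _ = planted_profiles
        a = kmedoids_cluster(ps, K=3, seed=5)
        b = kmedoids_cluster(ps, K=3, seed=5)
        assert a.labels(ps.ids).tolist() == b.labels(ps.ids).tolist()

    def test_planted_recovery(self, planted_profiles):
        ps, truth = planted_profiles
        sol = kmedoids_cluster(ps, K=3, seed=0)
        assert rand_index(sol.labels(ps.ids), truth) >= 0.95


class TestCutDendrogram:
    def _chain(self):
        leaves = [("a", ["a"]), ("b", ["b"]), ("c", ["c"])]
        merges = [(0, 1, 1.0), (3, 2, 5.0)]
        return Dendrogram(leaves=leaves, merges=merges)

    def test_cut_one_is_single_cluster(self):
        labels = cut_dendrogram(self._chain(), 1)
        assert len(set(labels.values())) == 1

    def test_cut_at_leaf_count_is_leaf_partition(self):
        labels = cut_dendrogram(self._chain(), 3)
        assert len(set(labels.values())) == 3

    def test_cut_splits_highest_merge(self):
        labels = cut_dendrogram(self._chain(), 2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cut_dendrogram(self._chain(), 4)

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        newick = self._chain().to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            "a_1", "b_1", "c_1"}


class TestRandIndex:
    def test_identical_partitions(self):
        assert rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_pair_vs_singletons_example(self):
        # {12|34} vs all singletons: 4 of 6 pairs agree
        assert rand_index([0, 0, 1, 1], [0, 1, 2, 3]) == pytest.approx(4 / 6)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 4, size=50)
        b = rng.integers(0, 3, size=50)
        assert rand_index(a, b) == rand_index(b, a)

    def test_matches_sklearn(self):
        from sklearn.metrics import rand_score

        rng = np.random.default_rng(14)
        for _ in range(5):
            a = rng.integers(0, 5, size=80)
            b = rng.integers(0, 4, size=80)
            assert rand_index(a, b) == pytest.approx(rand_score(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rand_index([0, 1], [0, 1, 2])


class TestEvaluateSelection:
    def _solution(self):
        from profclust.clustering import ClusterSolution
        return ClusterSolution(
            clusters=[(["a", "b", "c"], "a"), (["d", "e"], "d"), (["f"], "f")],
            coverage=100.0)

    def test_maxsub_gap_good_selection(self):
        quality = {"a": 0.50, "d": 0.30, "f": 0.20, "x": 0.65}
        rec = evaluate_selection(self._solution(), quality, "maxsub_gap",
                                 top_n=3, gap=0.2)
        assert rec["good"] is True  # 0.65 - 0.50 = 0.15 < 0.2

    def test_top_model_equal_best_always_good(self):
        quality = {"a": 0.8, "d": 0.1, "f": 0.1}
        rec = evaluate_selection(self._solution(), quality, "maxsub_gap",
                                 gap=0.0)
        assert rec["good"] is True

    def test_rmsd_mode_takes_minimum_over_centroids(self):
        quality = {"a": 6.1, "d": 4.6, "f": 7.0}
        rec = evaluate_selection(self._solution(), quality, "rmsd_to_native",
                                 top_n=3)
        assert rec["min_rmsd"] == pytest.approx(4.6)

    def test_jury_result_uses_top_ranked_model(self, tiny_profiles):
        result = jury_rank(tiny_profiles)
        rec = evaluate_selection(result, {"a": 0.4, "b": 0.9, "c": 0.9},
                                 "maxsub_gap", gap=0.2)
        assert rec["selected"] == ["a"]
        assert rec["good"] is False  # 0.9 - 0.4 > 0.2

    def test_missing_quality_named(self):
        with pytest.raises(KeyError, match="f"):
            evaluate_selection(self._solution(), {"a": 1, "d": 1},
                               "rmsd_to_native", top_n=3)


def test_cluster_tsv_writer(tmp_path):
    from profclust.clustering import ClusterSolution

    sol = ClusterSolution(clusters=[(["a", "b"], "a")], coverage=66.7,
                          unassigned=["c"])
    path = tmp_path / "c.tsv"
    write_clusters(sol, str(path))
    lines = path.read_text().splitlines()
    assert "a\t0\t1" in lines and "b\t0\t0" in lines and "c\t-1\t0" in lines
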