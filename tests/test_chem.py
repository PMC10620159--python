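import numpy as np
import pandas as pd
import pytest

from fritniche.chem import (
    N_BITS,
    FingerprintSet,
    build_network,
    cluster_metabolites,
    cluster_plants,
    dissimilarity_matrix,
    plant_group_matrix,
    set_similarity,
    tanimoto,
)
from fritniche.synth import gen_fingerprint_clusters, gen_plant_profiles


def fps_from_bits(rows: dict[str, list[int]], plants=None) -> FingerprintSet:
    """Build a FingerprintSet from short on-bit lists, padded to 881 bits."""
    mat = {}
    for name, on in rows.items():
        v = np.zeros(N_BITS, dtype=int)
        v[list(on)] = 1
        mat[name] = v
    return FingerprintSet(pd.DataFrame(mat).T, plants or {})


class TestTanimoto:
    def test_identical_nonzero(self):
        a = np.zeros(10)
        a[[1, 5]] = 1
        assert tanimoto(a, a) == 1.0

    def test_partial_overlap(self):
        # a=1100, b=0110: 1 shared of 3 union bits
        assert tanimoto([1, 1, 0, 0], [0, 1, 1, 0]) == pytest.approx(1 / 3)

    def test_both_all_zero_convention(self):
        assert tanimoto(np.zeros(8), np.zeros(8)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto([1, 0], [1, 0, 1])

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            s = tanimoto(a, b)
            assert 0 <= s <= 1
            assert s == tanimoto(b, a)
            if s == 1.0:
                np.testing.assert_array_equal(a, b)


class TestNetwork:
    def test_exact_threshold_creates_no_edge(self):
        # b holds 17 of a's 20 on-bits and nothing else: exactly 0.85
        fps = fps_from_bits({"a": list(range(20)), "b": list(range(17))})
        assert tanimoto(fps.fingerprints.loc["a"],
                        fps.fingerprints.loc["b"]) == pytest.approx(17 / 20)
        g = build_network(fps, threshold=0.85)
        assert g.number_of_edges() == 0

    def test_just_above_threshold_creates_edge(self):
        shared = list(range(18))
        fps = fps_from_bits({"a": shared + [100], "b": shared + [200]})
        # 18/20 = 0.9 > 0.85
        g = build_network(fps, threshold=0.85)
        assert g.has_edge("a", "b")

    def test_single_metabolite_isolated_node(self):
        g = build_network(fps_from_bits({"a": [0, 1]}))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_planted_clusters_have_no_between_edges(self):
        fps, truth = gen_fingerprint_clusters(seed=1)
        g = build_network(fps)
        for u, v in g.edges:
            assert truth.labels[u] == truth.labels[v]


class TestClustering:
    def test_two_cliques_two_groups(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        groups = cluster_metabolites(g)
        assert sorted(map(sorted, groups.values())) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_isolated_node_singleton(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b")
        groups = cluster_metabolites(g)
        assert {"solo"} in groups.values()

    @pytest.mark.parametrize("mode", ["components", "ipca"])
    def test_planted_clusters_recovered_exactly(self, mode):
        from sklearn.metrics import rand_score

        fps, truth = gen_fingerprint_clusters(seed=2)
        g = build_network(fps)
        groups = cluster_metabolites(g, mode=mode)
        pred = {}
        for gi, (gid, mets) in enumerate(groups.items()):
            for m in mets:
                pred[m] = gi
        mets = fps.metabolites
        assert rand_score([truth.labels[m] for m in mets],
                          [pred[m] for m in mets]) == 1.0

    def test_groups_partition_nodes(self):
        fps, _ = gen_fingerprint_clusters(3, 5, seed=3)
        g = build_network(fps)
        groups = cluster_metabolites(g)
        all_members = [m for mets in groups.values() for m in mets]
        assert sorted(all_members) == sorted(fps.metabolites)


class TestPlantGroupMatrix:
    def test_incidence(self):
        groups = {"G1": {"m1", "m2"}, "G2": {"m3"}}
        plants = {"pA": {"m1"}, "pB": set(), "pC": {"m2", "m3"}}
        mat = plant_group_matrix(groups, plants)
        assert mat.loc["pA"].tolist() == [1, 0]
        assert mat.loc["pB"].tolist() == [0, 0]
        assert mat.loc["pC"].tolist() == [1, 1]

    def test_ungrouped_metabolite_rejected(self):
        with pytest.raises(ValueError, match="ungrouped"):
            plant_group_matrix({"G1": {"m1"}}, {"p": {"m1", "mX"}})


class TestSetSimilarity:
    def test_worked_example(self):
        # {g1,g2,g3} vs {g2,g3,g4}
        a = [1, 1, 1, 0]
        b = [0, 1, 1, 1]
        assert set_similarity(a, b, "jaccard") == pytest.approx(0.5)
        assert set_similarity(a, b, "simpson") == pytest.approx(2 / 3)

    def test_identical_and_disjoint(self):
        a = [1, 1, 0]
        assert set_similarity(a, a, "jaccard") == 1.0
        assert set_similarity(a, a, "simpson") == 1.0
        b = [0, 0, 1]
        assert set_similarity(a, b, "jaccard") == 0.0
        assert set_similarity(a, b, "simpson") == 0.0

    def test_simpson_empty_set_rejected(self):
        with pytest.raises(ValueError):
            set_similarity([0, 0], [1, 0], "simpson")

    def test_simpson_dominates_jaccard(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = rng.integers(0, 2, 12)
            b = rng.integers(0, 2, 12)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert set_similarity(a, b, "simpson") >= set_similarity(a, b, "jaccard")

    def test_jaccard_triangle_inequality(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rows = rng.integers(0, 2, (3, 10))
            d = [1 - set_similarity(rows[i], rows[j], "jaccard")
                 for i, j in [(0, 1), (1, 2), (0, 2)]]
            assert d[2] <= d[0] + d[1] + 1e-12


class TestPlantTree:
    def test_identical_plants_merge_at_zero(self):
        mat = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]],
                           index=["p1", "p2", "p3"], columns=["G1", "G2", "G3"])
        dmat = dissimilarity_matrix(mat)
        tree = cluster_plants(dmat)
        first = tree.linkage_matrix[0]
        assert first[2] == 0.0
        assert frozenset(["p1", "p2"]) in tree.clades()

    def test_separated_pairs_grouped(self):
        mat = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 1, 1], [0, 1, 1, 1]],
            index=["a1", "a2", "b1", "b2"], columns=["G1", "G2", "G3", "G4"])
        tree = cluster_plants(dissimilarity_matrix(mat))
        clades = tree.clades()
        assert frozenset(["a1", "a2"]) in clades
        assert frozenset(["b1", "b2"]) in clades

    def test_duplicated_columns_give_full_support(self):
        # every column identical: resampling is a no-op, support 100
        mat = pd.DataFrame([[1] * 4, [1] * 4, [0] * 4],
                           index=["p1", "p2", "p3"],
                           columns=["G1", "G2", "G3", "G4"])
        dmat = dissimilarity_matrix(mat)
        tree = cluster_plants(dmat, n_boot=25, seed=1, matrix=mat)
        assert tree.support[frozenset(["p1", "p2"])] == 100.0

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame([[0, 0.5], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_plants(bad)

    def test_newick_contains_all_leaves_and_support(self):
        mat = pd.DataFrame([[1, 1, 0], [1, 1, 0], [0, 0, 1]],
                           index=["p1", "p2", "p3"], columns=["G1", "G2", "G3"])
        tree = cluster_plants(dissimilarity_matrix(mat), n_boot=10, seed=0, matrix=mat)
        nwk = tree.newick()
        for leaf in ["p1", "p2", "p3"]:
            assert leaf in nwk
        assert nwk.endswith(";")

    def test_end_to_end_planted_plant_grouping(self):
        fps, truth = gen_fingerprint_clusters(6, 6, seed=7)
        profiles = gen_plant_profiles(fps, truth, {
            "u1": {0, 1}, "u2": {0, 1}, "v1": {3, 4}, "v2": {3, 4},
            "w": {5}}, seed=8)
        g = build_network(profiles)
        groups = cluster_metabolites(g)
        pgm = plant_group_matrix(groups, profiles.plants)
        tree = cluster_plants(dissimilarity_matrix(pgm))
        clades = tree.clades()
        assert frozenset(["u1", "u2"]) in clades
        assert frozenset(["v1", "v2"]) in clades
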