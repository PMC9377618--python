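import numpy as np
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from socpod.association import AssociationMatrix, DyadTallies, association_matrix
from socpod.community import (
    best_partition_by_modularity,
    cluster_hwi,
    cophenetic_correlation,
    mantel_within_between,
    mean_hwi_cut_partition,
    modularity,
    threshold_scan,
)
from socpod.simulate import SimulationConfig, simulate_population
from socpod.sightings import build_sampling_periods

from conftest import periods_from_sets
from oracles import nx_modularity


def matrix_from_hwi(hwi):
    n = hwi.shape[0]
    zeros = np.zeros((n, n), dtype=int)
    t = DyadTallies(
        ids=[f"I{i}" for i in range(n)],
        x=(hwi > 0).astype(int),
        yab=zeros, ya=zeros, yb=zeros,
        n_periods_seen=np.ones(n, dtype=int),
    )
    return AssociationMatrix(
        ids=t.ids, hwi=hwi, tallies=t, never_cosampled=hwi == 0
    )


def block_matrix(sizes, within, between):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    hwi = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(hwi, 0.0)
    return matrix_from_hwi(hwi), labels


class TestClustering:
    def test_always_together_pairs_merge_first_at_one(self):
        m, _ = block_matrix([2, 2], 1.0, 0.0)
        for method in ("average", "ward"):
            sol = cluster_hwi(m, method=method)
            heights = sol.merge_heights_association_scale()
            assert heights[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["average", "ward"])
    def test_top_split_separates_blocks(self, method):
        m, labels = block_matrix([3, 3], 0.5, 0.0)
        sol = cluster_hwi(m, method=method)
        two = hierarchy.cut_tree(sol.linkage, n_clusters=2).ravel()
        assert adjusted_rand_score(labels, two) == 1.0

    def test_unsupported_method_rejected(self):
        m, _ = block_matrix([2, 2], 1.0, 0.0)
        with pytest.raises(ValueError):
            cluster_hwi(m, method="single-spectral")


class TestCopheneticCorrelation:
    def test_ultrametric_input_gives_one(self):
        # two tight pairs, uniform weaker cross-association: ultrametric
        m, _ = block_matrix([2, 2], 0.8, 0.2)
        sol = cluster_hwi(m)
        assert cophenetic_correlation(sol, m) == pytest.approx(1.0)
        # cophenetic heights equal the input association values
        coph = 1.0 - hierarchy.cophenet(sol.linkage)
        iu = np.triu_indices(4, k=1)
        np.testing.assert_allclose(
            coph, m.hwi[iu][_condensed_order(4)], atol=1e-12
        )

    def test_block_matrix_value_matches_direct_formula(self):
        m, _ = block_matrix([3, 3], 0.5, 0.1)
        sol = cluster_hwi(m)
        iu = np.triu_indices(6, k=1)
        coph_dist = hierarchy.cophenet(sol.linkage)
        expected = np.corrcoef(1.0 - m.hwi[iu][_condensed_order(6)], coph_dist)[0, 1]
        assert cophenetic_correlation(sol, m) == pytest.approx(expected)

    def test_noise_matrix_fails_acceptance_rule_on_average(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(50):
            a = rng.random((8, 8)) * 0.2
            hwi = (a + a.T) / 2
            np.fill_diagonal(hwi, 0)
            m = matrix_from_hwi(hwi)
            vals.append(cophenetic_correlation(cluster_hwi(m), m))
        assert np.mean(vals) < 0.8

    def test_too_few_dyads_error(self):
        m, _ = block_matrix([2], 1.0, 0.0)
        with pytest.raises(ValueError):
            cophenetic_correlation(cluster_hwi(m), m)


def _condensed_order(n):
    iu = np.triu_indices(n, k=1)
    return np.arange(len(iu[0]))


class TestModularity:
    def test_single_cluster_is_exactly_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 6))
        hwi = (a + a.T) / 2
        np.fill_diagonal(hwi, 0)
        assert modularity(hwi, np.zeros(6)) == pytest.approx(0.0)

    def test_all_singletons_nonpositive(self):
        rng = np.random.default_rng(2)
        a = rng.random((6, 6))
        hwi = (a + a.T) / 2
        np.fill_diagonal(hwi, 0)
        assert modularity(hwi, np.arange(6)) <= 0

    def test_two_equal_disconnected_cliques_score_half(self):
        m, labels = block_matrix([4, 4], 0.7, 0.0)
        assert modularity(m.hwi, labels) == pytest.approx(0.5)

    def test_agrees_with_networkx_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            a = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
            hwi = (a + a.T) / 2
            np.fill_diagonal(hwi, 0)
            if hwi.sum() == 0:
                continue
            labels = rng.integers(0, 3, size=n)
            assert modularity(hwi, labels) == pytest.approx(
                nx_modularity(hwi, labels), abs=1e-10
            )

    def test_best_cut_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            a = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            hwi = (a + a.T) / 2
            np.fill_diagonal(hwi, 0)
            if hwi.sum() == 0:
                continue
            m = matrix_from_hwi(hwi)
            sol = cluster_hwi(m)
            best = best_partition_by_modularity(sol)
            cuts = hierarchy.cut_tree(sol.linkage)
            brute = max(
                nx_modularity(hwi, cuts[:, c]) for c in range(cuts.shape[1])
            )
            assert best.q == pytest.approx(brute, abs=1e-10)

    def test_three_cluster_default_regime_recovers_structure(self):
        cfg = SimulationConfig(seed=21)
        df, truth = simulate_population(cfg)
        m = association_matrix(build_sampling_periods(df))
        best = best_partition_by_modularity(cluster_hwi(m))
        assert best.n_clusters == 3
        assert best.q > 0.3
        labels = [truth["cluster"][i] for i in m.ids]
        assert adjusted_rand_score(labels, best.partition) == 1.0

    def test_exact_recovery_with_no_between_cluster_mixing(self, small_clustered_catalog):
        df, truth = small_clustered_catalog
        m = association_matrix(build_sampling_periods(df))
        best = best_partition_by_modularity(cluster_hwi(m))
        labels = [truth["cluster"][i] for i in m.ids]
        assert adjusted_rand_score(labels, best.partition) == 1.0

    def test_newick_export_parses_and_is_ultrametric(self):
        m, _ = block_matrix([3, 3], 0.5, 0.1)
        sol = cluster_hwi(m)
        dendropy = pytest.importorskip("dendropy")
        tree = dendropy.Tree.get(data=sol.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(m.ids)
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in tree.leaf_node_iter()
        }
        assert max(depths.values()) - min(depths.values()) < 1e-6

    def test_mean_hwi_cut_available(self):
        m, labels = block_matrix([3, 3], 0.5, 0.0)
        part = mean_hwi_cut_partition(cluster_hwi(m))
        assert adjusted_rand_score(labels, part) == 1.0


class TestMantel:
    def test_block_structure_is_significant(self):
        m, labels = block_matrix([7, 7], 0.4, 0.05)
        out = mantel_within_between(m, labels, n_permutations=999, seed=0)
        assert out["p"] <= 0.01
        assert out["within_mean"] > out["between_mean"]

    def test_shuffled_labels_destroy_signal(self):
        m, labels = block_matrix([5, 5], 0.4, 0.05)
        rng = np.random.default_rng(1)
        out = mantel_within_between(m, rng.permutation(labels), n_permutations=499, seed=1)
        assert abs(out["r"]) < 0.3

    def test_agrees_with_skbio_mantel_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        m, labels = block_matrix([4, 4], 0.5, 0.1)
        rng = np.random.default_rng(5)
        noise = rng.random((8, 8)) * 0.05
        hwi = np.clip(m.hwi + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(hwi, 0)
        m2 = matrix_from_hwi(hwi)
        ours = mantel_within_between(m2, labels, n_permutations=99, seed=2)
        same = (labels[:, None] == labels[None, :]).astype(float)
        np.fill_diagonal(same, 0)
        r_ref, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(1 - hwi - np.eye(8) * (1 - 0)),
            skbio_distance.DistanceMatrix(1 - same - np.eye(8)),
            permutations=0,
        )
        assert ours["r"] == pytest.approx(r_ref, abs=1e-10)

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            a = rng.random((10, 10)) * 0.3
            hwi = (a + a.T) / 2
            np.fill_diagonal(hwi, 0)
            labels = rng.integers(0, 2, size=10)
            if len(np.unique(labels)) < 2:
                continue
            out = mantel_within_between(
                matrix_from_hwi(hwi), labels, n_permutations=99,
                seed=int(rng.integers(2**31)),
            )
            ps.append(out["p"])
        ps = np.array(ps)
        assert 0.4 < ps.mean() < 0.6
        assert (ps <= 0.05).mean() <= 0.12

    def test_single_cluster_errors(self):
        m, _ = block_matrix([4], 0.5, 0.0)
        with pytest.raises(ValueError):
            mantel_within_between(m, np.zeros(4))


class TestThresholdScan:
    def test_scan_behaviour_on_sparse_resight_fixture(self, small_clustered_catalog):
        df, _ = small_clustered_catalog
        scan = threshold_scan(df, range(1, 6))
        assert (scan["n_individuals"].diff().dropna() <= 0).all()
        assert scan.iloc[0]["n_individuals"] == df["individual_id"].nunique()
        # CCC does not degrade as poorly-resighted individuals are dropped
        ccc = scan["CCC"].to_numpy()
        assert ccc[-1] >= ccc[0] - 0.05

    def test_threshold_above_max_sightings_warns(self, small_clustered_catalog):
        df, _ = small_clustered_catalog
        with pytest.warns(UserWarning, match="fewer than 2"):
            scan = threshold_scan(df, [10_000])
        assert scan.iloc[0]["n_individuals"] == 0
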