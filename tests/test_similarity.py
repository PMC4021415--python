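from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from icod import (
    UNREACHABLE,
    DecayParams,
    SeedGeneSet,
    build_similarity_network,
    compute_mu,
    extract_subnetwork,
    generate_planted_modules,
    permutation_pvalue,
    shortest_path_distance,
    transform_distance,
)
from icod.fixtures import PlantedModuleSpec
from icod.similarity import DistanceProvider

from _oracles import brute_mu
from conftest import random_connected_graph


class TestShortestPathDistance:
    def test_hops_identity_and_unreachable(self, path3):
        assert shortest_path_distance(path3, "A", "C") == 2
        assert shortest_path_distance(path3, "B", "B") == 0
        two_comp = nx.Graph([("A", "B"), ("C", "D")])
        assert shortest_path_distance(two_comp, "A", "C") == UNREACHABLE

    def test_symmetry(self, triangle_tail):
        assert shortest_path_distance(triangle_tail, "A", "D") == shortest_path_distance(
            triangle_tail, "D", "A") == 2

    def test_absent_node_fatal(self, path3):
        with pytest.raises(ValueError, match="not in the network"):
            shortest_path_distance(path3, "A", "GHOST")


class TestTransformDistance:
    def test_zero_distance_gives_amplitude(self):
        # Decay transform at D=0 with default amplitude 0.9 and rate 1
        assert transform_distance(0) == pytest.approx(0.9, abs=1e-15)

    def test_one_hop(self):
        assert transform_distance(1) == pytest.approx(0.9 * math.exp(-1), rel=1e-12)
        assert transform_distance(1) == pytest.approx(0.331091, abs=1e-6)

    def test_unreachable_is_zero(self):
        assert transform_distance(UNREACHABLE) == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DecayParams(A=0)
        with pytest.raises(ValueError):
            DecayParams(b=-1)
        with pytest.raises(ValueError):
            DecayParams(C=-1)
        with pytest.raises(ValueError):
            transform_distance(-1)


class TestComputeMu:
    def test_identical_singletons(self, subnet_factory):
        net = nx.Graph([("A", "B")])
        si = subnet_factory(net, "i", {"A"})
        sj = subnet_factory(net, "j", {"A"})
        assert compute_mu(net, si, sj).mu == pytest.approx(1.0)

    def test_different_components_zero(self, subnet_factory):
        net = nx.Graph([("A", "B"), ("C", "D")])
        si = subnet_factory(net, "i", {"A", "B"})
        sj = subnet_factory(net, "j", {"C", "D"})
        res = compute_mu(net, si, sj)
        assert res.mu == 0.0 and res.numerator == 0.0

    def test_triangle_tail_worked_example(self, triangle_tail, subnet_factory):
        """Hand enumeration: members {A,B} x {B,C}; shared B gives 0.9;
        the three 1-hop cross pairs give 0.9/e each."""
        si = subnet_factory(triangle_tail, "i", {"A", "B"})
        sj = subnet_factory(triangle_tail, "j", {"B", "C"})
        res = compute_mu(triangle_tail, si, sj)
        expected = 1 / (1 + 3 * math.exp(-1))
        assert res.mu == pytest.approx(expected, rel=1e-12)
        assert res.mu == pytest.approx(0.47537, abs=5e-6)
        assert res.numerator == pytest.approx(0.9)
        assert res.n_overlap_pairs == 1

    def test_distances_use_global_network_not_subnetwork(self, subnet_factory):
        # A and C are 2 apart globally via B, but B is in neither subnetwork
        net = nx.path_graph(["A", "B", "C"])
        si = subnet_factory(net, "i", {"A"})
        sj = subnet_factory(net, "j", {"C"})
        res = compute_mu(net, si, sj)
        assert res.denominator == pytest.approx(0.9 * math.exp(-2), rel=1e-12)

    def test_c_zero_numerator_counts_shared_members(self, subnet_factory):
        net = nx.complete_graph(["A", "B", "C", "D"])
        si = subnet_factory(net, "i", {"A", "B", "C"})
        sj = subnet_factory(net, "j", {"B", "C", "D"})
        res = compute_mu(net, si, sj)
        assert res.numerator == pytest.approx(0.9 * 2, rel=1e-12)
        assert res.n_overlap_pairs == 2

    def test_empty_members_fatal(self, subnet_factory, path3):
        si = subnet_factory(path3, "i", {"A"})
        sj = subnet_factory(path3, "j", set())
        with pytest.raises(ValueError, match="non-empty"):
            compute_mu(path3, si, sj)

    def test_sparse_backend_matches_dense(self, triangle_tail, subnet_factory):
        si = subnet_factory(triangle_tail, "i", {"A", "B"})
        sj = subnet_factory(triangle_tail, "j", {"B", "C"})
        dense = compute_mu(triangle_tail, si, sj, distances=DistanceProvider(triangle_tail))
        lazy = compute_mu(triangle_tail, si, sj,
                          distances=DistanceProvider(triangle_tail, dense_limit=0))
        assert lazy.mu == pytest.approx(dense.mu, rel=1e-14)


class TestOracleEquivalence:
    def test_matches_floyd_warshall_brute_force(self, subnet_factory):
        """200 random graphs of <= 12 nodes vs the independent FW oracle."""
        rng = np.random.default_rng(20260920)
        for _ in range(200):
            net = random_connected_graph(rng, n_max=12)
            nodes = sorted(net.nodes)
            ki = int(rng.integers(1, len(nodes) + 1))
            kj = int(rng.integers(1, len(nodes) + 1))
            mi = set(rng.choice(nodes, size=ki, replace=False))
            mj = set(rng.choice(nodes, size=kj, replace=False))
            C = int(rng.integers(0, 3))
            params = DecayParams(A=0.9, b=1.0, C=C)
            got = compute_mu(net, subnet_factory(net, "i", mi),
                             subnet_factory(net, "j", mj), params).mu
            want = brute_mu(nodes, net.edges, mi, mj, A=0.9, b=1.0, C=C)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


class TestMuInvariants:
    def test_bounds_symmetry_and_c_monotonicity(self, subnet_factory):
        rng = np.random.default_rng(42)
        for _ in range(40):
            net = random_connected_graph(rng)
            nodes = sorted(net.nodes)
            mi = set(rng.choice(nodes, size=int(rng.integers(1, len(nodes) + 1)), replace=False))
            mj = set(rng.choice(nodes, size=int(rng.integers(1, len(nodes) + 1)), replace=False))
            si, sj = subnet_factory(net, "i", mi), subnet_factory(net, "j", mj)
            prev = -1.0
            for C in (0, 1, 2, 3):
                params = DecayParams(C=C)
                fwd = compute_mu(net, si, sj, params).mu
                rev = compute_mu(net, sj, si, params).mu
                assert 0 <= fwd <= 1 + 1e-12
                assert fwd == pytest.approx(rev, rel=1e-12, abs=1e-15)
                assert fwd >= prev - 1e-12  # raising C never lowers mu
                prev = fwd


@pytest.fixture(scope="module")
def planted():
    spec = PlantedModuleSpec(
        n_background=500, attachment_m=2,
        module_sizes={"mod_a": 20, "mod_b": 20},
        overlap_fraction=0.5, core_degree_bias="hub_core", rng_seed=7)
    return generate_planted_modules(spec)


@pytest.fixture(scope="module")
def three_modules():
    spec = PlantedModuleSpec(
        n_background=300, attachment_m=2,
        module_sizes={"m1": 10, "m2": 10, "m3": 10},
        overlap_fraction=0.4, rng_seed=1)
    net, seed_sets, _ = generate_planted_modules(spec)
    subs = [extract_subnetwork(net, s) for s in seed_sets]
    return net, subs


class TestPermutationPvalue:
    def test_planted_overlap_is_significant(self, planted):
        """Two modules sharing half their seeds on a 500-node scale-free net
        must beat a 200-draw uniform null."""
        net, (sa, sb), _ = planted
        res = permutation_pvalue(net, sa, sb, n_permutations=200, rng_seed=11)
        assert res.p_value <= 0.05
        assert res.null_mus.shape == (200,)

    def test_plus_one_estimator_bounds(self, planted):
        net, (sa, sb), _ = planted
        res = permutation_pvalue(net, sa, sb, n_permutations=50, rng_seed=3)
        assert 1 / 51 <= res.p_value <= 1.0

    def test_identical_seed_runs_are_bit_reproducible(self, planted):
        net, (sa, sb), _ = planted
        r1 = permutation_pvalue(net, sa, sb, n_permutations=30, rng_seed=5)
        r2 = permutation_pvalue(net, sa, sb, n_permutations=30, rng_seed=5)
        assert np.array_equal(r1.null_mus, r2.null_mus)
        assert r1.p_value == r2.p_value

    def test_degree_binned_scheme_runs(self, planted):
        net, (sa, sb), _ = planted
        res = permutation_pvalue(net, sa, sb, n_permutations=30,
                                 scheme="degree_binned", rng_seed=5)
        assert res.scheme == "degree_binned" and 0 < res.p_value <= 1

    def test_oversized_seed_request_fatal(self, path3):
        big = SeedGeneSet("big", frozenset({"A", "B", "C"}))
        from icod.similarity import _draw_null_seeds

        with pytest.raises(ValueError, match="exceeds"):
            _draw_null_seeds(path3, frozenset("ABCD"), "uniform",
                             np.random.default_rng(0), None, np.array(["A", "B", "C"]))


class TestSimilarityNetwork:
    def test_all_pairs_scored_symmetric(self, three_modules):
        net, subs = three_modules
        sim = build_similarity_network(subs, net, n_permutations=20, rng_seed=0)
        assert len(sim.results) == 3  # C(3,2)
        assert np.allclose(sim.mu_matrix.values, sim.mu_matrix.values.T)
        assert np.allclose(np.diag(sim.mu_matrix.values), 1.0)

    def test_identical_entries_reach_self_similarity(self, three_modules):
        """An identical twin scores exactly the module's self-similarity,
        the maximum attainable for that member set (1 only for singleton
        modules, since the denominator spans all cross pairs)."""
        net, subs = three_modules
        twin = type(subs[0])(label="twin", seed_genes_used=subs[0].seed_genes_used,
                             members=subs[0].members, graph=subs[0].graph)
        sim = build_similarity_network([subs[0], twin], net, n_permutations=10, rng_seed=0)
        self_mu = compute_mu(net, subs[0], subs[0]).mu
        assert sim.mu_matrix.loc["m1", "twin"] == pytest.approx(self_mu, rel=1e-12)
        assert 0 < self_mu <= 1
        # cross-module mu never exceeds the smaller self-similarity
        cross = compute_mu(net, subs[0], subs[1]).mu
        assert cross < self_mu

    def test_duplicate_labels_fatal(self, three_modules):
        net, subs = three_modules
        with pytest.raises(ValueError, match="duplicate"):
            build_similarity_network([subs[0], subs[0]], net, n_permutations=5)

    def test_eight_labels_give_28_pairs(self):
        spec = PlantedModuleSpec(
            n_background=400, attachment_m=2,
            module_sizes={f"d{k}": 6 for k in range(8)},
            overlap_fraction=0.5, rng_seed=2, quantile=0.5)
        net, seed_sets, _ = generate_planted_modules(spec)
        subs = [extract_subnetwork(net, s) for s in seed_sets]
        sim = build_similarity_network(subs, net, n_permutations=5, rng_seed=0)
        assert len(sim.results) == 28

    def test_graph_export_thresholds_at_p(self, three_modules):
        net, subs = three_modules
        sim = build_similarity_network(subs, net, n_permutations=20, rng_seed=0)
        full = sim.to_graph(p_cutoff=None)
        assert full.number_of_edges() == 3
        cut = sim.to_graph(p_cutoff=0.05)
        assert set(cut.edges) <= set(full.edges)
        frame = sim.long_form()
        assert "p_bh" in frame.columns and len(frame) == 3
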