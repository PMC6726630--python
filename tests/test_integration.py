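"""Consensus integration via k-partite cliques, and the three filters."""

import itertools

import numpy as np
import pytest

from cdbench import (
    ClusterSet,
    IntegrationConfig,
    ReliabilityConfig,
    build_kpartite,
    enumerate_consensus_cliques,
    filter_protein,
    filter_reliability,
    filter_size,
    integrate,
)

from conftest import noisy_fixture, oracle_maximal_cliques


def _cs(name, *groups):
    return ClusterSet(name, [frozenset(g) for g in groups])


class TestKPartiteGraph:
    def test_identical_clusters_linked_at_phi_one(self):
        g = build_kpartite([_cs("A", "abc"), _cs("B", "abc")], phi=1.0)
        assert set(g.edges()) == {((0, 0), (1, 0))}
        # nearly-identical clusters are NOT linked at phi = 1
        g = build_kpartite([_cs("A", "abc"), _cs("B", "abcd")], phi=1.0)
        assert g.number_of_edges() == 0

    def test_phi_comparison_is_strict(self):
        # JCC({a,b,c},{a,b,d}) = 2/4 = 0.5: no edge at phi = 0.5
        g = build_kpartite([_cs("A", "abc"), _cs("B", "abd")], phi=0.5)
        assert g.number_of_edges() == 0
        # JCC({a,b,c},{a,b}) = 2/3 > 0.5: edge present
        g = build_kpartite([_cs("A", "abc"), _cs("B", "ab")], phi=0.5)
        assert g.number_of_edges() == 1

    def test_no_intra_part_edges_ever(self):
        sets = [_cs("A", "abc", "abd"), _cs("B", "abc", "abd")]
        g = build_kpartite(sets, phi=0.1)
        assert all(u[0] != v[0] for u, v in g.edges())

    def test_needs_two_methods(self):
        with pytest.raises(ValueError, match=">= 2 methods"):
            build_kpartite([_cs("A", "abc")], phi=0.5)


class TestCliqueEnumeration:
    def test_triangle_and_strict_cutoff(self):
        sets = [_cs("A", "abc"), _cs("B", "abc"), _cs("C", "abc", "xyz")]
        g = build_kpartite(sets, phi=0.9)
        cliques = enumerate_consensus_cliques(g, psi=1)
        assert cliques == [((0, 0), (1, 0), (2, 0))]
        # the isolated node (2,1) is a maximal clique of size 1, kept only
        # when psi = 0 (the cutoff is strict)
        assert enumerate_consensus_cliques(g, psi=0) == [
            ((0, 0), (1, 0), (2, 0)),
            ((2, 1),),
        ]

    def test_path_yields_two_cliques(self):
        # A-B and B-C similar, A-C not: two maximal 2-cliques
        sets = [_cs("A", "abcd"), _cs("B", "abce"), _cs("C", "acef")]
        g = build_kpartite(sets, phi=0.5)
        assert set(g.edges()) == {((0, 0), (1, 0)), ((1, 0), (2, 0))}
        assert enumerate_consensus_cliques(g, psi=1) == [
            ((0, 0), (1, 0)),
            ((1, 0), (2, 0)),
        ]

    def test_agrees_with_subset_brute_force(self):
        """Oracle equivalence on random k-partite graphs with <= 12 nodes."""
        rng = np.random.default_rng(0)
        for trial in range(40):
            k = int(rng.integers(2, 5))
            sets = []
            pool = list("abcdefghij")
            for part in range(k):
                n_clusters = int(rng.integers(1, 4))
                sets.append(ClusterSet(f"M{part}", [
                    frozenset(rng.choice(pool, size=rng.integers(2, 5),
                                         replace=False).tolist())
                    for _ in range(n_clusters)
                ]))
            if sum(cs.m for cs in sets) > 12:
                continue
            phi = float(rng.uniform(0.1, 0.9))
            g = build_kpartite(sets, phi)
            adjacency = {node: set(g.neighbors(node)) for node in g.nodes}
            expected = {
                c for c in oracle_maximal_cliques(list(g.nodes), adjacency)
                if len(c) > 1
            }
            got = {frozenset(c) for c in enumerate_consensus_cliques(g, psi=1)}
            assert got == expected, f"trial {trial}"


class TestIntegrate:
    def test_union_and_intersection_coincide_at_phi_one(self):
        """With phi = 1 only identical clusters form cliques, so both modes
        return the same consensus set — on arbitrary inputs."""
        for seed in range(6):
            _, a = noisy_fixture(seed)
            _, b = noisy_fixture(seed + 100)
            # make some clusters identical across methods
            shared = a.clusters[: max(1, a.m // 2)]
            b = ClusterSet("B", shared + b.clusters)
            a = ClusterSet("A", a.clusters)
            union = integrate([a, b], IntegrationConfig(phi=1.0, psi=1, mode="union"))
            inter = integrate(
                [a, b], IntegrationConfig(phi=1.0, psi=1, mode="intersection")
            )
            assert union.clusters == inter.clusters

    def test_union_vs_intersection_set_arithmetic(self):
        a = _cs("A", "abc")
        b = _cs("B", "abd")
        config = IntegrationConfig(phi=0.4, psi=1, mode="union")
        assert integrate([a, b], config).clusters == [frozenset("abcd")]
        config = IntegrationConfig(phi=0.4, psi=1, mode="intersection")
        assert integrate([a, b], config).clusters == [frozenset("ab")]

    def test_consensus_identity_keeps_clusters_reported_by_two_methods(self):
        """phi = 1, psi = 1 keeps exactly the clusters reported identically
        by at least two methods."""
        a = _cs("A", "abc", "de")
        b = _cs("B", "abc", "fg")
        c = _cs("C", "xyz")
        merged = integrate([a, b, c], IntegrationConfig(phi=1.0, psi=1))
        assert merged.clusters == [frozenset("abc")]

    def test_subset_superset_invariants(self):
        for seed in range(5):
            _, a = noisy_fixture(seed)
            _, b = noisy_fixture(seed + 50)
            sets = [ClusterSet("A", a.clusters), ClusterSet("B", b.clusters)]
            phi = 0.3
            g = build_kpartite(sets, phi)
            cliques = enumerate_consensus_cliques(g, psi=1)
            union = integrate(sets, IntegrationConfig(phi=phi, psi=1, mode="union"))
            inter = integrate(
                sets, IntegrationConfig(phi=phi, psi=1, mode="intersection")
            )
            for clique in cliques:
                members = [g.nodes[node]["cluster"] for node in clique]
                u = frozenset().union(*members)
                i = frozenset.intersection(*members)
                assert u in union.clusters
                assert all(i <= m <= u for m in members)
                if i:
                    assert i in inter.clusters

    def test_default_psi_is_half_k(self):
        # k = 4, psi default 2: a 2-clique must not survive, a 3-clique must
        a = _cs("A", "abcd")
        b = _cs("B", "abcd")
        c = _cs("C", "abce")
        d = _cs("D", "qrs")
        merged = integrate([a, b, c, d], IntegrationConfig(phi=0.5))
        assert merged.clusters == [frozenset("abcde")]
        merged2 = integrate([a, b, d, _cs("E", "tuv")],
                            IntegrationConfig(phi=0.5))
        assert merged2.clusters == []


class TestFilters:
    def test_filter_size_window(self):
        cs = _cs("A", "a", "ab", "abc")
        assert filter_size(cs, 2, 2).clusters == [frozenset("ab")]
        assert filter_size(cs, 1, 10).clusters == cs.clusters
        cs2 = _cs("A", "ab", "cde")
        assert filter_size(cs2, 3, 10).clusters == [frozenset("cde")]

    def test_filter_size_rejects_bad_bounds_and_is_idempotent(self):
        cs = _cs("A", "ab", "cde")
        with pytest.raises(ValueError):
            filter_size(cs, 3, 2)
        once = filter_size(cs, 2, 2)
        assert filter_size(once, 2, 2).clusters == once.clusters

    def test_filter_protein_queries(self):
        a = _cs("A", "abc", "ade", "xy")
        b = _cs("B", "qr")
        hits = filter_protein([a, b], "a")
        assert hits["A"] == [frozenset("abc"), frozenset("ade")]  # input order
        assert hits["B"] == []
        assert filter_protein([a, b], "zz") == {"A": [], "B": []}

    def test_filter_reliability_beta_one_is_identity(self):
        for seed in range(3):
            _, target = noisy_fixture(seed)
            _, panel = noisy_fixture(seed + 10)
            out = filter_reliability(target, [panel], ReliabilityConfig(beta=1))
            assert out.clusters == target.clusters

    def test_filter_reliability_counts_exact_copy_in_panel(self):
        target = _cs("T", "abc", "def", "gh")
        panel = [_cs("P", "abc")]
        out = filter_reliability(target, panel, ReliabilityConfig(beta=2))
        assert out.clusters == [frozenset("abc")]

    def test_filter_reliability_beta_exceeding_methods_warns_empty(self):
        target = _cs("T", "abc")
        panel = [_cs("P", "abc")]
        with pytest.warns(UserWarning, match="beta"):
            out = filter_reliability(target, panel, ReliabilityConfig(beta=4))
        assert out.clusters == []
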