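"""Motif census: frozen small cases, brute-force oracle equivalence,
count invariants, strengths and differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from moistnet import (
    MotifStrength,
    ParameterError,
    census,
    degrees,
    motif_strength,
    strength_difference,
)
from conftest import make_network, random_network
from _oracles import brute_force_census


class TestDegrees:
    def test_out_star(self):
        net = make_network(3, [(0, 1), (0, 2)])
        deg = degrees(net)
        assert deg.k_out[0] == 2
        assert deg.k_in[1] == deg.k_in[2] == 1

    def test_empty_network(self):
        net = make_network(4, np.empty((0, 2), dtype=int))
        deg = degrees(net)
        assert deg.k_in.sum() == deg.k_out.sum() == 0

    def test_matches_networkx_on_random_graph(self):
        rng = np.random.default_rng(5)
        net = random_network(50, 0.1, rng)
        g = nx.DiGraph(list(map(tuple, net.edges)))
        deg = degrees(net)
        for node in g.nodes:
            assert deg.k_in[node] == g.in_degree(node)
            assert deg.k_out[node] == g.out_degree(node)

    def test_degree_conservation(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            net = random_network(40, 0.15, rng)
            deg = degrees(net)
            assert deg.k_in.sum() == deg.k_out.sum() == net.n_edges


class TestSmallCases:
    def test_single_ffl(self):
        cen = census(make_network(3, [(0, 1), (1, 2), (0, 2)]))
        assert list(cen.ffl_target) == [0, 0, 1]
        assert cen.zl.sum() == 0 and cen.nbr_center.sum() == 0

    def test_single_zero_loop(self):
        cen = census(make_network(2, [(0, 1), (1, 0)]))
        assert list(cen.zl) == [1, 1]
        assert cen.ffl_target.sum() == 0 and cen.nbr_center.sum() == 0

    def test_single_neighboring_loop(self):
        # S -> A, A <-> B: A is the center
        cen = census(make_network(3, [(0, 1), (1, 2), (2, 1)]))
        assert list(cen.nbr_center) == [0, 1, 0]
        assert list(cen.zl) == [0, 1, 1]
        assert cen.ffl_target.sum() == 0

    def test_fully_bidirectional_triangle(self):
        # frozen from exhaustive triple enumeration: every node is FFL target
        # twice, has two reciprocal partners, and centers two NBrs (one per
        # partner, with the third node as the distinct source)
        edges = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        cen = census(make_network(3, edges), "pattern")
        f, z, nb, inv, part = brute_force_census(3, edges, "pattern")
        assert np.array_equal(cen.ffl_target, f) and list(f) == [2, 2, 2]
        assert np.array_equal(cen.zl, z) and list(z) == [2, 2, 2]
        assert np.array_equal(cen.nbr_center, nb) and list(nb) == [2, 2, 2]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            census(make_network(2, [(0, 1)]), "exotic")


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["pattern", "induced"])
    def test_random_graphs_match_enumeration(self, mode):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 41))
            net = random_network(n, float(rng.uniform(0.02, 0.3)), rng)
            cen = census(net, mode)
            f, z, nb, inv, part = brute_force_census(n, net.edges, mode)
            assert np.array_equal(cen.ffl_target, f)
            assert np.array_equal(cen.zl, z)
            assert np.array_equal(cen.nbr_center, nb)
            assert np.array_equal(cen.total_involvement, inv)
            got = dict(zip(map(tuple, cen.edges), cen.edge_participation))
            assert got == part


edge_lists = st.lists(
    st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] != e[1]),
    max_size=30,
    unique=True,
)


class TestCountInvariants:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(edges=edge_lists)
    def test_totals_and_participation_sums(self, edges):
        net = make_network(8, np.asarray(edges, dtype=int).reshape(-1, 2))
        cen = census(net, "pattern")
        assert cen.zl.sum() % 2 == 0
        # each occurrence contributes its edge count to the participation sum
        assert cen.edge_participation.sum() == (
            3 * cen.n_ffl + 2 * cen.n_zl_pairs + 3 * cen.n_nbr
        )
        # and its node count to the involvement sum
        assert cen.total_involvement.sum() == (
            3 * cen.n_ffl + 2 * cen.n_zl_pairs + 3 * cen.n_nbr
        )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(edges=edge_lists, extra=st.tuples(st.integers(0, 7), st.integers(0, 7)))
    def test_pattern_counts_monotone_under_edge_addition(self, edges, extra):
        if extra[0] == extra[1] or extra in edges:
            return
        before = census(make_network(8, np.asarray(edges, int).reshape(-1, 2)), "pattern")
        after = census(
            make_network(8, np.asarray(edges + [extra], int).reshape(-1, 2)), "pattern"
        )
        for t in ("ffl", "zl", "nbr"):
            assert np.all(after.counts(t) >= before.counts(t))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(edges=edge_lists)
    def test_induced_counts_bounded_by_pattern(self, edges):
        net = make_network(8, np.asarray(edges, dtype=int).reshape(-1, 2))
        pattern = census(net, "pattern")
        induced = census(net, "induced")
        for t in ("ffl", "zl", "nbr"):
            assert np.all(induced.counts(t) <= pattern.counts(t))


class TestStrengths:
    def test_normalization_by_global_max(self):
        net = make_network(4, [(0, 1), (1, 2), (0, 2), (1, 3), (2, 3), (1, 2)][:5])
        cen = census(net)
        st_ = motif_strength(cen)
        for t in ("ffl", "zl", "nbr"):
            counts = cen.counts(t)
            if counts.max() > 0:
                assert st_[t].max() == 1.0
                assert np.array_equal(np.argsort(st_[t]), np.argsort(counts, kind="stable"))
            assert np.all((0 <= st_[t]) & (st_[t] <= 1))

    def test_zero_counts_flagged(self):
        net = make_network(3, [(0, 1), (1, 2), (0, 2)])  # no ZL, no NBr
        st_ = motif_strength(census(net))
        assert "zl" in st_.zero_types and "nbr" in st_.zero_types
        assert np.all(st_["zl"] == 0)

    def test_difference_is_elementwise_and_bounded(self):
        st_ = MotifStrength(
            strengths={
                "ffl": np.array([1.0, 0.0, 0.5]),
                "zl": np.array([0.25, 1.0, 0.5]),
                "nbr": np.array([0.0, 0.5, 1.0]),
            },
            normalizers={"ffl": 4, "zl": 4, "nbr": 2},
            zero_types=(),
        )
        d = strength_difference(st_, "ffl_minus_zl")
        assert d.values == pytest.approx([0.75, -1.0, 0.0])
        d2 = strength_difference(st_, "ffl_minus_nbr")
        assert d2.values == pytest.approx([1.0, -0.5, -0.5])
        assert np.all(np.abs(d.values) <= 1) and np.all(np.abs(d2.values) <= 1)
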