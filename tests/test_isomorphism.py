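import itertools
import math
import random

import networkx as nx
import pytest

from graphette import (
    GraphetteError,
    apply_permutation,
    are_isomorphic,
    complement,
    cycles_of,
    decode,
    degree_sequence,
    degrees,
    encode,
    enumerate_orbits,
    generate_automorphisms,
    num_pairs,
    orbit_count,
)
from graph_fixtures import cycle_bits, path_bits, star_bits


def to_networkx(g):
    G = nx.Graph()
    G.add_nodes_from(range(g.k))
    G.add_edges_from(g.edges)
    return G


def brute_force_automorphisms(g):
    """Independent oracle: filter all k! permutations."""
    return [
        pi
        for pi in itertools.permutations(range(g.k))
        if apply_permutation(g, pi).bits == g.bits
    ]


class TestAreIsomorphic:
    def test_one_edge_isomorphs(self):
        g = decode(encode(3, {(1, 0)}), 3)
        h = decode(encode(3, {(2, 1)}), 3)
        ok, pi = are_isomorphic(g, h)
        assert ok
        assert apply_permutation(g, pi).bits == h.bits

    def test_degree_mismatch_short_circuit(self):
        ok, pi = are_isomorphic(decode(path_bits(3), 3), decode(4, 3))
        assert not ok and pi is None

    def test_permuted_graph_is_isomorphic(self):
        rng = random.Random(7)
        for _ in range(100):
            k = rng.randint(2, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            pi = list(range(k))
            rng.shuffle(pi)
            ok, wit = are_isomorphic(g, apply_permutation(g, tuple(pi)))
            assert ok
            assert apply_permutation(g, wit).bits == apply_permutation(g, tuple(pi)).bits

    def test_size_mismatch_error(self):
        with pytest.raises(GraphetteError):
            are_isomorphic(decode(0, 3), decode(0, 4))

    def test_witness_is_lexicographically_first(self):
        g = decode(encode(3, {(1, 0)}), 3)
        ok, pi = are_isomorphic(g, g)
        assert ok and pi == (0, 1, 2)

    @pytest.mark.parametrize("k", [4, 5])
    def test_networkx_oracle_agreement(self, k):
        rng = random.Random(k)
        for _ in range(150):
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            h = decode(rng.randrange(1 << num_pairs(k)), k)
            ok, _ = are_isomorphic(g, h)
            assert ok == nx.is_isomorphic(to_networkx(g), to_networkx(h))


class TestAutomorphisms:
    def test_triangle_full_symmetric_group(self):
        assert len(generate_automorphisms(decode(7, 3))) == 6

    def test_path3_endpoint_swap(self):
        g = decode(path_bits(3), 3)  # path 0-1-2, centre 1
        autos = generate_automorphisms(g)
        assert sorted(autos) == [(0, 1, 2), (2, 1, 0)]

    def test_5cycle_dihedral(self):
        g = decode(cycle_bits(5), 5)
        autos = generate_automorphisms(g)
        assert len(autos) == 10
        assert sorted(autos) == sorted(brute_force_automorphisms(g))

    def test_k1(self):
        assert generate_automorphisms(decode(0, 1)) == [(0,)]

    def test_matches_brute_force(self):
        rng = random.Random(11)
        for _ in range(100):
            k = rng.randint(2, 6)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            assert generate_automorphisms(g) == brute_force_automorphisms(g)

    def test_identity_always_member(self):
        rng = random.Random(3)
        for _ in range(50):
            k = rng.randint(1, 8)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            assert tuple(range(k)) in generate_automorphisms(g)

    def test_every_member_fixes_graph(self):
        rng = random.Random(5)
        for _ in range(50):
            k = rng.randint(2, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            for pi in generate_automorphisms(g):
                assert apply_permutation(g, pi).bits == g.bits

    def test_lagrange(self):
        rng = random.Random(13)
        for _ in range(100):
            k = rng.randint(1, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            assert math.factorial(k) % len(generate_automorphisms(g)) == 0

    def test_closure_under_composition_sampled(self):
        rng = random.Random(17)
        for _ in range(50):
            k = rng.randint(2, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            autos = generate_automorphisms(g)
            auto_set = set(autos)
            for _ in range(10):
                pi = rng.choice(autos)
                sigma = rng.choice(autos)
                comp = tuple(sigma[pi[i]] for i in range(k))
                assert comp in auto_set

    def test_complement_has_same_automorphisms(self):
        rng = random.Random(19)
        for _ in range(100):
            k = rng.randint(2, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            assert generate_automorphisms(g) == generate_automorphisms(complement(g))


class TestCycles:
    def test_worked_example(self):
        assert cycles_of((2, 0, 1, 3, 5, 4)) == [(0, 2, 1), (3,), (4, 5)]

    def test_identity(self):
        for k in range(1, 9):
            assert cycles_of(tuple(range(k))) == [(u,) for u in range(k)]

    def test_transposition(self):
        assert cycles_of((1, 0)) == [(0, 1)]

    def test_cycles_partition_nodes(self):
        rng = random.Random(23)
        for _ in range(200):
            k = rng.randint(1, 8)
            pi = list(range(k))
            rng.shuffle(pi)
            cycles = cycles_of(tuple(pi))
            flat = sorted(u for cyc in cycles for u in cyc)
            assert flat == list(range(k))

    def test_cycle_order_follows_images(self):
        rng = random.Random(29)
        for _ in range(100):
            k = rng.randint(2, 8)
            pi = list(range(k))
            rng.shuffle(pi)
            for cyc in cycles_of(tuple(pi)):
                for idx, u in enumerate(cyc):
                    assert pi[u] == cyc[(idx + 1) % len(cyc)]

    def test_power_by_cycle_length_fixes_members(self):
        rng = random.Random(31)
        for _ in range(50):
            k = rng.randint(2, 8)
            pi = list(range(k))
            rng.shuffle(pi)
            for cyc in cycles_of(tuple(pi)):
                lam = len(cyc)
                for u in cyc:
                    v = u
                    for _ in range(lam):
                        v = pi[v]
                    assert v == u

    def test_not_a_permutation(self):
        with pytest.raises(GraphetteError):
            cycles_of((0, 0, 1))


class TestOrbits:
    def test_single_edge_two_orbits(self):
        # edge (1,0): endpoints swap, node 2 isolated
        colors = enumerate_orbits(decode(1, 3))
        assert colors == (0, 0, 2)
        assert orbit_count(decode(1, 3)) == 2

    def test_path3_two_orbits(self):
        g = decode(path_bits(3), 3)  # centre node 1
        colors = enumerate_orbits(g)
        assert colors[0] == colors[2] != colors[1]
        assert orbit_count(g) == 2

    def test_5cycle_vertex_transitive(self):
        assert enumerate_orbits(decode(cycle_bits(5), 5)) == (0,) * 5

    def test_star_two_orbits(self):
        g = decode(star_bits(6), 6)
        colors = enumerate_orbits(g)
        assert len(set(colors)) == 2
        assert colors[1:] == (1,) * 5

    def test_colors_are_orbit_minima(self):
        rng = random.Random(37)
        for _ in range(100):
            k = rng.randint(1, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            colors = enumerate_orbits(g)
            for u in range(k):
                members = [v for v in range(k) if colors[v] == colors[u]]
                assert colors[u] == min(members)

    def test_orbits_refine_degree_classes(self):
        rng = random.Random(41)
        for _ in range(100):
            k = rng.randint(2, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            colors = enumerate_orbits(g)
            deg = degrees(g)
            for u in range(k):
                for v in range(k):
                    if colors[u] == colors[v]:
                        assert deg[u] == deg[v]

    def test_orbit_count_complement_symmetry(self):
        rng = random.Random(43)
        for _ in range(100):
            k = rng.randint(1, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            assert orbit_count(g) == orbit_count(complement(g))

    def test_cycles_stay_within_one_color(self):
        rng = random.Random(47)
        for _ in range(50):
            k = rng.randint(2, 7)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            colors = enumerate_orbits(g)
            for pi in generate_automorphisms(g):
                for cyc in cycles_of(pi):
                    assert len({colors[u] for u in cyc}) == 1

    def test_same_color_implies_automorphism_witness_k_le_5(self):
        """Nodes sharing a final colour are mapped onto each other by some
        automorphism (checked exhaustively on every class representative)."""
        for k in range(1, 6):
            seen = set()
            for bits in range(1 << num_pairs(k)):
                g = decode(bits, k)
                key = min(
                    apply_permutation(g, pi).bits
                    for pi in itertools.permutations(range(k))
                )
                if key in seen:
                    continue
                seen.add(key)
                colors = enumerate_orbits(g)
                autos = generate_automorphisms(g)
                for u in range(k):
                    for v in range(k):
                        if colors[u] == colors[v]:
                            assert any(pi[u] == v for pi in autos)

    def test_nodes_in_different_orbits_never_swapped(self):
        rng = random.Random(53)
        for _ in range(50):
            k = rng.randint(2, 6)
            g = decode(rng.randrange(1 << num_pairs(k)), k)
            colors = enumerate_orbits(g)
            for pi in generate_automorphisms(g):
                for u in range(k):
                    assert colors[pi[u]] == colors[u]
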