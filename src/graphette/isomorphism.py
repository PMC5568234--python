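"""Permutation-based isomorphism testing, automorphism groups and orbits.

Everything here is brute force by design: graphettes have at most 8 nodes,
so backtracking over degree-compatible images is cheap, and the output is
a ground truth that fancier canonical-labelling schemes can be checked
against.
"""

from __future__ import annotations

from typing import Sequence

from .core import (
    Graphette,
    GraphetteError,
    adjacency_masks,
    complement,
    degree_sequence,
    degrees,
)

__all__ = [
    "are_isomorphic",
    "generate_automorphisms",
    "cycles_of",
    "enumerate_orbits",
    "orbit_count",
]


def are_isomorphic(
    g: Graphette, h: Graphette
) -> tuple[bool, tuple[int, ...] | None]:
    """Test isomorphism; on success also return a witness permutation.

    The witness ``pi`` satisfies ``apply_permutation(g, pi).bits == h.bits``
    and is the lexicographically first such permutation (images searched in
    ascending order).  A sorted-degree-sequence mismatch short-circuits to
    ``(False, None)`` without any permutation search.
    """
    if g.k != h.k:
        raise GraphetteError(f"size mismatch: k={g.k} vs k={h.k}")
    k = g.k
    if g.bits == h.bits:
        return True, tuple(range(k))
    if degree_sequence(g) != degree_sequence(h):
        return False, None

    deg_g = degrees(g)
    deg_h = degrees(h)
    adj_g = adjacency_masks(g)
    adj_h = adjacency_masks(h)
    image = [-1] * k
    used = [False] * k

    def extend(i: int) -> bool:
        if i == k:
            return True
        ai = adj_g[i]
        for v in range(k):
            if used[v] or deg_h[v] != deg_g[i]:
                continue
            ok = True
            for j in range(i):
                if ((ai >> j) & 1) != ((adj_h[v] >> image[j]) & 1):
                    ok = False
                    break
            if ok:
                image[i] = v
                used[v] = True
                if extend(i + 1):
                    return True
                used[v] = False
        image[i] = -1
        return False

    if extend(0):
        return True, tuple(image)
    return False, None


def generate_automorphisms(g: Graphette) -> list[tuple[int, ...]]:
    """All node permutations fixing ``g``'s adjacency matrix, in
    lexicographic order of their image sequences.

    Two pruning rules: candidate images are restricted to nodes of equal
    degree, and when ``g`` has more edges than its complement the search
    runs on the complement instead (a permutation fixes a graph iff it
    fixes the complement, and the degree classes coincide).
    """
    k = g.k
    if 2 * g.num_edges > k * (k - 1) // 2:
        g = complement(g)
    deg = degrees(g)
    adj = adjacency_masks(g)
    image = [-1] * k
    used = [False] * k
    out: list[tuple[int, ...]] = []

    def extend(i: int) -> None:
        if i == k:
            out.append(tuple(image))
            return
        ai = adj[i]
        for v in range(k):
            if used[v] or deg[v] != deg[i]:
                continue
            ok = True
            for j in range(i):
                if ((ai >> j) & 1) != ((adj[v] >> image[j]) & 1):
                    ok = False
                    break
            if ok:
                image[i] = v
                used[v] = True
                extend(i + 1)
                used[v] = False
        image[i] = -1

    extend(0)
    return out


def cycles_of(pi: Sequence[int]) -> list[tuple[int, ...]]:
    """Split a permutation into its disjoint cycles.

    Cycles are listed by ascending smallest member; within a cycle,
    successive entries are successive images under ``pi``.  For example
    ``(2, 0, 1, 3, 5, 4)`` splits into ``(0, 2, 1)``, ``(3,)``, ``(4, 5)``.
    """
    k = len(pi)
    if sorted(pi) != list(range(k)):
        raise GraphetteError(f"{pi!r} is not a permutation of 0..{k - 1}")
    seen = [False] * k
    cycles: list[tuple[int, ...]] = []
    for start in range(k):
        if seen[start]:
            continue
        cyc = [start]
        seen[start] = True
        u = pi[start]
        while u != start:
            cyc.append(u)
            seen[u] = True
            u = pi[u]
        cycles.append(tuple(cyc))
    return cycles


def enumerate_orbits(g: Graphette) -> tuple[int, ...]:
    """Per-node orbit colours of the automorphism group of ``g``.

    Each node starts with its own index as colour; the cycles of every
    automorphism are repeatedly collapsed onto their minimum colour until
    nothing changes, so the final colour of a node is the smallest node
    index in its orbit.  A single pass over the cycles is not enough in
    general (a later cycle can lower the colour of an earlier one), hence
    the fixed-point loop.
    """
    k = g.k
    color = list(range(k))
    autos = generate_automorphisms(g)
    cycle_sets = [cycles_of(pi) for pi in autos]
    changed = True
    while changed:
        changed = False
        for cycles in cycle_sets:
            for cyc in cycles:
                cmin = min(color[u] for u in cyc)
                for u in cyc:
                    if color[u] != cmin:
                        color[u] = cmin
                        changed = True
    return tuple(color)


def orbit_count(g: Graphette) -> int:
    """Number of distinct automorphism orbits of ``g``."""
    return len(set(enumerate_orbits(g)))
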