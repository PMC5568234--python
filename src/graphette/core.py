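"""Bit-vector encoding of small undirected graphs and host-graph handling.

A *graphette* is an arbitrary (possibly disconnected) undirected graph on
``k`` labelled nodes, ``1 <= k <= 8``.  It is stored as the integer whose
bits are the lower triangle of the adjacency matrix read row by row: the
node pair ``(i, j)`` with ``i > j`` occupies bit position
``p(i, j) = i*(i-1)//2 + j`` (least-significant bit first).  With
``b(k) = k*(k-1)//2`` pair positions, every integer in ``[0, 2**b(k))``
is a distinct labelled graph and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

MAX_K = 8

__all__ = [
    "MAX_K",
    "GraphetteError",
    "InvalidEdgeError",
    "InvalidNodeSetError",
    "Graphette",
    "HostGraph",
    "num_pairs",
    "pair_index",
    "encode",
    "decode",
    "induced_bits",
    "apply_permutation",
    "complement",
    "degrees",
    "degree_sequence",
    "is_connected",
]


class GraphetteError(ValueError):
    """Base class for invalid graphette inputs."""


class InvalidEdgeError(GraphetteError):
    """An edge refers to an out-of-range node or is a self-loop."""


class InvalidNodeSetError(GraphetteError):
    """A node set has duplicates or out-of-range members."""


def num_pairs(k: int) -> int:
    """Number of unordered node pairs on ``k`` nodes: ``k*(k-1)//2``."""
    return k * (k - 1) // 2


def pair_index(i: int, j: int) -> int:
    """Bit position of the pair ``(i, j)`` with ``i > j``."""
    if not 0 <= j < i:
        raise InvalidEdgeError(f"pair ({i},{j}) must satisfy 0 <= j < i")
    return i * (i - 1) // 2 + j


def _check_k(k: int) -> None:
    if not isinstance(k, int) or not 1 <= k <= MAX_K:
        raise GraphetteError(f"k must be an integer in [1, {MAX_K}], got {k!r}")


@dataclass(frozen=True)
class Graphette:
    """An undirected graph on ``k`` nodes encoded as a ``b(k)``-bit integer."""

    k: int
    bits: int

    def __post_init__(self) -> None:
        _check_k(self.k)
        if not 0 <= self.bits < (1 << num_pairs(self.k)):
            raise GraphetteError(
                f"bits {self.bits} out of range for k={self.k} "
                f"(must be < 2**{num_pairs(self.k)})"
            )

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        """Edge set as pairs ``(i, j)`` with ``i > j``."""
        out = []
        p = 0
        for i in range(self.k):
            for j in range(i):
                if (self.bits >> p) & 1:
                    out.append((i, j))
                p += 1
        return frozenset(out)

    @property
    def num_edges(self) -> int:
        return bin(self.bits).count("1")

    def has_edge(self, u: int, v: int) -> bool:
        if u == v:
            return False
        i, j = (u, v) if u > v else (v, u)
        return bool((self.bits >> pair_index(i, j)) & 1)


def encode(k: int, edges: Iterable[tuple[int, int]]) -> int:
    """Encode an edge set on ``k`` nodes into its bit-vector integer.

    Each edge ``(i, j)`` must satisfy ``0 <= j < i < k``; the pair
    contributes ``2**p(i, j)`` to the result.
    """
    _check_k(k)
    bits = 0
    for i, j in edges:
        if i == j:
            raise InvalidEdgeError(f"self-loop ({i},{i}) is not allowed")
        if not (0 <= j < i < k):
            raise InvalidEdgeError(
                f"edge ({i},{j}) must satisfy 0 <= j < i < k={k}"
            )
        bits |= 1 << pair_index(i, j)
    return bits


def decode(bits: int, k: int) -> Graphette:
    """Inverse of :func:`encode`: wrap a bit vector as a :class:`Graphette`."""
    return Graphette(k, bits)


def apply_permutation(g: Graphette, pi: Sequence[int]) -> Graphette:
    """Relabel ``g`` by ``pi``: the result has edge ``(pi[u], pi[v])`` iff
    ``g`` has edge ``(u, v)``."""
    k = g.k
    if len(pi) != k or sorted(pi) != list(range(k)):
        raise GraphetteError(f"permutation {pi!r} is not a bijection on 0..{k - 1}")
    bits = 0
    p = 0
    for i in range(k):
        for j in range(i):
            if (g.bits >> p) & 1:
                a, c = pi[i], pi[j]
                if a < c:
                    a, c = c, a
                bits |= 1 << pair_index(a, c)
            p += 1
    return Graphette(k, bits)


def complement(g: Graphette) -> Graphette:
    """Edge-complement: flip every pair bit."""
    mask = (1 << num_pairs(g.k)) - 1
    return Graphette(g.k, g.bits ^ mask)


def degrees(g: Graphette) -> tuple[int, ...]:
    """Per-node degrees, in node order."""
    deg = [0] * g.k
    p = 0
    for i in range(g.k):
        for j in range(i):
            if (g.bits >> p) & 1:
                deg[i] += 1
                deg[j] += 1
            p += 1
    return tuple(deg)


def degree_sequence(g: Graphette) -> tuple[int, ...]:
    """Sorted (non-decreasing) degree multiset."""
    return tuple(sorted(degrees(g)))


def adjacency_masks(g: Graphette) -> tuple[int, ...]:
    """Neighbourhood of each node as a bitmask over node indices."""
    adj = [0] * g.k
    p = 0
    for i in range(g.k):
        for j in range(i):
            if (g.bits >> p) & 1:
                adj[i] |= 1 << j
                adj[j] |= 1 << i
            p += 1
    return tuple(adj)


def is_connected(g: Graphette) -> bool:
    """True iff all ``k`` nodes lie in one component (``k = 1`` is connected)."""
    k = g.k
    if k == 1:
        return True
    adj = adjacency_masks(g)
    seen = 1  # start BFS from node 0
    frontier = adj[0]
    while frontier:
        seen |= frontier
        nxt = 0
        m = frontier
        while m:
            u = (m & -m).bit_length() - 1
            nxt |= adj[u]
            m &= m - 1
        frontier = nxt & ~seen
    return seen == (1 << k) - 1


class HostGraph:
    """A large undirected simple graph read from a plain-text edge list.

    Node labels are arbitrary strings; internal indices 0..n-1 are assigned
    in first-appearance order.  Duplicate edges are dropped silently;
    self-loops are an error.
    """

    __slots__ = ("labels", "index_of", "adj", "edges")

    def __init__(
        self,
        edge_labels: Iterable[tuple[str, str]],
        isolated: Iterable[str] = (),
    ):
        self.labels: list[str] = []
        self.index_of: dict[str, int] = {}
        self.adj: list[set[int]] = []
        edge_set: set[tuple[int, int]] = set()
        for a, b in edge_labels:
            if a == b:
                raise InvalidEdgeError(f"self-loop on node {a!r} is not allowed")
            u, v = self._intern(a), self._intern(b)
            key = (u, v) if u < v else (v, u)
            if key in edge_set:
                continue
            edge_set.add(key)
            self.adj[u].add(v)
            self.adj[v].add(u)
        for label in isolated:
            self._intern(label)
        self.edges: list[tuple[int, int]] = sorted(edge_set)

    def _intern(self, label: str) -> int:
        idx = self.index_of.get(label)
        if idx is None:
            idx = len(self.labels)
            self.index_of[label] = idx
            self.labels.append(label)
            self.adj.append(set())
        return idx

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.adj[u]

    @classmethod
    def from_text(cls, text: str) -> "HostGraph":
        pairs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise GraphetteError(
                    f"line {lineno}: expected two whitespace-separated labels, "
                    f"got {len(tokens)}"
                )
            pairs.append((tokens[0], tokens[1]))
        return cls(pairs)

    @classmethod
    def from_file(cls, path) -> "HostGraph":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_text(fh.read())


def induced_bits(host: HostGraph, nodes: Sequence[int]) -> int:
    """Bit vector of the subgraph induced on an ordered node set.

    Bit ``p(i, j)`` is set iff the host has an edge between ``nodes[i]``
    and ``nodes[j]``; the order of ``nodes`` fixes the encoding.
    """
    k = len(nodes)
    _check_k(k)
    if len(set(nodes)) != k:
        raise InvalidNodeSetError(f"node set {nodes!r} has duplicate members")
    n = host.n
    for u in nodes:
        if not 0 <= u < n:
            raise InvalidNodeSetError(f"node index {u} out of range [0, {n})")
    bits = 0
    p = 0
    for i in range(k):
        ai = host.adj[nodes[i]]
        for j in range(i):
            if nodes[j] in ai:
                bits |= 1 << p
            p += 1
    return bits
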