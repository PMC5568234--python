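"""Canonical lookup tables over all 2**b(k) bit vectors, and global orbit IDs.

The canonical representative of an isomorphism class is its numerically
smallest bit vector.  Scanning bit vectors in ascending order therefore
makes the first-seen member of every class its canonical; instead of
re-testing each vector against the canonicals found so far, the builder
expands each newly found canonical into its whole isomorphism class by
applying all k! permutations at once (vectorised), which fills in exactly
the same table far faster.  The partitioned "sifting" path reproduces the
serial result bit for bit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .core import Graphette, GraphetteError, decode, degree_sequence, is_connected, num_pairs
from .isomorphism import are_isomorphic, enumerate_orbits

logger = logging.getLogger(__name__)

__all__ = [
    "CanonicalMap",
    "GlobalOrbitTable",
    "PartitionResult",
    "LookupResult",
    "build_canonical_map",
    "build_partition",
    "sift_canonicals",
    "assign_global_orbits",
    "lookup",
    "pack_permutation",
    "unpack_permutation",
]

_PERM_BITS = 3  # images are < 8, so 3 bits each in the packed word


def pack_permutation(pi: Sequence[int]) -> int:
    """Pack up to 8 images of < 8 into one word, 3 bits each, LSB first."""
    word = 0
    for i, v in enumerate(pi):
        word |= v << (_PERM_BITS * i)
    return word


def unpack_permutation(word: int, k: int) -> tuple[int, ...]:
    return tuple((word >> (_PERM_BITS * i)) & 0b111 for i in range(k))


@lru_cache(maxsize=None)
def _perm_tables(k: int):
    """Per-k permutation machinery for vectorised class expansion.

    Returns (perms, src_of, inv_packed, pow2) where perms is the list of
    all k! permutations in lexicographic order, src_of[p, d] is the source
    bit position whose value lands at destination position d under perms[p],
    inv_packed[p] is the packed inverse of perms[p], and pow2 the bit
    weights.
    """
    perms = list(itertools.permutations(range(k)))
    b = num_pairs(k)
    nperm = len(perms)
    src_of = np.empty((nperm, b), dtype=np.intp)
    inv_packed = np.empty(nperm, dtype=np.uint32)
    for p, pi in enumerate(perms):
        for i in range(k):
            for j in range(i):
                s = i * (i - 1) // 2 + j
                a, c = pi[i], pi[j]
                if a < c:
                    a, c = c, a
                src_of[p, a * (a - 1) // 2 + c] = s
        inv = [0] * k
        for i, v in enumerate(pi):
            inv[v] = i
        inv_packed[p] = pack_permutation(inv)
    pow2 = (np.int64(1) << np.arange(b, dtype=np.int64))
    return perms, src_of, inv_packed, pow2


@dataclass
class CanonicalMap:
    """Lookup table from every bit vector on ``k`` nodes to its canonical.

    ``canon_of[B]`` indexes into ``canonicals``; ``perm_of[B]`` is the
    packed witness permutation taking the graphette ``B`` to its canonical;
    ``connected[c]`` flags whether canonical ``c`` is connected (i.e. also
    a graphlet).
    """

    k: int
    canon_of: np.ndarray  # (2**b,) int32
    perm_of: np.ndarray  # (2**b,) uint32, packed
    canonicals: np.ndarray  # (NC,) int64, strictly ascending
    connected: np.ndarray  # (NC,) bool

    @property
    def num_canonicals(self) -> int:
        return len(self.canonicals)

    @property
    def size(self) -> int:
        return 1 << num_pairs(self.k)

    def witness(self, bits: int) -> tuple[int, ...]:
        """Unpacked permutation taking graphette ``bits`` to its canonical."""
        self._check_bits(bits)
        return unpack_permutation(int(self.perm_of[bits]), self.k)

    def canonical_bits(self, bits: int) -> int:
        self._check_bits(bits)
        return int(self.canonicals[self.canon_of[bits]])

    def _check_bits(self, bits: int) -> None:
        if not 0 <= bits < self.size:
            raise GraphetteError(
                f"bit vector {bits} out of range for k={self.k}"
            )

    def equals(self, other: "CanonicalMap") -> bool:
        return (
            self.k == other.k
            and np.array_equal(self.canon_of, other.canon_of)
            and np.array_equal(self.perm_of, other.perm_of)
            and np.array_equal(self.canonicals, other.canonicals)
            and np.array_equal(self.connected, other.connected)
        )


@dataclass
class GlobalOrbitTable:
    """Global orbit IDs for every node position of every canonical.

    IDs are consecutive from 0: canonicals are processed in ascending
    order and, within a canonical, orbits are numbered by increasing
    minimal node index.  Positions of different canonicals never share an
    ID.
    """

    k: int
    orbit_id: np.ndarray  # (NC, k) int32
    num_orbits: int

    def equals(self, other: "GlobalOrbitTable") -> bool:
        return (
            self.k == other.k
            and self.num_orbits == other.num_orbits
            and np.array_equal(self.orbit_id, other.orbit_id)
        )


@dataclass
class PartitionResult:
    """Per-range canonization: temporary canonical bits for every vector in
    ``[lo, hi)``, each minimal within its isomorphism class intersected with
    the range."""

    k: int
    lo: int
    hi: int
    temp_canon: np.ndarray  # (hi-lo,) int64: temporary canonical bits per B


class LookupResult(NamedTuple):
    canonical_index: int
    canonical_bits: int
    witness: tuple[int, ...]
    orbit_ids: tuple[int, ...]
    connected: bool


def _check_build_k(k: int) -> None:
    if not isinstance(k, int) or not 1 <= k <= 8:
        raise GraphetteError(f"k must be in [1, 8], got {k!r}")


def _expand_class(k: int, bits: int):
    """All isomorphs of ``bits`` with, for each, the packed inverse of the
    lexicographically first permutation producing it.

    Returns ``(isomorphs, inv_packed_first)``: ``isomorphs`` are the
    distinct images of ``bits`` under all k! permutations (ascending), and
    ``inv_packed_first[i]`` is the packed permutation taking isomorph ``i``
    back to ``bits``.
    """
    _, src_of, inv_packed, pow2 = _perm_tables(k)
    b = num_pairs(k)
    src = (np.int64(bits) >> np.arange(b, dtype=np.int64)) & 1
    ints = src[src_of] @ pow2
    uniq, first = np.unique(ints, return_index=True)
    return uniq, inv_packed[first]


def build_canonical_map(
    k: int, progress: Callable[[int, int], None] | None = None
) -> CanonicalMap:
    """Exhaustively canonize all ``2**b(k)`` bit vectors on ``k`` nodes.

    ``progress``, if given, is called as ``progress(B, num_canonicals)`` at
    fixed bit-vector intervals (long k=7 builds want a heartbeat).
    """
    _check_build_k(k)
    b = num_pairs(k)
    size = 1 << b
    canon_of = np.full(size, -1, dtype=np.int32)
    perm_of = np.zeros(size, dtype=np.uint32)
    canonicals: list[int] = []
    # Ascending scan in chunks: only still-unassigned vectors start a new
    # class, and the first unassigned vector is its class minimum.
    chunk = min(size, 1 << 16)
    for pos in range(0, size, chunk):
        if progress is not None:
            progress(pos, len(canonicals))
        unassigned = np.flatnonzero(canon_of[pos : pos + chunk] < 0)
        for off in unassigned:
            B = pos + int(off)
            if canon_of[B] >= 0:  # claimed by an earlier class in this chunk
                continue
            ci = len(canonicals)
            canonicals.append(B)
            if k == 1:
                canon_of[0] = 0
                continue
            isomorphs, inv_first = _expand_class(k, B)
            canon_of[isomorphs] = ci
            perm_of[isomorphs] = inv_first
    canon_arr = np.asarray(canonicals, dtype=np.int64)
    connected = np.fromiter(
        (is_connected(decode(int(c), k)) for c in canon_arr),
        dtype=bool,
        count=len(canon_arr),
    )
    logger.info("k=%d: %d canonicals over %d bit vectors", k, len(canon_arr), size)
    return CanonicalMap(k, canon_of, perm_of, canon_arr, connected)


def build_partition(k: int, lo: int, hi: int) -> PartitionResult:
    """Canonize the bit-vector range ``[lo, hi)`` in isolation.

    Scans the range in ascending order and maps each vector to the lowest
    isomorphic vector seen *within the range*, using sorted-degree-sequence
    buckets to prune the pairwise isomorphism tests.
    """
    _check_build_k(k)
    size = 1 << num_pairs(k)
    if not 0 <= lo < hi <= size:
        raise GraphetteError(f"invalid range [{lo}, {hi}) for k={k}")
    temp_canon = np.empty(hi - lo, dtype=np.int64)
    buckets: dict[tuple[int, ...], list[Graphette]] = {}
    for B in range(lo, hi):
        g = decode(B, k)
        key = degree_sequence(g)
        target = B
        for cand in buckets.get(key, ()):
            iso, _ = are_isomorphic(g, cand)
            if iso:
                target = cand.bits
                break
        else:
            buckets.setdefault(key, []).append(g)
        temp_canon[B - lo] = target
    return PartitionResult(k, lo, hi, temp_canon)


def sift_canonicals(parts: Sequence[PartitionResult]) -> CanonicalMap:
    """Merge per-range partition results into the full canonical map.

    The ranges must cover ``[0, 2**b(k))`` exactly once.  Temporary
    canonicals from all parts are repeatedly merged — each re-pointed to
    the lowest-numbered isomorphic temporary canonical — until the set is
    stable, yielding the global canonical list; witness permutations are
    then filled in by class expansion, so the result is bit-identical to
    :func:`build_canonical_map`.
    """
    if not parts:
        raise GraphetteError("no partition results given")
    k = parts[0].k
    if any(p.k != k for p in parts):
        raise GraphetteError("partition results disagree on k")
    size = 1 << num_pairs(k)
    ordered = sorted(parts, key=lambda p: p.lo)
    pos = 0
    for p in ordered:
        if p.lo != pos:
            raise GraphetteError(
                f"partition ranges must cover [0, {size}) exactly; "
                f"gap or overlap at {p.lo} (expected {pos})"
            )
        pos = p.hi
    if pos != size:
        raise GraphetteError(
            f"partition ranges must cover [0, {size}) exactly; end at {pos}"
        )

    tc = np.concatenate([p.temp_canon for p in ordered])
    # Iteratively re-point temporary canonicals at the lowest-numbered
    # isomorphic temporary canonical until nothing moves.
    while True:
        temps = np.unique(tc)
        mapping: dict[int, int] = {}
        buckets: dict[tuple[int, ...], list[Graphette]] = {}
        for t in temps:
            t = int(t)
            g = decode(t, k)
            key = degree_sequence(g)
            target = t
            for cand in buckets.get(key, ()):
                iso, _ = are_isomorphic(g, cand)
                if iso:
                    target = cand.bits
                    break
            else:
                buckets.setdefault(key, []).append(g)
            mapping[t] = target
        if all(t == v for t, v in mapping.items()):
            break
        lut = np.vectorize(mapping.__getitem__, otypes=[np.int64])
        tc = lut(tc)

    canonicals = np.unique(tc)
    # Fill witnesses (and re-derive canon_of) by class expansion from the
    # merged canonical list; cross-check against the sifted assignment.
    canon_of = np.full(size, -1, dtype=np.int32)
    perm_of = np.zeros(size, dtype=np.uint32)
    for ci, c in enumerate(canonicals):
        if k == 1:
            canon_of[0] = 0
            continue
        isomorphs, inv_first = _expand_class(k, int(c))
        if (canon_of[isomorphs] >= 0).any():
            raise GraphetteError("sift merge produced overlapping classes")
        canon_of[isomorphs] = ci
        perm_of[isomorphs] = inv_first
    if (canon_of < 0).any():
        raise GraphetteError("sift merge left bit vectors unassigned")
    if not np.array_equal(canonicals[canon_of], tc):
        raise GraphetteError("sift merge disagrees with class expansion")
    connected = np.fromiter(
        (is_connected(decode(int(c), k)) for c in canonicals),
        dtype=bool,
        count=len(canonicals),
    )
    return CanonicalMap(k, canon_of, perm_of, canonicals, connected)


def assign_global_orbits(cmap: CanonicalMap) -> GlobalOrbitTable:
    """Number every automorphism orbit of every canonical with a global ID.

    Canonicals are processed in ascending order; within one canonical,
    orbits are numbered by increasing minimal node index, so IDs are
    consecutive integers starting at 0.
    """
    k = cmap.k
    orbit_id = np.empty((cmap.num_canonicals, k), dtype=np.int32)
    next_id = 0
    for ci, c in enumerate(cmap.canonicals):
        colors = enumerate_orbits(decode(int(c), k))
        local = {}
        for col in colors:  # colours are orbit minima, seen in index order
            if col not in local:
                local[col] = next_id
                next_id += 1
        orbit_id[ci] = [local[col] for col in colors]
    return GlobalOrbitTable(k, orbit_id, next_id)


def lookup(
    cmap: CanonicalMap, orbits: GlobalOrbitTable, bits: int
) -> LookupResult:
    """Constant-time identification of the graphette encoded by ``bits``.

    The orbit ID reported for original node position ``u`` is the ID of
    position ``witness[u]`` in the canonical.
    """
    if cmap.k != orbits.k:
        raise GraphetteError("canonical map and orbit table disagree on k")
    cmap._check_bits(bits)
    ci = int(cmap.canon_of[bits])
    sigma = unpack_permutation(int(cmap.perm_of[bits]), cmap.k)
    row = orbits.orbit_id[ci]
    return LookupResult(
        canonical_index=ci,
        canonical_bits=int(cmap.canonicals[ci]),
        witness=sigma,
        orbit_ids=tuple(int(row[sigma[u]]) for u in range(cmap.k)),
        connected=bool(cmap.connected[ci]),
    )
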