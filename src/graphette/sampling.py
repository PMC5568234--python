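"""Statistical sampling of k-node sets from a host network.

Three selection strategies:

``uniform``
    a uniformly random k-subset of the nodes;
``local``
    a uniform seed node, then repeated addition of a uniformly chosen
    neighbour of the current set (falling back to a uniform non-member
    when the neighbourhood is exhausted, so disconnected hosts never
    stall);
``edge``
    a uniformly chosen edge's endpoints, then the same expansion.

Each sampled set is identified in constant time through the canonical
lookup tables, accumulating the graphette distribution and the per-node
orbit degree vectors.  Samples are drawn with replacement across draws.
All randomness flows through a single ``numpy`` generator seeded by the
caller, so fixed seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .canonize import CanonicalMap, GlobalOrbitTable, unpack_permutation
from .core import GraphetteError, HostGraph, induced_bits

__all__ = [
    "GraphetteDistribution",
    "OrbitDegreeVectors",
    "sample_kset",
    "estimate_distribution",
    "orbit_degree_vectors",
    "write_distribution_tsv",
    "write_odv_tsv",
]


@dataclass
class GraphetteDistribution:
    """Sampled counts per canonical graphette; counts are the source of
    truth, frequencies are derived."""

    k: int
    n_samples: int
    counts: np.ndarray  # (NC,) int64

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_samples


@dataclass
class OrbitDegreeVectors:
    """Per host node, how often it was sampled into each global orbit."""

    k: int
    n_samples: int
    counts: np.ndarray  # (n_nodes, num_orbits) int64


def sample_kset(
    host: HostGraph, k: int, method: str, rng: np.random.Generator
) -> tuple[int, ...]:
    """Draw one ordered set of ``k`` distinct node indices."""
    n = host.n
    if k > n:
        raise GraphetteError(f"cannot sample k={k} nodes from a {n}-node host")
    if method == "uniform":
        return tuple(int(v) for v in rng.choice(n, size=k, replace=False))
    if method == "local":
        members = [int(rng.integers(n))]
    elif method == "edge":
        if not host.edges:
            raise GraphetteError("edge-based sampling requires at least one edge")
        u, v = host.edges[int(rng.integers(len(host.edges)))]
        members = [u, v][:k]
    else:
        raise GraphetteError(f"unknown sampling method {method!r}")
    member_set = set(members)
    frontier = set()
    for u in members:
        frontier |= host.adj[u]
    frontier -= member_set
    while len(members) < k:
        if frontier:
            pool = sorted(frontier)
        else:  # neighbourhood exhausted: uniform non-member fallback
            pool = [u for u in range(n) if u not in member_set]
        v = pool[int(rng.integers(len(pool)))]
        members.append(v)
        member_set.add(v)
        frontier |= host.adj[v]
        frontier -= member_set
    return tuple(members)


def _iter_identified_samples(host, k, n_samples, method, seed, cmap):
    rng = np.random.default_rng(seed)
    for _ in range(n_samples):
        nodes = sample_kset(host, k, method, rng)
        bits = induced_bits(host, nodes)
        yield nodes, bits, int(cmap.canon_of[bits])


def estimate_distribution(
    host: HostGraph,
    k: int,
    n_samples: int,
    method: str,
    seed: int,
    cmap: CanonicalMap,
) -> GraphetteDistribution:
    """Approximate the induced-subgraph distribution from ``n_samples``
    draws, counted per canonical graphette."""
    if cmap.k != k:
        raise GraphetteError(f"tables built for k={cmap.k}, requested k={k}")
    counts = np.zeros(cmap.num_canonicals, dtype=np.int64)
    for _, _, ci in _iter_identified_samples(host, k, n_samples, method, seed, cmap):
        counts[ci] += 1
    return GraphetteDistribution(k, n_samples, counts)


def orbit_degree_vectors(
    host: HostGraph,
    k: int,
    n_samples: int,
    method: str,
    seed: int,
    cmap: CanonicalMap,
    orbits: GlobalOrbitTable,
) -> OrbitDegreeVectors:
    """Accumulate per-node orbit hit counts over ``n_samples`` draws.

    For each sample, the node at original position ``u`` is credited with
    the global orbit ID of canonical position ``witness[u]``.  The grand
    total over all nodes and orbits is ``n_samples * k``.
    """
    if cmap.k != k or orbits.k != k:
        raise GraphetteError(f"tables built for k={cmap.k}, requested k={k}")
    counts = np.zeros((host.n, orbits.num_orbits), dtype=np.int64)
    for nodes, bits, ci in _iter_identified_samples(
        host, k, n_samples, method, seed, cmap
    ):
        sigma = unpack_permutation(int(cmap.perm_of[bits]), k)
        row = orbits.orbit_id[ci]
        for pos, node in enumerate(nodes):
            counts[node, row[sigma[pos]]] += 1
    return OrbitDegreeVectors(k, n_samples, counts)


def write_distribution_tsv(
    dist: GraphetteDistribution, cmap: CanonicalMap, path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#canonical_index\tbits\tconnected\tcount\tfrequency\n")
        for ci in range(cmap.num_canonicals):
            fh.write(
                "{}\t{}\t{}\t{}\t{:.6g}\n".format(
                    ci,
                    int(cmap.canonicals[ci]),
                    int(cmap.connected[ci]),
                    int(dist.counts[ci]),
                    dist.counts[ci] / dist.n_samples,
                )
            )


def write_odv_tsv(odv: OrbitDegreeVectors, host: HostGraph, path) -> None:
    num_orbits = odv.counts.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#node\t" + "\t".join(f"orbit{j}" for j in range(num_orbits)) + "\n")
        for u in range(host.n):
            fh.write(
                host.labels[u]
                + "\t"
                + "\t".join(str(int(v)) for v in odv.counts[u])
                + "\n"
            )
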