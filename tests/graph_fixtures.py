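"""Programmatic test graphs: structured graphettes and random hosts."""

import random

from graphette import HostGraph, encode


def _norm(i, j):
    return (i, j) if i > j else (j, i)


def path_bits(k):
    """Path 0-1-...-(k-1)."""
    return encode(k, {_norm(i, i + 1) for i in range(k - 1)})


def cycle_bits(k):
    edges = {_norm(i, (i + 1) % k) for i in range(k)}
    return encode(k, edges)


def star_bits(k):
    """Star with centre 0."""
    return encode(k, {(i, 0) for i in range(1, k)})


def clique_bits(k):
    return encode(k, {(i, j) for i in range(k) for j in range(i)})


def er_host(n, p, seed, ensure_all_nodes=True):
    """Erdős–Rényi G(n, p) host with string labels n0..n{n-1}."""
    rng = random.Random(seed)
    edges = [
        (f"n{i}", f"n{j}")
        for i in range(n)
        for j in range(i)
        if rng.random() < p
    ]
    isolated = [f"n{i}" for i in range(n)] if ensure_all_nodes else []
    return HostGraph(edges, isolated=isolated)


def random_bits(k, rng):
    from graphette import num_pairs

    return rng.randrange(1 << num_pairs(k))
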