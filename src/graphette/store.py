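"""Binary persistence of the canonical map and global orbit table.

Layout (all words little-endian 32-bit):

``<prefix>.map``
    24-byte header, then one word per bit vector (``2**b(k)`` of them):
    canonical index in bits 0-13, connected flag in bit 14.
``<prefix>.perm``
    no header; one word per bit vector packing the witness permutation,
    3 bits per node image, LSB first.
``<prefix>.orbits``
    24-byte header, then ``NC(k) * k`` words of global orbit IDs, row per
    canonical.
``<prefix>.canon.txt``
    human-readable listing: one line per canonical with its index, bit
    vector, connectedness, per-node orbit colour and global orbit ID.

Header: magic ``GTTB``, then five uint32 words: format version, k, b(k),
NC(k), total orbit count.  The canonical list itself is not stored: it is
recovered on read as the first bit vector mapping to each index (indices
are assigned in ascending bit-vector order, so this is exact).
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np

from .canonize import CanonicalMap, GlobalOrbitTable, PartitionResult, unpack_permutation
from .core import num_pairs

__all__ = [
    "TableStoreError",
    "MissingTableError",
    "HeaderMismatchError",
    "TruncatedTableError",
    "write_tables",
    "read_tables",
    "write_partition",
    "read_partition",
]

MAGIC = b"GTTB"
PART_MAGIC = b"GTTP"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<4s5I")  # magic, version, k, b, NC, num_orbits
_PART_HEADER = struct.Struct("<4s2I2Q")  # magic, version, k, lo, hi

_CANON_MASK = (1 << 14) - 1
_CONN_BIT = 14


class TableStoreError(Exception):
    """Base class for table file problems."""


class MissingTableError(TableStoreError):
    """A required table file does not exist."""


class HeaderMismatchError(TableStoreError):
    """Magic, version or k in a file header does not match expectations."""


class TruncatedTableError(TableStoreError):
    """A payload is shorter (or longer) than its header promises."""


def _map_path(prefix) -> str:
    return f"{prefix}.map"


def _perm_path(prefix) -> str:
    return f"{prefix}.perm"


def _orbit_path(prefix) -> str:
    return f"{prefix}.orbits"


def _text_path(prefix) -> str:
    return f"{prefix}.canon.txt"


def write_tables(cmap: CanonicalMap, orbits: GlobalOrbitTable, prefix) -> list[str]:
    """Write the four table files for ``prefix``; returns the paths."""
    if cmap.k != orbits.k:
        raise ValueError("canonical map and orbit table disagree on k")
    k = cmap.k
    b = num_pairs(k)
    header = _HEADER.pack(
        MAGIC, FORMAT_VERSION, k, b, cmap.num_canonicals, orbits.num_orbits
    )

    words = cmap.canon_of.astype(np.uint32)
    words |= cmap.connected[cmap.canon_of].astype(np.uint32) << _CONN_BIT
    map_path = _map_path(prefix)
    with open(map_path, "wb") as fh:
        fh.write(header)
        fh.write(words.astype("<u4").tobytes())

    perm_path = _perm_path(prefix)
    with open(perm_path, "wb") as fh:
        fh.write(cmap.perm_of.astype("<u4").tobytes())

    orbit_path = _orbit_path(prefix)
    with open(orbit_path, "wb") as fh:
        fh.write(header)
        fh.write(orbits.orbit_id.astype("<u4").tobytes())

    text_path = _text_path(prefix)
    with open(text_path, "w", encoding="utf-8") as fh:
        fh.write("#canonical_index\tbits\tconnected\torbit_colors\tglobal_orbit_ids\n")
        for ci in range(cmap.num_canonicals):
            row = orbits.orbit_id[ci]
            colors = [int(min(np.flatnonzero(row == row[u]))) for u in range(k)]
            fh.write(
                "{}\t{}\t{}\t{}\t{}\n".format(
                    ci,
                    int(cmap.canonicals[ci]),
                    int(cmap.connected[ci]),
                    ",".join(map(str, colors)),
                    ",".join(str(int(v)) for v in row),
                )
            )
    return [map_path, perm_path, orbit_path, text_path]


def _read_header(raw: bytes, path, k: int) -> tuple[int, int, int]:
    if len(raw) < _HEADER.size:
        raise TruncatedTableError(f"{path}: file shorter than header")
    magic, version, hk, hb, nc, num_orbits = _HEADER.unpack(raw[: _HEADER.size])
    if magic != MAGIC:
        raise HeaderMismatchError(f"{path}: bad magic {magic!r}")
    if version != FORMAT_VERSION:
        raise HeaderMismatchError(f"{path}: unsupported version {version}")
    if hk != k:
        raise HeaderMismatchError(f"{path}: header k={hk}, requested k={k}")
    if hb != num_pairs(k):
        raise HeaderMismatchError(f"{path}: header b={hb} != b({k})={num_pairs(k)}")
    return hb, nc, num_orbits


def _read_file(path) -> bytes:
    if not os.path.exists(path):
        raise MissingTableError(f"table file not found: {path}")
    return Path(path).read_bytes()


def read_tables(prefix, k: int) -> tuple[CanonicalMap, GlobalOrbitTable]:
    """Load tables written by :func:`write_tables`; headers are validated
    against ``k`` and the payload lengths, and the canonical list and
    connectivity flags are reconstructed from the map payload."""
    b = num_pairs(k)
    size = 1 << b

    raw = _read_file(_map_path(prefix))
    _, nc, num_orbits = _read_header(raw, _map_path(prefix), k)
    payload = raw[_HEADER.size:]
    if len(payload) != 4 * size:
        raise TruncatedTableError(
            f"{_map_path(prefix)}: payload {len(payload)} bytes, expected {4 * size}"
        )
    words = np.frombuffer(payload, dtype="<u4")
    canon_of = (words & _CANON_MASK).astype(np.int32)
    conn_bits = (words >> _CONN_BIT) & 1

    uniq, first = np.unique(canon_of, return_index=True)
    if not np.array_equal(uniq, np.arange(nc)):
        raise TableStoreError(
            f"{_map_path(prefix)}: canonical indices are not 0..{nc - 1}"
        )
    canonicals = first.astype(np.int64)  # first occurrence = the canonical itself
    connected = conn_bits[canonicals].astype(bool)

    raw = _read_file(_perm_path(prefix))
    if len(raw) != 4 * size:
        raise TruncatedTableError(
            f"{_perm_path(prefix)}: {len(raw)} bytes, expected {4 * size}"
        )
    perm_of = np.frombuffer(raw, dtype="<u4").copy()
    for c in canonicals[: min(len(canonicals), 64)]:
        pi = unpack_permutation(int(perm_of[c]), k)
        if pi != tuple(range(k)):
            raise TableStoreError(
                f"{_perm_path(prefix)}: canonical {int(c)} has non-identity witness"
            )

    raw = _read_file(_orbit_path(prefix))
    _, onc, onum = _read_header(raw, _orbit_path(prefix), k)
    if (onc, onum) != (nc, num_orbits):
        raise HeaderMismatchError(
            f"{_orbit_path(prefix)}: header counts disagree with map file"
        )
    payload = raw[_HEADER.size:]
    if len(payload) != 4 * nc * k:
        raise TruncatedTableError(
            f"{_orbit_path(prefix)}: payload {len(payload)} bytes, expected {4 * nc * k}"
        )
    orbit_id = np.frombuffer(payload, dtype="<u4").astype(np.int32).reshape(nc, k)
    if not np.array_equal(np.unique(orbit_id), np.arange(num_orbits)):
        raise TableStoreError(
            f"{_orbit_path(prefix)}: orbit IDs are not consecutive from 0"
        )

    cmap = CanonicalMap(k, canon_of, perm_of, canonicals, connected)
    return cmap, GlobalOrbitTable(k, orbit_id, num_orbits)


def write_partition(part: PartitionResult, path) -> None:
    with open(path, "wb") as fh:
        fh.write(
            _PART_HEADER.pack(PART_MAGIC, FORMAT_VERSION, part.k, part.lo, part.hi)
        )
        fh.write(part.temp_canon.astype("<u4").tobytes())


def read_partition(path) -> PartitionResult:
    raw = _read_file(path)
    if len(raw) < _PART_HEADER.size:
        raise TruncatedTableError(f"{path}: file shorter than header")
    magic, version, k, lo, hi = _PART_HEADER.unpack(raw[: _PART_HEADER.size])
    if magic != PART_MAGIC:
        raise HeaderMismatchError(f"{path}: bad magic {magic!r}")
    if version != FORMAT_VERSION:
        raise HeaderMismatchError(f"{path}: unsupported version {version}")
    payload = raw[_PART_HEADER.size:]
    if len(payload) != 4 * (hi - lo):
        raise TruncatedTableError(
            f"{path}: payload {len(payload)} bytes, expected {4 * (hi - lo)}"
        )
    temp = np.frombuffer(payload, dtype="<u4").astype(np.int64)
    return PartitionResult(k, lo, hi, temp)
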