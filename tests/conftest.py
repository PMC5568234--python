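import pytest

from graphette import assign_global_orbits, build_canonical_map


@pytest.fixture(scope="session")
def tables():
    """Session-wide cache of (CanonicalMap, GlobalOrbitTable) per k."""
    cache = {}

    def get(k):
        if k not in cache:
            cmap = build_canonical_map(k)
            cache[k] = (cmap, assign_global_orbits(cmap))
        return cache[k]

    return get
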