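import pytest

from cxweb.cx2 import serialize_cx2
from cxweb.fixtures import FixtureSpec, random_bundle, random_hierarchy


def bundles_equal(a, b) -> bool:
    """Structural equality via the canonical serialization."""
    return serialize_cx2(a) == serialize_cx2(b)


@pytest.fixture
def small_bundle():
    """10 nodes / 15 edges with mappings and one bypass (seed 1)."""
    return random_bundle(FixtureSpec(seed=1))


@pytest.fixture
def plain_bundle():
    """5 nodes / 6 edges, defaults-only style (seed 2)."""
    return random_bundle(FixtureSpec(seed=2, node_count=5, edge_count=6,
                                     style_complexity=0))


@pytest.fixture
def hierarchy():
    """Depth-3 assembly hierarchy over a 12-node interaction network."""
    return random_hierarchy(FixtureSpec(seed=3, node_count=12, edge_count=20,
                                        hierarchy_depth=3))
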