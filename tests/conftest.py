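import numpy as np
import pytest

from gmconn.atlas import bundled_atlas
from gmconn.volume import GrayMatterVolume


@pytest.fixture(scope="session")
def atlas30():
    return bundled_atlas((30, 30, 30))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def jitter_volume(rng):
    """30^3 volume, every voxel 0.5 plus distinct jitter: all 1000 cubes pass."""
    vals = 0.5 + 0.05 * rng.random(size=(30, 30, 30))
    return GrayMatterVolume(values=vals, affine=np.eye(4), subject_id="jitter")


def random_binary_network(n, density, rng):
    """Random symmetric zero-diagonal adjacency for metric tests."""
    from gmconn.network import BinaryNetwork

    upper = rng.random((n, n)) < density
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(np.uint8)
    return BinaryNetwork(adjacency=adj, threshold_used=0.0)
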