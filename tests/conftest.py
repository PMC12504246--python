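import numpy as np
import pytest

from histoatlas.atlas import AtlasVolume, RegionNode
from histoatlas.synth import SynthSpec, make_atlas, make_series


@pytest.fixture(scope="session")
def synth_atlas():
    """Default synthetic atlas (seed 1) with its hierarchy."""
    return make_atlas(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def small_atlas():
    """A 16^3 two-label atlas for fast brute-force oracle comparisons."""
    labels = np.zeros((16, 16, 16), dtype=np.int32)
    labels[2:14, 2:14, 2:8] = 1
    labels[2:14, 2:14, 8:14] = 2
    hierarchy = [
        RegionNode(1, "lower", None, (200, 0, 0)),
        RegionNode(2, "upper", None, (0, 0, 200)),
    ]
    return AtlasVolume(
        name="small", labels=labels, midline=(0, 7.5), hierarchy=hierarchy
    )


@pytest.fixture(scope="session")
def synth_series(synth_atlas):
    atlas, _ = synth_atlas
    return make_series(atlas, 5, seed=2)


def random_anchoring(rng, width=9, height=7, scale=20.0, nr=0):
    """Random non-degenerate anchoring used by oracle-comparison tests."""
    from histoatlas.anchoring import SectionAnchoring

    while True:
        o = rng.uniform(-4, scale, size=3)
        u = rng.uniform(-scale, scale, size=3)
        v = rng.uniform(-scale, scale, size=3)
        if np.linalg.norm(np.cross(u, v)) > 1e-6:
            return SectionAnchoring(nr, width, height, o, u, v)
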