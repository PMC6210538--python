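import numpy as np
import pytest

from infantpose.features import FeatureConfig, HOGLevel
from infantpose.model import BodyModel, KinematicTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tiny_model(rng, n_parts=3, states=2, bins=2, chain=False):
    """A random small-tree model over a coarse feature grid (cell 1 px)."""
    parts = tuple(f"p{i}" for i in range(n_parts))
    edges = []
    for i in range(1, n_parts):
        parent = parts[i - 1] if chain else parts[int(rng.integers(0, i))]
        edges.append((parent, parts[i]))
    tree = KinematicTree(parts=parts, edges=tuple(edges), root=parts[0])
    spp = {p: int(states if np.isscalar(states) else states[i]) for i, p in enumerate(parts)}
    cfg = FeatureConfig(cell_size_px=1, bins=bins)
    m = BodyModel.empty(tree, spp, cfg)
    for k in m.filters:
        m.filters[k] = rng.normal(size=m.filters[k].shape)
    for e in m.deformations:
        z = rng.normal(size=m.deformations[e].shape) * 0.05
        z[..., 2:] = np.abs(z[..., 2:]) + 0.01
        m.deformations[e] = z
        m.anchors[e] = rng.normal(size=m.anchors[e].shape)
        m.cooc_pair[e] = rng.normal(size=m.cooc_pair[e].shape)
    for p in m.cooc_unary:
        m.cooc_unary[p] = rng.normal(size=m.cooc_unary[p].shape)
    m.bias = float(rng.normal())
    return m


def random_level(rng, rows=8, cols=8, bins=2):
    return HOGLevel(
        cells=rng.normal(size=(rows, cols, bins)), cell_size_px=1, scale=1.0, bins=bins
    )


@pytest.fixture
def tiny_model(rng):
    return random_tiny_model(rng)


@pytest.fixture
def tiny_level(rng):
    return random_level(rng)
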