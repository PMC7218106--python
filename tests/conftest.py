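import numpy as np
import pytest

from n2vhc.embed import Embedding
from n2vhc.graph import Network


@pytest.fixture
def triangle() -> Network:
    net = Network()
    net.add_edge("a", "b")
    net.add_edge("b", "c")
    net.add_edge("a", "c")
    return net


@pytest.fixture
def path_graph() -> Network:
    net = Network()
    net.add_edge("a", "b")
    net.add_edge("b", "c")
    return net


@pytest.fixture
def blob_embedding() -> tuple[Embedding, dict[str, int]]:
    """Four well-separated Gaussian blobs in 8 dimensions."""
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(loc=c, scale=0.3, size=(15, 8))
                   for c in (0.0, 5.0, 10.0, 15.0)])
    ids = [f"n{i:02d}" for i in range(60)]
    truth = {ids[i]: i // 15 + 1 for i in range(60)}
    return Embedding(ids, X), truth
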