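import numpy as np
import pytest

from enct import NodeConnectome


def make_random_connectome(
    n: int, density: float = 0.3, seed: int = 0, threshold: float = 1e-3
) -> NodeConnectome:
    """Random sparse symmetric connectome with log-normal weights."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < density
    w = np.zeros(len(iu))
    w[present] = np.exp(-2.0 + 0.7 * rng.standard_normal(present.sum()))
    A = np.zeros((n, n))
    A[iu, ju] = w
    A[ju, iu] = w
    return NodeConnectome(A, absence_threshold=threshold)


@pytest.fixture
def triangle() -> NodeConnectome:
    """Unit-weight triangle: 3 nodes, 3 edges, vertex-transitive."""
    A = np.ones((3, 3)) - np.eye(3)
    return NodeConnectome(A)


@pytest.fixture
def path_4_9() -> NodeConnectome:
    """Path 0-1-2 with weights 4 and 9."""
    A = np.array([[0.0, 4.0, 0.0], [4.0, 0.0, 9.0], [0.0, 9.0, 0.0]])
    return NodeConnectome(A)
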