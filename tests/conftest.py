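import numpy as np
import pytest
from hypothesis import settings

from wmnet import ConnectivityMatrix, load_aal90, load_coordinates

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def atlas():
    return load_aal90()


@pytest.fixture(scope="session")
def coords():
    return load_coordinates()


def as_matrix(values, kind="FA_bin", subject_id="s"):
    return ConnectivityMatrix(subject_id, kind, np.asarray(values, dtype=float))


def random_small_graph(rng, n, weighted, p=0.45):
    """Random symmetric adjacency on n nodes; weights in (0.2, 1] if weighted."""
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    if weighted:
        w = 0.2 + 0.8 * rng.random((n, n))
        a = a * w
    a = a + a.T
    return a
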