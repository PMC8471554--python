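import numpy as np
import pytest

from gcnet import GCMap


@pytest.fixture
def paper_graph():
    """Three-node didactic topology: p1->p2, p1->p3, p2->p1, equal weights."""
    w = np.array([[0, 1, 1], [1, 0, 0], [0, 0, 0]], dtype=float)
    return GCMap(w, ["p1", "p2", "p3"])


@pytest.fixture
def cycle2():
    """Two-node directed cycle with unit weights."""
    return GCMap(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"])


@pytest.fixture
def make_random_gcmap():
    """Factory for random sparse nonnegative GC maps."""

    def _make(rng, n, density=0.5, ensure_no_dangling=False):
        w = rng.exponential(size=(n, n)) * (rng.random((n, n)) < density)
        np.fill_diagonal(w, 0.0)
        if ensure_no_dangling:
            for i in np.flatnonzero(w.sum(axis=1) == 0):
                j = (i + 1) % n
                w[i, j] = rng.exponential() + 0.1
        return GCMap(w, [f"n{i}" for i in range(n)])

    return _make
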