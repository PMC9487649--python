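import numpy as np
import pytest

from tieclust import ProximityMatrix, fixture_intro_chain, fixture_nested_tie


@pytest.fixture
def chain():
    """d(A,B) = d(B,C) = 1, d(A,C) = 2: the minimal tied instance."""
    return fixture_intro_chain()


@pytest.fixture
def nested_tie():
    """Synthetic 10-taxon matrix with one mid-dendrogram tie between clusters."""
    return fixture_nested_tie()


@pytest.fixture
def equilateral():
    """Three items, all pairwise distances equal."""
    v = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    return ProximityMatrix(["A", "B", "C"], v, "distance", 1)


def tie_free_matrix():
    """4 items with all distinct distances and distinct update means."""
    v = np.array(
        [
            [0.0, 1.0, 5.0, 9.2],
            [1.0, 0.0, 5.4, 9.6],
            [5.0, 5.4, 0.0, 2.0],
            [9.2, 9.6, 2.0, 0.0],
        ]
    )
    return ProximityMatrix(["A", "B", "C", "D"], v, "distance", 1)


@pytest.fixture
def tie_free():
    return tie_free_matrix()
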