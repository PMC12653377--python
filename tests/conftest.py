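import numpy as np
import pytest

from cdpath.models import ItemParameterSet
from cdpath.qmatrix import QMatrix, ResponseMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def q2():
    """Tiny 2-attribute Q-matrix: two anchors plus one two-attribute item."""
    return QMatrix(
        np.array([[1, 0], [0, 1], [1, 1]]),
        ("Item1", "Item2", "Item3"),
        ("A1", "A2"),
    )


@pytest.fixture
def dina_items_q2(q2):
    """Clean DINA items for q2 (g=0.1, s=0.1)."""
    return tuple(
        ItemParameterSet(
            "DINA", tuple(q2.required_attributes(j)), np.array([0.1, 0.1]),
            label=q2.item_labels[j],
        )
        for j in range(q2.n_items)
    )


def make_responses(rng, profiles, items):
    from cdpath.models import item_class_probs, profile_index

    K = profiles.shape[1]
    P = item_class_probs(items, K)
    cls = np.array([profile_index(p) for p in profiles])
    probs = P[:, cls].T
    return ResponseMatrix((rng.random(probs.shape) < probs).astype(np.int8))
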