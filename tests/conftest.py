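import numpy as np
import pytest

from sbias import Chronogram, read_newick


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — height 2, one cherry."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star5():
    return read_newick("(A:1,B:1,C:1,D:1,E:1);")


def make_caterpillar(n_tips: int, internal_ages=None) -> Chronogram:
    """n-tip caterpillar; internal ages default to n-1, n-2, ..., 1."""
    if internal_ages is None:
        internal_ages = list(range(n_tips - 1, 0, -1))
    assert len(internal_ages) == n_tips - 1
    parent, age, labels = [], [], []
    # internals 0..n-2 chained, tips appended after
    for i, a in enumerate(internal_ages):
        parent.append(i - 1)  # -1 for the root
        age.append(float(a))
        labels.append(None)
    for i in range(n_tips):
        # tip i hangs off internal min(i, n-2)
        parent.append(min(i, n_tips - 2))
        age.append(0.0)
        labels.append(f"t{i + 1}")
    return Chronogram(parent, age, labels)


def make_balanced(depth: int, branch: float = 1.0) -> Chronogram:
    """Perfectly balanced binary tree with 2**depth tips, all branches equal."""
    parent, age, labels = [-1], [float(depth) * branch], [None]
    frontier = [0]
    for level in range(1, depth + 1):
        nxt = []
        for p in frontier:
            for _ in range(2):
                parent.append(p)
                age.append(float(depth - level) * branch)
                labels.append(None)
                nxt.append(len(parent) - 1)
        frontier = nxt
    for i, v in enumerate(frontier):
        labels[v] = f"t{i + 1}"
    return Chronogram(parent, age, labels)
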