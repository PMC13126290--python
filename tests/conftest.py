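import numpy as np
import pytest

from ploidyscale.swc import NEURITE, SOMA, NeuronTree


def make_tree(nodes, metadata=None):
    """Build a NeuronTree from (parent, type, x, y, z, radius) tuples.

    Node indices follow list order; parent -1 marks the root.
    """
    parent = np.array([n[0] for n in nodes])
    ntype = np.array([n[1] for n in nodes])
    xyz = np.array([[n[2], n[3], n[4]] for n in nodes], dtype=float)
    radius = np.array([n[5] for n in nodes], dtype=float)
    return NeuronTree(np.arange(len(nodes)), parent, ntype, xyz, radius,
                      dict(metadata or {}))


@pytest.fixture
def soma_only_tree():
    return make_tree([(-1, SOMA, 0, 0, 0, 10.0)])


@pytest.fixture
def straight_chain_tree():
    """Soma r=2 plus 5 collinear cylinder edges (r=0.5, effective l=10 each).

    The first neurite node sits 12 um from the soma centre so the stem
    contributes 10 um of soma-surface-referenced length.
    """
    nodes = [(-1, SOMA, 0, 0, 0, 2.0)]
    for i in range(5):
        nodes.append((i, NEURITE, 12.0 + 10.0 * i, 0, 0, 0.5))
    return make_tree(nodes)


@pytest.fixture
def binary_tree_depth3():
    """Symmetric binary tree: stem then 3 bifurcation generations (8 tips)."""
    nodes = [(-1, SOMA, 0, 0, 0, 1.0), (0, NEURITE, 5, 0, 0, 0.5)]
    frontier = [1]
    x = 5.0
    spread = 8.0
    for _depth in range(3):
        x += 5.0
        nxt = []
        for j, parent in enumerate(frontier):
            for sign in (-1.0, 1.0):
                y = nodes[parent][3] + sign * spread
                nodes.append((parent, NEURITE, x, y, 0, 0.5))
                nxt.append(len(nodes) - 1)
        frontier = nxt
        spread /= 2.0
    return make_tree(nodes)
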