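import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from spotclust.spot_data import SampleAnnotation, SpotMatrix


def random_clock_tree(rng, n_leaves: int) -> TreeNode:
    """Random rooted ultrametric (clock-like) tree by coalescent-style merging."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    heights = [0.0] * n_leaves
    h = 0.0
    while len(nodes) > 1:
        h += rng.uniform(0.1, 1.0)
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        right, hr = nodes.pop(j), heights.pop(j)
        left, hl = nodes.pop(i), heights.pop(i)
        left.length = h - hl
        right.length = h - hr
        nodes.append(TreeNode(children=[left, right]))
        heights.append(h)
    return nodes[0]


def random_additive_tree(rng, n_leaves: int) -> TreeNode:
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}", length=rng.uniform(0.2, 2.0)) for i in range(3)]
    root = TreeNode(children=nodes)
    tips = nodes[:]
    for i in range(3, n_leaves):
        edge = tips[rng.integers(len(tips))] if rng.random() < 0.7 else None
        if edge is None:
            internal = [n for n in root.traverse(include_self=False) if not n.is_tip()]
            edge = internal[rng.integers(len(internal))] if internal else tips[0]
        # split `edge` by inserting a new parent with a fresh tip
        parent = edge.parent
        parent.remove(edge)
        lo = edge.length * rng.uniform(0.2, 0.8)
        new_tip = TreeNode(name=f"t{i}", length=rng.uniform(0.2, 2.0))
        mid = TreeNode(children=[edge, new_tip], length=edge.length - lo)
        edge.length = lo
        parent.append(mid)
        tips.append(new_tip)
    return root


def binary_matrix(rng, n_spots: int, n_samples: int, p: float = 0.4) -> SpotMatrix:
    vals = (rng.random((n_spots, n_samples)) < p).astype(np.int8)
    return SpotMatrix(
        [f"s{i}" for i in range(n_spots)],
        [f"x{j}" for j in range(n_samples)],
        vals,
    )


def two_block_matrix(n_per_group: int = 3, n_spots_per_group: int = 20) -> SpotMatrix:
    """Two sample groups with disjoint, internally identical spot sets."""
    a = np.zeros((2 * n_spots_per_group, 2 * n_per_group), dtype=np.int8)
    a[:n_spots_per_group, :n_per_group] = 1
    a[n_spots_per_group:, n_per_group:] = 1
    ids = [f"A{j}" for j in range(n_per_group)] + [f"B{j}" for j in range(n_per_group)]
    return SpotMatrix([f"s{i}" for i in range(a.shape[0])], ids, a)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def annotation_factory():
    import pandas as pd

    def make(sample_ids, species, **extra):
        df = pd.DataFrame({"sample_id": sample_ids, "species": species, **extra})
        return SampleAnnotation(df)

    return make
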