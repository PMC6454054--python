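import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from latidyn.core_io import OtuTable, PhyloTree


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return PhyloTree(TreeNode.read(["((A:1,B:1):1,C:2);"]))


@pytest.fixture
def star_tree() -> PhyloTree:
    return PhyloTree(TreeNode.read(["(A:1,B:1,C:1,D:1);"]))


@pytest.fixture
def small_table() -> OtuTable:
    data = pd.DataFrame(
        [[5, 0, 3], [0, 5, 2], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return OtuTable(data)


def random_tree(n_tips: int, rng) -> PhyloTree:
    """Random binary tree with uniform random branch lengths (test helper,
    built by naive recursive splitting, independent of the package's Yule
    simulator)."""
    names = [f"t{i}" for i in range(n_tips)]

    def build(tips):
        if len(tips) == 1:
            return f"{tips[0]}:{rng.uniform(0.1, 1.0):.6f}"
        k = rng.integers(1, len(tips))
        left, right = tips[:k], tips[k:]
        return (
            f"({build(left)},{build(right)}):{rng.uniform(0.1, 1.0):.6f}"
        )

    order = list(rng.permutation(names))
    return PhyloTree(TreeNode.read([f"({build(order[:1])},{build(order[1:])});"]))


def random_table(tree: PhyloTree, n_samples: int, rng, depth: int = 50) -> OtuTable:
    counts = rng.multinomial(
        depth, rng.dirichlet(np.ones(tree.n_tips)), size=n_samples
    )
    return OtuTable(
        pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n_samples)], columns=tree.tip_names
        )
    )
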