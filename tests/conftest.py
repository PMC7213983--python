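import numpy as np
import pytest

from calgevo import PhyloTree, SimSpec


@pytest.fixture
def calgranulin_tree() -> PhyloTree:
    """Four-clade tree mirroring the calgranulin family layout."""
    return PhyloTree.from_newick(
        "(((A8:0.08,A9:0.08):0.05,A12:0.1):0.05,MRP126:0.15);"
    )


@pytest.fixture
def spec() -> SimSpec:
    return SimSpec(seed=1234)


def random_tree(rng: np.random.Generator, n_leaves: int, max_bl: float = 0.5):
    """Random rooted binary tree with uniform branch lengths in (0, max_bl]."""
    from calgevo.trees import Node, PhyloTree

    nodes = [Node(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(Node(name="", children=[left, right]))
    tree = PhyloTree(nodes[0])
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.uniform(0.01, max_bl))
    return tree


def random_alignment(rng: np.random.Generator, names, n_sites: int):
    from calgevo import AMINO_ACIDS, Alignment

    seqs = [
        "".join(rng.choice(list(AMINO_ACIDS), size=n_sites)) for _ in names
    ]
    return Alignment(list(names), seqs)
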