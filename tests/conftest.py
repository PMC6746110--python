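import numpy as np
import pandas as pd
import pytest

from anatidiv.io_formats import CommunityGrid, TraitSchema, TraitTable
from anatidiv.synthetic import simulate_traits, simulate_tree_ensemble
from anatidiv.trait_space import build_functional_dendrogram
from anatidiv.trees import PhyloTree


@pytest.fixture
def toy_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_grid() -> CommunityGrid:
    cells = pd.DataFrame(
        {"lat": [10.0, 20.0, -15.0, 0.0], "lon": [0.0, 10.0, 20.0, 30.0]},
        index=pd.Index(["g1", "g2", "g3", "g4"], name="cell_id"),
    )
    presence = pd.DataFrame(
        [[1, 0, 1], [1, 1, 1], [0, 0, 1], [0, 0, 0]],
        index=cells.index,
        columns=["A", "B", "C"],
    )
    return CommunityGrid(cells, presence)


@pytest.fixture
def small_trait_table() -> TraitTable:
    schema = TraitSchema(
        kinds={
            "mass": "continuous",
            "diet_a": "percentage",
            "diet_b": "percentage",
            "migratory": "binary",
        },
        percentage_groups={"diet": ["diet_a", "diet_b"]},
    )
    df = pd.DataFrame(
        {
            "mass": [1.0, 2.0, 3.0],
            "diet_a": [60.0, 40.0, 0.0],
            "diet_b": [40.0, 60.0, 100.0],
            "migratory": [1.0, 1.0, 0.0],
        },
        index=["s1", "s2", "s3"],
    )
    return TraitTable(df, schema)


# Shared 60-species pool: building it once keeps the suite fast.
@pytest.fixture(scope="session")
def pool60():
    trees = simulate_tree_ensemble(60, 5, seed=101)
    traits = simulate_traits(trees[0], seed=101)
    dendro = build_functional_dendrogram(traits)
    return trees, traits, dendro


def random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random rooted bifurcating tree with uniform branch lengths (test helper)."""
    labels = [f"t{i}" for i in range(n_tips)]
    parent = [-1]
    length = [0.0]
    tips = [0]
    while len(tips) < n_tips:
        v = tips.pop(int(rng.integers(len(tips))))
        a, b = len(parent), len(parent) + 1
        parent.extend([v, v])
        length.extend(rng.uniform(0.1, 2.0, 2).tolist())
        tips.extend([a, b])
    # re-index so tips come first
    order = tips + [i for i in range(len(parent)) if i not in tips]
    pos = {old: new for new, old in enumerate(order)}
    new_parent = np.full(len(parent), -1, dtype=np.int64)
    new_length = np.zeros(len(parent))
    for old, new in pos.items():
        p = parent[old]
        new_parent[new] = pos[p] if p != -1 else -1
        new_length[new] = length[old]
    return PhyloTree(new_parent, new_length, labels)


def spanning_sum_oracle(tree: PhyloTree, species: set[str], convention: str) -> float:
    """Brute-force edge-union oracle: an edge is on the spanned subtree iff its
    subtree contains a selected tip (root convention) -- and, for the mrca
    convention, does not contain all of them."""
    n = tree.n_nodes
    desc = [set() for _ in range(n)]
    for i, lab in enumerate(tree.tip_labels):
        v = i
        while v != -1:
            desc[v].add(lab)
            v = tree.parent[v]
    total = 0.0
    for v in range(n):
        hit = desc[v] & species
        if not hit:
            continue
        if convention == "mrca" and species <= desc[v]:
            continue
        total += tree.length[v]
    return total
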