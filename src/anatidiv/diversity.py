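"""Community diversity metrics: TD (richness), Faith's PD, dendrogram FD.

PD and FD are the same computation -- the branch-length sum of the subtree
spanned by a community's species -- applied to a phylogenetic tree and to
the functional dendrogram respectively.  PD is averaged over a tree
ensemble to integrate over phylogenetic uncertainty.

Two spanning conventions are supported.  ``root`` (default) sums every
edge on the union of tip-to-root paths, so a single-species community has
positive PD/FD and the metric is monotone under species addition.
``mrca`` restricts the sum to edges below the set's most recent common
ancestor, so singletons score 0.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import CommunityGrid
from .trait_space import FunctionalDendrogram
from .trees import PhyloTree, TreeEnsemble

__all__ = [
    "taxonomic_diversity",
    "subtree_branch_sum",
    "ensemble_pd",
    "dendrogram_fd",
    "diversity_map",
]


def taxonomic_diversity(grid: CommunityGrid) -> pd.Series:
    """Species richness per cell."""
    return grid.richness().rename("TD")


def subtree_branch_sum(tree: PhyloTree, species: Iterable[str], convention: str = "root") -> float:
    return tree.branch_sum(species, convention=convention)


def ensemble_pd(trees: TreeEnsemble, species: Iterable[str], convention: str = "root") -> float:
    """Faith's PD averaged over the tree ensemble."""
    sp = list(species)
    return float(np.mean([t.branch_sum(sp, convention=convention) for t in trees]))


def dendrogram_fd(dendro: FunctionalDendrogram, species: Iterable[str], convention: str = "root") -> float:
    """Petchey-Gaston functional diversity: branch sum on the UPGMA dendrogram."""
    return dendro.tree.branch_sum(species, convention=convention)


def diversity_map(
    grid: CommunityGrid,
    trees: TreeEnsemble,
    dendro: FunctionalDendrogram,
    convention: str = "root",
) -> pd.DataFrame:
    """Per-cell TD, FD and ensemble-mean PD with cell coordinates.

    Empty cells are reported as (0, 0, 0) rather than errors so that
    whole-grid maps are total.  Iteration is tree-outer / cell-inner; the
    result is value-identical to computing each cell independently.
    """
    grid.check_against_pool(trees.label_set())
    grid.check_against_pool(dendro.tree.label_set())
    cell_species = {cid: grid.species_in(cid) for cid in grid.cell_ids}
    td = taxonomic_diversity(grid)
    fd = {
        cid: (dendro.tree.branch_sum(sp, convention) if sp else 0.0)
        for cid, sp in cell_species.items()
    }
    pd_sum = {cid: 0.0 for cid in grid.cell_ids}
    for tree in trees:
        for cid, sp in cell_species.items():
            if sp:
                pd_sum[cid] += tree.branch_sum(sp, convention)
    ntree = len(trees)
    out = pd.DataFrame(
        {
            "lat": grid.cells["lat"],
            "lon": grid.cells["lon"],
            "TD": td,
            "FD": pd.Series(fd),
            "PD": pd.Series({c: v / ntree for c, v in pd_sum.items()}),
        }
    )
    out.index.name = "cell_id"
    return out
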