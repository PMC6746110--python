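"""Faunal regions from community composition.

Communities are filtered (named range-restricted species dropped first,
then cells below a richness floor), pairwise Sørensen dissimilarity is
computed on presence/absence, and the cells are clustered with the same
UPGMA engine used for the functional dendrogram.  The number of groups is
a user decision informed by the within-group mean dissimilarity curve over
k = 1..15; no automatic elbow detection is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CommunityGrid, ValidationError
from .trait_space import cut_linkage, upgma

__all__ = [
    "filter_communities",
    "sorensen_matrix",
    "cluster_regions",
    "within_group_curve",
    "hemisphere_split",
    "RegionModel",
    "delineate_regions",
]

# O(n^2) dissimilarity matrices get large quickly; warn past this many cells.
MEMORY_GUARD_CELLS = 5000


def filter_communities(
    grid: CommunityGrid,
    drop_species: tuple[str, ...] = (),
    min_richness: int = 4,
) -> CommunityGrid:
    """Drop named species columns, then cells with richness < min_richness.

    The order matters and is fixed: a cell whose richness falls below the
    floor only because a dropped species is removed is itself removed.
    """
    unknown = [s for s in drop_species if s not in grid.species]
    if unknown:
        raise ValidationError(f"species to drop not present in grid: {unknown}")
    keep_cols = [s for s in grid.species if s not in set(drop_species)]
    presence = grid.presence[keep_cols]
    rich = presence.sum(axis=1)
    keep_cells = rich.index[rich >= min_richness]
    return CommunityGrid(grid.cells.loc[keep_cells].copy(), presence.loc[keep_cells].copy())


def sorensen_matrix(grid: CommunityGrid) -> pd.DataFrame:
    """Pairwise Sørensen dissimilarity D = 1 - 2a / (2a + b + c).

    a = species shared by the two cells; b, c = species unique to each.
    Every cell must hold at least one species.
    """
    A = grid.presence.to_numpy(float)
    rich = A.sum(axis=1)
    if (rich == 0).any():
        empty = [cid for cid, r in zip(grid.cell_ids, rich) if r == 0]
        raise ValidationError(f"Sørensen undefined for empty cells: {empty[:5]}")
    if len(rich) > MEMORY_GUARD_CELLS:
        warnings.warn(
            f"Sørensen matrix over {len(rich)} cells needs "
            f"~{8 * len(rich) ** 2 / 1e9:.1f} GB", stacklevel=2,
        )
    shared = A @ A.T
    denom = rich[:, None] + rich[None, :]
    D = 1.0 - 2.0 * shared / denom
    D = np.clip(D, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=grid.cell_ids, columns=grid.cell_ids)


def cluster_regions(D: pd.DataFrame, k: int) -> pd.Series:
    """UPGMA on the cell dissimilarity matrix, cut at k groups (labels 1..k)."""
    Z = upgma(D)
    labels = cut_linkage(Z, k)
    return pd.Series(labels, index=D.index, name="cluster")


def within_group_curve(D: pd.DataFrame, k_max: int = 15) -> pd.DataFrame:
    """Mean within-group pairwise dissimilarity for k = 1..k_max group cuts.

    At k = 1 this is the grand mean of the upper triangle of D.  Pairs are
    pooled across groups; singleton groups contribute no pairs.
    """
    Z = upgma(D)
    vals = D.to_numpy(float)
    n = vals.shape[0]
    iu = np.triu_indices(n, k=1)
    rows = []
    for k in range(1, min(k_max, n) + 1):
        labels = cut_linkage(Z, k)
        same = labels[iu[0]] == labels[iu[1]]
        mean_d = float(vals[iu][same].mean()) if same.any() else 0.0
        rows.append((k, mean_d))
    return pd.DataFrame(rows, columns=["k", "mean_within_dissimilarity"])


def hemisphere_split(
    labels: pd.Series,
    lat: pd.Series,
    mapping: dict[int, str] | None = None,
) -> pd.Series:
    """Assign each cluster to 'north' or 'south'.

    An explicit cluster -> hemisphere mapping wins; otherwise the sign of
    the cluster's mean cell latitude decides, and an exactly-zero mean
    latitude demands an explicit mapping.
    """
    out = {}
    for cl in sorted(labels.unique()):
        if mapping is not None and cl in mapping:
            hemi = mapping[cl]
            if hemi not in ("north", "south"):
                raise ValidationError(f"hemisphere must be 'north' or 'south', got {hemi!r}")
        else:
            mean_lat = float(lat[labels == cl].mean())
            if mean_lat == 0.0:
                raise ValidationError(
                    f"cluster {cl} has mean latitude exactly 0; supply an explicit mapping"
                )
            hemi = "north" if mean_lat > 0 else "south"
        out[cl] = hemi
    return labels.map(out).rename("hemisphere")


@dataclass
class RegionModel:
    grid: CommunityGrid            # filtered cells
    dissimilarity: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series              # cluster per retained cell
    hemisphere: pd.Series
    curve: pd.DataFrame

    def table(self) -> pd.DataFrame:
        out = self.grid.cells.copy()
        out["cluster"] = self.labels
        out["hemisphere"] = self.hemisphere
        out.index.name = "cell_id"
        return out


def delineate_regions(
    grid: CommunityGrid,
    drop_species: tuple[str, ...] = (),
    min_richness: int = 4,
    k: int = 12,
    k_max: int = 15,
    hemisphere_mapping: dict[int, str] | None = None,
) -> RegionModel:
    """Filter, Sørensen, UPGMA, cut at k, hemisphere assignment — end to end."""
    filtered = filter_communities(grid, drop_species, min_richness)
    if len(filtered.cell_ids) < 2:
        raise ValidationError("fewer than 2 communities remain after filtering")
    D = sorensen_matrix(filtered)
    Z = upgma(D)
    k_eff = min(k, len(filtered.cell_ids))
    labels = pd.Series(cut_linkage(Z, k_eff), index=D.index, name="cluster")
    hemi = hemisphere_split(labels, filtered.cells["lat"], hemisphere_mapping)
    vals = D.to_numpy(float)
    iu = np.triu_indices(vals.shape[0], k=1)
    rows = []
    for kk in range(1, min(k_max, len(filtered.cell_ids)) + 1):
        lab = cut_linkage(Z, kk)
        same = lab[iu[0]] == lab[iu[1]]
        mean_d = float(vals[iu][same].mean()) if same.any() else 0.0
        rows.append((kk, mean_d))
    curve = pd.DataFrame(rows, columns=["k", "mean_within_dissimilarity"])
    return RegionModel(filtered, D, Z, labels, hemi, curve)
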