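"""Functional trait space: Gower similarity, dissimilarity, UPGMA dendrogram.

The functional dendrogram is built the classic way: Gower similarity on the
mixed-type trait matrix, dissimilarity D = 1 - S, then UPGMA (average
linkage) clustering.  The branch-length sum of the subtree spanned by a
community on this dendrogram is the dendrogram-based functional diversity
index used throughout the pipeline.

UPGMA is implemented here (rather than taken from scipy) so that merge
tie-breaking is defined -- ties go to the pair whose lexicographically
smallest member label is smallest -- making the dendrogram a function of
the labeled dissimilarity matrix alone, independent of row order and
platform.  The scipy implementation serves as a cross-check in the test
suite on matrices without ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TraitTable, ValidationError
from .trees import PhyloTree

__all__ = [
    "gower_similarity",
    "to_dissimilarity",
    "upgma",
    "cut_linkage",
    "FunctionalDendrogram",
    "build_functional_dendrogram",
]


def gower_similarity(traits: TraitTable, log_transform: tuple[str, ...] = ()) -> pd.DataFrame:
    """Gower similarity matrix over all species pairs.

    Per-trait similarity: continuous and percentage traits score
    ``1 - |x_i - x_j| / range`` with the range taken over the full species
    pool; binary traits score 1 on agreement, 0 otherwise.  The similarity
    of a pair is the unweighted mean over the traits observed in both
    species (pairwise deletion of missing values).  Traits with zero range
    carry no information and are dropped with a warning.
    """
    df = traits.data.copy()
    for t in log_transform:
        if traits.schema.kinds.get(t) != "continuous":
            raise ValidationError(f"log transform requested for non-continuous trait {t!r}")
        if (df[t] <= 0).any():
            raise ValidationError(f"log transform of non-positive values in trait {t!r}")
        df[t] = np.log10(df[t])
    species = list(df.index)
    n = len(species)
    if n < 2:
        raise ValidationError("Gower similarity needs at least 2 species")
    sim_sum = np.zeros((n, n))
    weight = np.zeros((n, n))
    for trait, kind in traits.schema.kinds.items():
        x = df[trait].to_numpy(float)
        ok = np.isfinite(x)
        valid = np.outer(ok, ok)
        if kind == "binary":
            s = (x[:, None] == x[None, :]).astype(float)
        else:
            rng = np.nanmax(x) - np.nanmin(x)
            if not np.isfinite(rng) or rng == 0:
                warnings.warn(
                    f"trait {trait!r} has zero range and is dropped from Gower similarity",
                    stacklevel=2,
                )
                continue
            s = 1.0 - np.abs(x[:, None] - x[None, :]) / rng
        sim_sum += np.where(valid, np.nan_to_num(s), 0.0)
        weight += valid
    off_diag = ~np.eye(n, dtype=bool)
    if (weight[off_diag] == 0).any():
        i, j = np.argwhere((weight == 0) & off_diag)[0]
        raise ValidationError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no observed trait"
        )
    weight[weight == 0] = 1.0  # diagonal of all-missing species; forced to 1 below
    S = sim_sum / weight
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=species, columns=species)


def to_dissimilarity(S: pd.DataFrame) -> pd.DataFrame:
    """D = 1 - S, with the diagonal forced to exactly zero."""
    vals = S.to_numpy(float)
    if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
        raise ValidationError("similarity values outside [0, 1]")
    D = 1.0 - vals
    D = np.clip(D, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=S.index, columns=S.columns)


def _check_dissimilarity(D: np.ndarray) -> None:
    if not np.isfinite(D).all():
        raise ValidationError("dissimilarity matrix contains non-finite entries")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix is not symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValidationError("dissimilarity matrix diagonal is not zero")


def upgma(D: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomeration of a labeled dissimilarity matrix.

    Returns a scipy-style linkage matrix ``Z`` of shape ``(n-1, 4)``: each
    row is ``(id_a, id_b, merge_dissimilarity, new_size)`` with original
    observations numbered ``0..n-1`` in label order and merged clusters
    numbered onward.  Ties in the minimum inter-group average are broken by
    the lexicographically smallest member label (then the second smallest),
    so the result does not depend on input row order.
    """
    labels = [str(x) for x in D.index]
    W = D.to_numpy(float).copy()
    _check_dissimilarity(W)
    n = len(labels)
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 entities")
    np.fill_diagonal(W, np.inf)
    active = list(range(n))           # matrix slots currently in play
    cid = list(range(n))              # cluster id per slot
    size = [1] * n
    minlab = [labels[i] for i in range(n)]
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = W[np.ix_(active, active)]
        m = sub.min()
        ii, jj = np.where(sub <= m)   # exact ties only
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            i, j = active[a], active[b]
            key = tuple(sorted((minlab[i], minlab[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        a_id, b_id = sorted((cid[i], cid[j]))
        Z[step] = (a_id, b_id, m, size[i] + size[j])
        # UPGMA update: size-weighted average of the two merged rows
        wi, wj = size[i], size[j]
        new_row = (wi * W[i, :] + wj * W[j, :]) / (wi + wj)
        W[i, :] = new_row
        W[:, i] = new_row
        W[i, i] = np.inf
        cid[i] = n + step
        size[i] = wi + wj
        minlab[i] = min(minlab[i], minlab[j])
        active.remove(j)
    return Z


def cut_linkage(Z: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting a linkage at k groups."""
    from scipy.cluster.hierarchy import fcluster

    n = Z.shape[0] + 1
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    return fcluster(Z, t=k, criterion="maxclust")


@dataclass
class FunctionalDendrogram:
    """Ultrametric UPGMA tree over species, with its linkage matrix.

    Node heights are half the merge dissimilarity, so the cophenetic
    (tip-to-tip path) distance between two species equals the dissimilarity
    at which their groups merged.
    """

    tree: PhyloTree
    linkage: np.ndarray
    labels: list[str]

    @classmethod
    def from_linkage(cls, Z: np.ndarray, labels: list[str]) -> "FunctionalDendrogram":
        n = len(labels)
        n_nodes = 2 * n - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        height = np.zeros(n_nodes)
        for row in range(n - 1):
            a, b, d, _ = Z[row]
            node = n + row
            parent[int(a)] = node
            parent[int(b)] = node
            height[node] = d / 2.0
        length = np.zeros(n_nodes)
        for i in range(n_nodes):
            if parent[i] >= 0:
                length[i] = height[parent[i]] - height[i]
        return cls(PhyloTree(parent, length, list(labels)), np.asarray(Z, float), list(labels))

    def cophenetic(self) -> pd.DataFrame:
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        C = squareform(cophenet(self.linkage))
        return pd.DataFrame(C, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        return self.tree.to_newick()


def build_functional_dendrogram(
    traits: TraitTable, log_transform: tuple[str, ...] = ()
) -> FunctionalDendrogram:
    """Gower -> D = 1 - S -> UPGMA, end to end."""
    S = gower_similarity(traits, log_transform=log_transform)
    D = to_dissimilarity(S)
    Z = upgma(D)
    return FunctionalDendrogram.from_linkage(Z, [str(x) for x in D.index])
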