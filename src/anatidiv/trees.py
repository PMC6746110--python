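"""Rooted phylogenetic trees with branch lengths, and ensembles thereof.

Trees are stored as flat parent-pointer arrays, which keeps the hot
operation of the whole pipeline -- summing the branch lengths of the
subtree spanned by a species set (Faith's PD and, on a functional
dendrogram, Petchey-Gaston FD) -- a tight loop over integer arrays.
Newick parsing and serialization are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "PhyloTree",
    "TreeEnsemble",
    "read_newick_ensemble",
    "write_newick_ensemble",
]


class TreeError(ValueError):
    """Raised for malformed trees, unknown tip labels, or ensemble mismatches."""


@dataclass
class PhyloTree:
    """A rooted tree with non-negative branch lengths and uniquely labeled tips.

    Nodes are integers ``0 .. n_nodes-1``; tips occupy ``0 .. n_tips-1`` in the
    order of ``tip_labels``.  ``parent[root] == -1``.  ``length[i]`` is the
    length of the edge above node ``i`` (the root's entry holds the root edge
    length, usually 0).
    """

    parent: np.ndarray
    length: np.ndarray
    tip_labels: list[str]
    _tip_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=float)
        if len(self.tip_labels) != len(set(self.tip_labels)):
            raise TreeError("duplicate tip labels")
        if np.any(self.length < 0):
            raise TreeError("negative branch length")
        if int((self.parent == -1).sum()) != 1:
            raise TreeError("tree must have exactly one root")
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def label_set(self) -> frozenset[str]:
        return frozenset(self.tip_labels)

    def total_branch_length(self) -> float:
        return float(self.length.sum())

    def tip_indices(self, species: Iterable[str]) -> list[int]:
        idx = []
        for s in species:
            try:
                idx.append(self._tip_index[s])
            except KeyError:
                raise TreeError(f"unknown species label: {s!r}") from None
        return idx

    def branch_sum(self, species: Iterable[str], convention: str = "root") -> float:
        """Branch-length sum of the subtree spanned by *species*.

        ``convention="root"``: sum of all edges on the union of tip-to-root
        paths (Faith's PD including the path to the root; singletons get the
        length of their root path).  ``convention="mrca"``: same, restricted
        to edges strictly below the most recent common ancestor of the set;
        a singleton therefore scores 0.
        """
        if convention not in ("root", "mrca"):
            raise ValueError(f"unknown convention: {convention!r}")
        tips = self.tip_indices(species)
        if not tips:
            raise TreeError("species set is empty")
        parent = self.parent
        length = self.length
        marked = np.zeros(self.n_nodes, dtype=bool)
        total = 0.0
        for t in tips:
            v = t
            while v != -1 and not marked[v]:
                marked[v] = True
                total += length[v]
                v = parent[v]
        if convention == "mrca":
            # Walk the first tip's root path; the MRCA is the deepest node of
            # that path reached by every other tip.
            path0 = []
            v = tips[0]
            while v != -1:
                path0.append(v)
                v = parent[v]
            pos = {node: i for i, node in enumerate(path0)}
            mrca_pos = 0
            for t in tips[1:]:
                v = t
                while v not in pos:
                    v = parent[v]
                mrca_pos = max(mrca_pos, pos[v])
            for node in path0[mrca_pos:]:
                total -= length[node]
        return total

    def relabeled(self, new_labels: Sequence[str]) -> "PhyloTree":
        """Same topology and lengths with tips relabeled positionally."""
        if len(new_labels) != self.n_tips:
            raise TreeError("label count mismatch")
        return PhyloTree(self.parent.copy(), self.length.copy(), list(new_labels))

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        leaves = [nd for nd in tree.leaf_node_iter()]
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        nodes = leaves + internals
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.zeros(len(nodes), dtype=float)
        labels = []
        for nd in leaves:
            if nd.taxon is None or nd.taxon.label is None:
                raise TreeError("unlabeled tip")
            labels.append(str(nd.taxon.label).replace(" ", "_"))
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            ln = nd.edge.length
            if ln is not None:
                if ln < 0:
                    raise TreeError(f"negative branch length {ln}")
                length[i] = float(ln)
        return cls(parent, length, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"Newick parse failure: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)

        def render(v: int) -> str:
            if not children[v]:
                return f"{self.tip_labels[v]}:{self.length[v]:.17g}"
            inner = ",".join(render(c) for c in children[v])
            if self.parent[v] == -1:
                return f"({inner})"
            return f"({inner}):{self.length[v]:.17g}"

        return render(self.root) + ";"


@dataclass
class TreeEnsemble:
    """An ordered collection of trees over one shared species pool."""

    trees: list[PhyloTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("ensemble must contain at least one tree")
        ref = self.trees[0].label_set()
        for k, t in enumerate(self.trees[1:], start=1):
            if t.label_set() != ref:
                diff = sorted(ref.symmetric_difference(t.label_set()))
                raise TreeError(
                    f"tree {k} tip set differs from tree 0; symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    def label_set(self) -> frozenset[str]:
        return self.trees[0].label_set()


def read_newick_ensemble(path) -> TreeEnsemble:
    """Read a multi-tree Newick file (one tree per line or a tree stream)."""
    with open(path) as fh:
        text = fh.read()
    try:
        tl = dendropy.TreeList.get(data=text, schema="newick")
    except Exception as exc:
        raise TreeError(f"Newick parse failure in {path}: {exc}") from exc
    if len(tl) == 0:
        raise TreeError(f"no trees found in {path}")
    return TreeEnsemble([PhyloTree.from_dendropy(t) for t in tl])


def write_newick_ensemble(ensemble: TreeEnsemble, path) -> None:
    with open(path, "w") as fh:
        for t in ensemble:
            fh.write(t.to_newick() + "\n")
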