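"""Branch-table representation of phylogenetic and functional trees.

Diversity and endemism computations only need, for every branch, its
length and the set of tips below it. Trees are therefore flattened to a
(branch x species) membership matrix plus a length vector — built either
from a rooted phylogeny (Newick / dendropy) or from a functional
dendrogram (Gower distance on the trait table + UPGMA clustering).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


@dataclass
class FeatureTree:
    """A rooted tree flattened to branches: lengths + tips-below membership."""

    species: list[str]
    lengths: np.ndarray  # (n_branches,)
    membership: np.ndarray  # (n_branches, n_species) bool
    kind: str = "phylogenetic"  # phylogenetic | functional

    def __post_init__(self) -> None:
        if (self.lengths < 0).any():
            raise ValueError("branch lengths must be >= 0")
        if self.membership.shape != (len(self.lengths), len(self.species)):
            raise ValueError("membership shape mismatch")

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def root_to_tip(self) -> np.ndarray:
        """Summed branch length above each tip."""
        return self.lengths @ self.membership

    def pairwise_distances(self) -> np.ndarray:
        """Patristic distance matrix between tips."""
        L = self.lengths[:, None] * self.membership
        shared = L.T @ self.membership  # sum of lengths of branches containing both
        c = self.root_to_tip()
        return c[:, None] + c[None, :] - 2.0 * shared

    def reindex(self, species: list[str]) -> "FeatureTree":
        missing = set(species) - set(self.species)
        if missing:
            raise KeyError(f"species missing from {self.kind} tree: {sorted(missing)}")
        idx = [self.species.index(s) for s in species]
        m = self.membership[:, idx]
        keep = m.any(axis=1)
        return FeatureTree(list(species), self.lengths[keep], m[keep], self.kind)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, kind: str = "phylogenetic") -> "FeatureTree":
        leaves = list(tree.leaf_node_iter())
        species = [lf.taxon.label for lf in leaves]
        index = {lf: i for i, lf in enumerate(leaves)}
        lengths, rows = [], []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # skip the root edge
            el = node.edge.length
            lengths.append(0.0 if el is None else float(el))
            row = np.zeros(len(species), dtype=bool)
            for lf in node.leaf_iter():
                row[index[lf]] = True
            rows.append(row)
        return cls(species, np.asarray(lengths), np.asarray(rows), kind)

    @classmethod
    def from_newick(cls, newick: str, kind: str = "phylogenetic") -> "FeatureTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree, kind)

    @classmethod
    def star(cls, species: list[str], branch_length: float = 1.0) -> "FeatureTree":
        n = len(species)
        return cls(
            list(species), np.full(n, branch_length), np.eye(n, dtype=bool), "phylogenetic"
        )

    @classmethod
    def from_traits(cls, traits: pd.DataFrame) -> "FeatureTree":
        """Ultrametric functional dendrogram: Gower distance + UPGMA."""
        d = gower_distance(traits)
        return cls.from_linkage(
            linkage(squareform(d, checks=False), method="average"),
            list(traits.index),
            kind="functional",
        )

    @classmethod
    def from_linkage(cls, Z: np.ndarray, species: list[str], kind: str = "functional") -> "FeatureTree":
        n = len(species)
        heights = np.concatenate([np.zeros(n), Z[:, 2]])
        members: list[np.ndarray] = [np.eye(n, dtype=bool)[i] for i in range(n)]
        parent_height = np.zeros(2 * n - 1)
        for k, (a, b, h, _) in enumerate(Z):
            members.append(members[int(a)] | members[int(b)])
            parent_height[int(a)] = h
            parent_height[int(b)] = h
        lengths, rows = [], []
        for node in range(2 * n - 2):  # root (last) has no parent edge
            lengths.append(parent_height[node] - heights[node])
            rows.append(members[node])
        return cls(list(species), np.asarray(lengths), np.asarray(rows), kind)


def gower_distance(traits: pd.DataFrame) -> np.ndarray:
    """Gower distance for continuous traits: mean range-normalized |difference|."""
    X = traits.to_numpy(dtype=float)
    rng = X.max(axis=0) - X.min(axis=0)
    rng[rng == 0] = 1.0
    diff = np.abs(X[:, None, :] - X[None, :, :]) / rng
    return diff.mean(axis=2)
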