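"""Rooted phylogenetic tree with branch lengths, backed by flat arrays.

The container is deliberately minimal: parsing and serialisation are
delegated to :mod:`dendropy`, while the numeric traversals needed by the
diversity algorithms (postorder walks, leaf-descendant incidence, patristic
distances) are exposed as cached numpy arrays.
"""

from __future__ import annotations

import warnings
from functools import cached_property
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import LookupError_, MalformedInputError, ValidationError

__all__ = ["PhyloTree"]


class PhyloTree:
    """Immutable rooted tree over uniquely labelled leaves.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder (root last).
    ``branch_length[i]`` is the length of the edge above node ``i``;
    the root carries 0. All lengths are non-negative and mandatory on
    non-root edges.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_length: Sequence[float],
        leaf_labels: dict[str, int],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        self.leaf_index = dict(leaf_labels)
        self._validate()

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        nodes = list(dtree.postorder_node_iter())
        if len(nodes) < 3:
            raise ValidationError("tree must contain at least two leaves")
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes), dtype=np.float64)
        labels: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValidationError(
                        "branch length missing on a non-root edge; lengths are "
                        "mandatory because diversity sums are undefined without them"
                    )
                blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                label = None if nd.taxon is None else nd.taxon.label
                if not label:
                    raise ValidationError("leaf with empty or missing label")
                if label in labels:
                    raise ValidationError(f"duplicate leaf label: {label!r}")
                labels[label] = i
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        from dendropy.dataio.newickreader import NewickReader

        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValidationError(f"duplicate leaf label: {exc}") from exc
        except Exception as exc:  # dendropy raises several parser classes
            raise MalformedInputError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    def _validate(self) -> None:
        n = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0] != n - 1:
            raise ValidationError("nodes must be in postorder with the root last")
        if np.any(self.branch_length < 0):
            raise ValidationError("negative branch length")
        n_children = np.bincount(self.parent[self.parent >= 0], minlength=n)
        is_leaf = n_children == 0
        if np.any((n_children == 1)):
            raise ValidationError("internal node with a single child")
        leaf_idx = set(np.flatnonzero(is_leaf).tolist())
        if set(self.leaf_index.values()) != leaf_idx:
            raise ValidationError("leaf label map does not match tree topology")
        self._is_leaf = is_leaf

    # ------------------------------------------------------------------ #
    # basic structure
    # ------------------------------------------------------------------ #

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)

    @cached_property
    def leaf_labels(self) -> list[str]:
        """Leaf labels sorted lexicographically (the canonical leaf order)."""
        return sorted(self.leaf_index)

    @cached_property
    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def leaf_ids(self, labels: Iterable[str]) -> np.ndarray:
        """Map leaf labels to their column indices in :attr:`leaf_matrix`."""
        order = {lab: j for j, lab in enumerate(self.leaf_labels)}
        cols = []
        for lab in labels:
            if lab not in order:
                raise LookupError_(f"unknown leaf label: {lab!r}")
            cols.append(order[lab])
        return np.asarray(cols, dtype=np.int64)

    # ------------------------------------------------------------------ #
    # numeric views
    # ------------------------------------------------------------------ #

    @cached_property
    def leaf_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves): entry [v, j] true iff leaf j is in clade v.

        Leaf columns follow :attr:`leaf_labels` order.
        """
        M = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        for j, lab in enumerate(self.leaf_labels):
            M[self.leaf_index[lab], j] = True
        for v in range(self.n_nodes):  # postorder: children precede parents
            p = self.parent[v]
            if p >= 0:
                M[p] |= M[v]
        return M

    @cached_property
    def leaf_depths(self) -> np.ndarray:
        """Root-to-leaf path lengths in :attr:`leaf_labels` order."""
        bl = self.branch_length
        M = self.leaf_matrix
        return bl @ M

    @cached_property
    def patristic_matrix(self) -> np.ndarray:
        """All-pairs leaf distances (leaf order = :attr:`leaf_labels`)."""
        M = self.leaf_matrix.astype(np.float64)
        shared = (M * self.branch_length[:, None]).T @ M  # shared root-path length
        d = self.leaf_depths
        out = d[:, None] + d[None, :] - 2.0 * shared
        np.fill_diagonal(out, 0.0)
        return out

    def check_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """Warn (and return False) if leaf depths differ beyond tolerance."""
        d = self.leaf_depths
        spread = d.max() - d.min()
        scale = max(d.max(), 1.0)
        if spread > rel_tol * scale:
            warnings.warn(
                "tree is not ultrametric (leaf depth spread "
                f"{spread:.3g}); diversity values remain valid but are not "
                "on a common time scale",
                stacklevel=2,
            )
            return False
        return True

    # ------------------------------------------------------------------ #
    # serialisation
    # ------------------------------------------------------------------ #

    def to_newick(self) -> str:
        """Deterministic Newick string (children in stored order, %.12g lengths)."""
        label_of = {i: lab for lab, i in self.leaf_index.items()}

        parts: dict[int, str] = {}
        for v in range(self.n_nodes):  # postorder
            if self._is_leaf[v]:
                lab = label_of[v]
                if any(c in lab for c in "(),:;[] '\t"):
                    lab = "'" + lab.replace("'", "''") + "'"
                parts[v] = lab
            else:
                inner = ",".join(parts[c] for c in self.children[v])
                parts[v] = f"({inner})"
            if self.parent[v] >= 0:
                parts[v] += f":{self.branch_length[v]:.12g}"
        return parts[self.root] + ";"
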