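"""Rooted, strictly binary phylogenies with branch lengths.

The comparative analyses in this package assume a fully resolved rooted tree
whose tips are the species under study.  This module wraps a
:class:`dendropy.Tree` with the validation those analyses require (binary
topology, strictly positive branch lengths, unique tip labels) and provides a
canonical child ordering so that every quantity derived from the tree —
independent contrasts in particular — is deterministic regardless of how the
newick string orders children.
"""

from __future__ import annotations

import io as _io
from typing import Mapping

import dendropy
import numpy as np


class PhylogenyError(ValueError):
    """Raised when a tree violates the structural requirements."""


class Phylogeny:
    """A rooted strictly binary tree with positive branch lengths.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  Validated on construction: every internal node
        must have exactly two children, every non-root edge a branch length
        > 0, and tip labels must be unique and non-empty.  The root edge may
        carry no length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        # canonical child order: by lexicographically smallest descendant tip
        self._min_tip = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._min_tip[node] = node.taxon.label
            else:
                self._min_tip[node] = min(self._min_tip[c] for c in node.child_nodes())
        self._contrast_cache = None

    # ------------------------------------------------------------------ build
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Newick string with branch lengths, canonical child order."""
        buf = _io.StringIO()
        self._write_node(self._tree.seed_node, buf)
        buf.write(";")
        return buf.getvalue()

    def _write_node(self, node, buf) -> None:
        if node.is_leaf():
            buf.write(node.taxon.label)
        else:
            buf.write("(")
            children = self._ordered_children(node)
            for k, child in enumerate(children):
                if k:
                    buf.write(",")
                self._write_node(child, buf)
            buf.write(")")
        if node.parent_node is not None:
            buf.write(f":{node.edge.length:.10g}")

    # --------------------------------------------------------------- validate
    def _validate(self) -> None:
        seen = set()
        root = self._tree.seed_node
        if root is None:
            raise PhylogenyError("empty tree")
        n_tips = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                n_tips += 1
                label = node.taxon.label if node.taxon is not None else None
                if not label:
                    raise PhylogenyError("tip with empty label")
                if label in seen:
                    raise PhylogenyError(f"duplicate tip label {label!r}")
                seen.add(label)
            else:
                k = len(node.child_nodes())
                if k != 2:
                    raise PhylogenyError(
                        f"internal node with {k} children; the tree must be "
                        "strictly binary — resolve polytomies before use"
                    )
            if node.parent_node is not None:
                bl = node.edge.length
                if bl is None:
                    raise PhylogenyError("missing branch length")
                if not bl > 0:
                    raise PhylogenyError(f"non-positive branch length {bl}")
        if n_tips < 2:
            raise PhylogenyError("tree must have at least 2 tips")

    # ------------------------------------------------------------- properties
    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in sorted (canonical) order."""
        return sorted(self._min_tip[n] for n in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self._tree.preorder_internal_node_iter())

    @property
    def n_edges(self) -> int:
        """Edges with branch lengths (root edge excluded)."""
        return sum(1 for n in self._tree.preorder_node_iter() if n.parent_node is not None)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths, keyed by tip label."""
        acc: dict[int, float] = {id(self._tree.seed_node): 0.0}
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                acc[id(node)] = acc[id(node.parent_node)] + node.edge.length
            if node.is_leaf():
                out[node.taxon.label] = acc[id(node)]
        return out

    def _ordered_children(self, node):
        return sorted(node.child_nodes(), key=lambda c: self._min_tip[c])

    def walk_preorder(self):
        """Yield ``(node_key, parent_key, branch_length, tip_label)`` tuples.

        Root first (parent_key ``None``, branch length 0); children are
        visited in canonical (smallest-descendant) order; ``tip_label`` is
        ``None`` for internal nodes.  Node keys are opaque ints, stable for
        the lifetime of this object.
        """
        stack = [(self._tree.seed_node, None)]
        while stack:
            node, parent_key = stack.pop()
            key = id(node)
            bl = node.edge.length if node.parent_node is not None else 0.0
            label = node.taxon.label if node.is_leaf() else None
            yield key, parent_key, bl, label
            for child in reversed(self._ordered_children(node)):
                stack.append((child, key))

    # ------------------------------------------------------------- contrasts
    def contrast_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Linear map from tip values to standardized independent contrasts.

        Felsenstein's pruning algorithm is linear in the tip values, so the
        J−1 standardized contrasts can be written as ``C @ v`` where ``v``
        holds tip values in :attr:`tip_labels` (sorted) order.  Returns
        ``(C, node_ids)`` with ``C`` of shape (J−1, J); rows follow a
        canonical post-order (children visited in smallest-descendant order)
        and each node id is ``"<min tip of first child>|<min tip of second
        child>"``, which is unique on a binary tree.

        The sign convention — first child minus second child, children
        ordered by their lexicographically smallest descendant tip — is fixed
        and applied identically to every variable contrasted on the tree, so
        rank correlations between contrast sets are well defined.
        """
        if self._contrast_cache is not None:
            return self._contrast_cache
        labels = self.tip_labels
        col = {lab: i for i, lab in enumerate(labels)}
        J = len(labels)
        rows: list[np.ndarray] = []
        node_ids: list[str] = []

        def prune(node) -> tuple[np.ndarray, float]:
            """Return (weight vector of the node's implied value, adjusted branch length)."""
            edge = node.edge.length if node.parent_node is not None else 0.0
            if node.is_leaf():
                w = np.zeros(J)
                w[col[node.taxon.label]] = 1.0
                return w, edge
            c1, c2 = self._ordered_children(node)
            w1, b1 = prune(c1)
            w2, b2 = prune(c2)
            rows.append((w1 - w2) / np.sqrt(b1 + b2))
            node_ids.append(f"{self._min_tip[c1]}|{self._min_tip[c2]}")
            w = (w1 / b1 + w2 / b2) / (1.0 / b1 + 1.0 / b2)
            return w, edge + b1 * b2 / (b1 + b2)

        prune(self._tree.seed_node)
        C = np.vstack(rows)
        self._contrast_cache = (C, node_ids)
        return self._contrast_cache

    def bm_covariance(self) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths.

        Entry (i, j) is the depth of the most recent common ancestor of tips
        i and j (tips in :attr:`tip_labels` order); diagonal entries are tip
        depths.  Useful for cross-checking contrasts against their
        generalized-least-squares formulation.
        """
        labels = self.tip_labels
        col = {lab: i for i, lab in enumerate(labels)}
        J = len(labels)
        V = np.zeros((J, J))
        acc: dict[int, float] = {id(self._tree.seed_node): 0.0}
        below: dict[int, list[int]] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                acc[id(node)] = acc[id(node.parent_node)] + node.edge.length
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = col[node.taxon.label]
                below[id(node)] = [i]
                V[i, i] = acc[id(node)]
            else:
                c1, c2 = node.child_nodes()
                for i in below[id(c1)]:
                    for j in below[id(c2)]:
                        V[i, j] = V[j, i] = acc[id(node)]
                below[id(node)] = below[id(c1)] + below[id(c2)]
        return V

    def align(self, values: Mapping[str, float]) -> np.ndarray:
        """Vector of per-tip values in canonical (sorted tip label) order."""
        labels = self.tip_labels
        missing = [l for l in labels if l not in values]
        extra = [k for k in values if k not in set(labels)]
        if missing or extra:
            raise PhylogenyError(
                f"tip/value mismatch: missing {missing!r}, extraneous {extra!r}"
            )
        return np.array([float(values[l]) for l in labels])

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"
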