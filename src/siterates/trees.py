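"""Phylogenetic tree handling for likelihood computation.

Trees arrive as Newick strings (with branch lengths in expected substitutions
per site) and are flattened to an indexed, postorder-sorted representation so
that pruning can run as vectorized array operations. Parsing and rerooting are
delegated to :mod:`dendropy`; neighbor joining to :mod:`skbio`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np


@dataclass
class IndexedTree:
    """Rooted tree flattened for postorder traversal.

    Nodes are numbered 0..n_nodes-1 with leaves first (in ``leaf_labels``
    order). ``children[i]`` lists the child node ids of node i; leaves have
    empty child lists. ``branch_lengths[i]`` is the length of the edge above
    node i (0 for the root). ``postorder`` lists node ids children-first.
    Likelihood under a reversible model is invariant to the root placement,
    so any rooting of an unrooted input is acceptable.
    """

    leaf_labels: list[str]
    children: list[list[int]]
    branch_lengths: np.ndarray
    postorder: list[int]
    root: int
    newick: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def leaf_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.leaf_labels)}

    def root_to_tip_depths(self) -> np.ndarray:
        """Path length from root to each leaf, in branch-length units."""
        depth = np.zeros(self.n_nodes)
        for node in reversed(self.postorder):  # preorder
            for ch in self.children[node]:
                depth[ch] = depth[node] + self.branch_lengths[ch]
        return depth[: self.n_leaves]

    def scale(self, factor: float) -> "IndexedTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        t = dendropy.Tree.get(data=self.newick, schema="newick")
        for edge in t.edges():
            if edge.length is not None:
                edge.length *= factor
        return IndexedTree.from_dendropy(t)

    @classmethod
    def from_newick(cls, newick: str | Path) -> "IndexedTree":
        if isinstance(newick, Path):
            newick = newick.read_text()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "IndexedTree":
        # Suppress dendropy's unifurcation-at-root artifacts.
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        node_id: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            node_id[id(lf)] = i
        next_id = len(leaves)
        for nd in tree.postorder_node_iter():
            if id(nd) not in node_id:
                node_id[id(nd)] = next_id
                next_id += 1
        children: list[list[int]] = [[] for _ in range(next_id)]
        blen = np.zeros(next_id)
        postorder: list[int] = []
        for nd in tree.postorder_node_iter():
            i = node_id[id(nd)]
            postorder.append(i)
            children[i] = [node_id[id(c)] for c in nd.child_nodes()]
            if nd.edge.length is not None:
                blen[i] = float(nd.edge.length)
            if blen[i] < 0:
                raise ValueError("negative branch length")
        root = node_id[id(tree.seed_node)]
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
        return cls(labels, children, blen, postorder, root, newick)


def reroot_at_edge(newick: str, leaf_label: str) -> str:
    """Reroot the tree on the edge above ``leaf_label`` (midpoint of that edge).

    Used to exercise root invariance of reversible-model likelihoods.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaf = None
    for lf in tree.leaf_node_iter():
        if (lf.taxon.label if lf.taxon else lf.label) == leaf_label:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"leaf {leaf_label!r} not in tree")
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=length / 2, length2=length / 2)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
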