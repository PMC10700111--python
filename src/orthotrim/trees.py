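"""Array-backed rooted trees shared by the weighting and phylo-HMM layers.

Newick parsing is delegated to :mod:`dendropy`; the result is flattened
into index arrays (post-order, root last) so that per-column likelihood
recursions can be vectorized with numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["ArrayTree"]


@dataclass
class ArrayTree:
    """A rooted tree with branch lengths, flattened for numeric traversal.

    Nodes are indexed in post-order with the root last.  ``edge_length[i]``
    is the length of the branch above node ``i`` (0 for the root).  Tips
    are the nodes with no children; ``tip_labels[j]`` is the taxon label
    of the node at index ``tip_index[j]``.
    """

    n_nodes: int
    children: list[list[int]]
    edge_length: np.ndarray
    tip_index: np.ndarray
    tip_labels: list[str]
    postorder: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.postorder = np.arange(self.n_nodes)
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "ArrayTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(node): i for i, node in enumerate(nodes)}
        children: list[list[int]] = []
        edge_length = np.zeros(len(nodes))
        tip_index: list[int] = []
        tip_labels: list[str] = []
        for i, node in enumerate(nodes):
            kids = [index[id(c)] for c in node.child_nodes()]
            children.append(kids)
            if node.parent_node is not None:
                edge_length[i] = node.edge.length if node.edge.length is not None else 0.0
            if not kids:
                tip_index.append(i)
                label = node.taxon.label if node.taxon is not None else str(i)
                tip_labels.append(label)
        return cls(
            n_nodes=len(nodes),
            children=children,
            edge_length=edge_length,
            tip_index=np.asarray(tip_index),
            tip_labels=tip_labels,
        )

    @classmethod
    def from_newick(cls, newick: str) -> "ArrayTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        depth = np.zeros(self.n_nodes)
        # walk in reverse post-order so parents precede children
        parent = np.full(self.n_nodes, -1)
        for i, kids in enumerate(self.children):
            for c in kids:
                parent[c] = i
        for i in reversed(range(self.n_nodes)):
            if parent[i] >= 0:
                depth[i] = depth[parent[i]] + self.edge_length[i]
        return depth

    def tips_under(self, node: int) -> list[int]:
        """Tip *positions* (indices into ``tip_labels``) below ``node``."""
        pos = {int(t): j for j, t in enumerate(self.tip_index)}
        stack, out = [node], []
        while stack:
            i = stack.pop()
            kids = self.children[i]
            if not kids:
                out.append(pos[i])
            else:
                stack.extend(kids)
        return out

    def shared_path_covariance(self) -> np.ndarray:
        """Brownian-motion covariance: cov(i, j) = root-to-MRCA path length.

        Diagonal entries are root-to-tip distances.  Order follows
        ``tip_labels``.
        """
        depth = self.node_depths()
        n = self.n_tips
        cov = np.zeros((n, n))
        for j, t in enumerate(self.tip_index):
            cov[j, j] = depth[t]
        for i, kids in enumerate(self.children):
            if not kids:
                continue
            groups = [self.tips_under(c) for c in kids]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for x in groups[a]:
                        for y in groups[b]:
                            cov[x, y] = cov[y, x] = depth[i]
        return cov
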