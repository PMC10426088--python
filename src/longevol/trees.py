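"""Rooted phylogenies: Newick IO, a flat array view for the likelihood
engine, foreground marking, and Brownian-motion covariance structure.

dendropy owns parsing and tree manipulation; :class:`ArrayTree` is a frozen
postorder snapshot (children lists, branch lengths, tip labels) that the
pruning algorithm and the simulator traverse without touching dendropy
objects in inner loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_BRANCH_LENGTH = 0.1


class TreeError(ValueError):
    pass


def read_newick(source: str, *, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree; absent branch lengths initialise to 0.1."""
    if is_path:
        tree = dendropy.Tree.get(path=str(source), schema="newick",
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=source, schema="newick",
                                 preserve_underscores=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = DEFAULT_BRANCH_LENGTH
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


@dataclass
class ArrayTree:
    """Postorder array representation of a rooted tree.

    Node ``i``'s branch is the edge above it; the root (last postorder node)
    has no branch and its entry in ``branch_lengths`` is ignored.
    """

    children: list[list[int]]          # per node, postorder indices
    branch_lengths: np.ndarray         # per node, length of edge above
    labels: list[str | None]           # tip labels; None for internals
    foreground: np.ndarray = field(default=None)  # bool per node (branch marks)

    def __post_init__(self):
        if self.foreground is None:
            self.foreground = np.zeros(self.n_nodes, dtype=bool)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "ArrayTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children = [[index[id(ch)] for ch in nd.child_nodes()] for nd in nodes]
        lengths = np.array(
            [nd.edge.length if nd.edge.length is not None else 0.0 for nd in nodes],
            dtype=float,
        )
        lengths[-1] = 0.0  # root edge
        if np.any(lengths < 0):
            raise TreeError("negative branch length in input tree")
        labels = [nd.taxon.label if nd.taxon is not None else None for nd in nodes]
        return cls(children=children, branch_lengths=lengths, labels=labels)

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = True) -> "ArrayTree":
        return cls.from_dendropy(read_newick(source, is_path=is_path))

    # -- basic structure --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_indices(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    def tip_index(self, label: str) -> int:
        for i in self.tip_indices:
            if self.labels[i] == label:
                return i
        raise TreeError(f"tip {label!r} not in tree")

    def parents(self) -> np.ndarray:
        par = np.full(self.n_nodes, -1, dtype=int)
        for i, ch in enumerate(self.children):
            for c in ch:
                par[c] = i
        return par

    def path_to_root(self, node: int) -> list[int]:
        """Nodes (= branches above them) on the path node -> root, root excluded."""
        par = self.parents()
        path = []
        while par[node] != -1:
            path.append(node)
            node = par[node]
        return path

    # -- foreground marking -----------------------------------------------
    def with_foreground(self, tip_labels) -> "ArrayTree":
        """New tree with the terminal branches of ``tip_labels`` marked foreground."""
        fg = np.zeros(self.n_nodes, dtype=bool)
        for lab in tip_labels:
            fg[self.tip_index(lab)] = True
        return ArrayTree(children=self.children, branch_lengths=self.branch_lengths,
                         labels=self.labels, foreground=fg)

    def with_branch_lengths(self, lengths: np.ndarray) -> "ArrayTree":
        lengths = np.asarray(lengths, dtype=float).copy()
        lengths[self.root] = 0.0
        if np.any(lengths < 0):
            raise TreeError("negative branch length")
        return ArrayTree(children=self.children, branch_lengths=lengths,
                         labels=self.labels, foreground=self.foreground)

    # -- metrics ----------------------------------------------------------
    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depths = np.zeros(self.n_nodes)
        par = self.parents()
        for i in reversed(range(self.n_nodes - 1)):  # preorder, root excluded
            depths[i] = depths[par[i]] + self.branch_lengths[i]
        return depths

    def total_length(self) -> float:
        return float(self.branch_lengths[: self.root].sum())

    def mrca_depth_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Shared root-to-MRCA path length for every tip pair.

        Diagonal holds the full root-to-tip depth.  Returns the matrix and
        the tip-label order it is indexed by.
        """
        depths = self.node_depths()
        tips = self.tip_indices
        tip_pos = {t: k for k, t in enumerate(tips)}
        n = len(tips)
        V = np.zeros((n, n))
        desc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if not self.children[i]:
                desc[i] = [i]
                V[tip_pos[i], tip_pos[i]] = depths[i]
            else:
                groups = [desc[c] for c in self.children[i]]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        for ta in groups[a]:
                            for tb in groups[b]:
                                ka, kb = tip_pos[ta], tip_pos[tb]
                                V[ka, kb] = V[kb, ka] = depths[i]
                desc[i] = [t for g in groups for t in g]
        return V, [self.labels[t] for t in tips]

    # -- export -----------------------------------------------------------
    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                return f"{self.labels[i]}:{self.branch_lengths[i]:.10g}"
            inner = ",".join(render(c) for c in self.children[i])
            if i == self.root:
                return f"({inner});"
            return f"({inner}):{self.branch_lengths[i]:.10g}"

        return render(self.root)
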