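"""Rooted phylogenetic trees with named branches.

A light container shared by the simulator, the neighbor-joining builder,
Dollo loss mapping and per-branch dS: every non-root node defines the
branch leading into it, so ``branch id == child node id``. Branch lengths
are in whatever units the producer used (AND percentage points for
inferred trees, simulator units for true trees).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


@dataclass
class Node:
    id: str
    length: float = 0.0  # length of the branch leading into this node
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # keep dataclass repr from recursing
        return f"Node({self.id!r}, length={self.length:g})"


class Tree:
    """Rooted tree; binary except possibly at the root."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        for node in self.preorder():
            if node.id in self._index:
                raise ValueError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node

    # -- traversal ---------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All non-root nodes (each identifies the branch above it)."""
        return [n for n in self.preorder() if n.parent is not None]

    def node(self, node_id: str) -> Node:
        return self._index[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    # -- queries -----------------------------------------------------------
    def leafset_below(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.id)
            stack.extend(n.children)
        return frozenset(out)

    def depths(self) -> dict[str, float]:
        """Root-to-node path length for every node."""
        out = {self.root.id: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node.id] = out[node.parent.id] + node.length
        return out

    def leaf_distance_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """Pairwise leaf path lengths (via LCA depths)."""
        leaves = self.leaf_names()
        depth = self.depths()
        # ancestor sets for LCA; trees here are small
        anc: dict[str, list[str]] = {}
        for leaf in leaves:
            chain = []
            node = self.node(leaf)
            while node is not None:
                chain.append(node.id)
                node = node.parent
            anc[leaf] = chain
        mat = [[0.0] * len(leaves) for _ in leaves]
        for (i, a), (j, b) in itertools.combinations(enumerate(leaves), 2):
            seen = set(anc[a])
            lca = next(x for x in anc[b] if x in seen)
            d = depth[a] + depth[b] - 2.0 * depth[lca]
            mat[i][j] = mat[j][i] = d
        return leaves, mat

    # -- editing -----------------------------------------------------------
    def prune_leaf(self, leaf_id: str) -> "Tree":
        """Return a copy with one leaf removed; degree-2 nodes are spliced."""
        tree = self.copy()
        leaf = tree.node(leaf_id)
        if not leaf.is_leaf:
            raise ValueError(f"{leaf_id!r} is not a leaf")
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(leaf)
        node = parent
        # splice out nodes left with a single child
        while node is not None and len(node.children) == 1:
            child = node.children[0]
            if node.parent is None:  # root with one child -> child becomes root
                child.parent = None
                child.length = 0.0
                return Tree(child)
            child.length += node.length
            child.parent = node.parent
            node.parent.children[node.parent.children.index(node)] = child
            node = node.parent
        return Tree(tree.root)

    def copy(self) -> "Tree":
        def clone(node: Node, parent: Node | None) -> Node:
            new = Node(node.id, node.length, parent)
            new.children = [clone(c, new) for c in node.children]
            return new

        return Tree(clone(self.root, None))

    # -- serialization -----------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            label = node.id
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner}){node.id}"
            if lengths and node.parent is not None:
                return f"{label}:{node.length:.10g}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (dendropy backend) into a Tree."""
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")
        counter = itertools.count(1)

        def convert(dnode, parent: Node | None) -> Node:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            else:
                name = f"N{next(counter)}"
            node = Node(name, dnode.edge.length or 0.0, parent)
            node.children = [convert(c, node) for c in dnode.child_nodes()]
            return node

        return cls(convert(dt.seed_node, None))

    def __repr__(self) -> str:
        return f"Tree(n_leaves={len(self.leaves())})"
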