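"""Rooted sample tree with branch lengths.

A lightweight node/parent structure backing the tree-derived sample
weighting.  Newick parsing is delegated to dendropy; serialization is a
direct recursive writer.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = ["TreeNode", "SampleTree"]


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)  # branch length to parent; 0 at root
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def n_leaves(self) -> int:
        """Number of descendant leaves (1 for a leaf)."""
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children)


class SampleTree:
    """Rooted tree over samples; leaves carry sample ids."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise ValueError("every leaf must be labeled with a sample id")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels in sample tree")

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.iter_nodes() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    @property
    def n_samples(self) -> int:
        return len(self.leaves())

    # -- construction -------------------------------------------------

    @classmethod
    def from_linkage(cls, Z, labels: list[str]) -> "SampleTree":
        """Build from a scipy linkage matrix.

        Branch lengths are merge-height differences, clipped at zero
        (average linkage can produce slight inversions).
        """
        from scipy.cluster.hierarchy import to_tree

        cl_root = to_tree(Z)

        def build(cl_node, parent_height: float) -> TreeNode:
            if cl_node.is_leaf():
                node = TreeNode(name=labels[cl_node.id], length=max(0.0, parent_height))
                return node
            node = TreeNode(length=max(0.0, parent_height - cl_node.dist))
            for child in (cl_node.left, cl_node.right):
                node.add_child(build(child, cl_node.dist))
            return node

        root = build(cl_root, cl_root.dist)
        root.length = 0.0
        return cls(root)

    @classmethod
    def from_newick(cls, newick: str) -> "SampleTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = TreeNode(name=name, length=length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        root.length = 0.0
        return cls(root)

    def to_newick(self) -> str:
        def write(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:g}"
            inner = ",".join(write(c) for c in node.children)
            return f"({inner}):{node.length:g}"

        if self.root.is_leaf:
            return f"{self.root.name}:0;"
        inner = ",".join(write(c) for c in self.root.children)
        return f"({inner});"

    # -- comparison ---------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as frozensets of leaf names),
        for topology comparison (Robinson-Foulds style)."""
        all_leaves = frozenset(self.leaf_names())
        splits = set()
        for node in self.root.iter_nodes():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(l.name for l in node.iter_nodes() if l.is_leaf)
            if 1 < len(side) < len(all_leaves):
                splits.add(min(side, all_leaves - side, key=sorted))
        return splits

    def rf_distance(self, other: "SampleTree") -> int:
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("trees must share the same leaf set")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)
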