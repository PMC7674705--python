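"""Rooted species trees.

A minimal rooted-tree structure used throughout the package: leaves carry
species names, internal nodes optional labels, edges optional non-negative
lengths.  Newick parsing/serialisation is delegated to dendropy at the I/O
boundary (see :mod:`dolloscan.formats`); this class exists so that tree
algorithms (Dollo reconstruction, neighbourhood queries, simulation) can run
on plain Python objects.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: Optional[float] = None  # length of the edge above this node
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class SpeciesTree:
    """Rooted tree with uniquely named leaves.

    Invariants checked on construction: exactly one root, unique leaf
    labels, every internal node has >= 2 children (polytomies allowed),
    branch lengths non-negative where present.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nested(cls, nested) -> "SpeciesTree":
        """Build from nested tuples/strings, e.g. ``(("a", "b"), "c")``."""

        def build(obj) -> TreeNode:
            if isinstance(obj, str):
                return TreeNode(label=obj)
            node = TreeNode()
            for sub in obj:
                node.add_child(build(sub))
            return node

        return cls(build(nested))

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise ValueError("leaf without a label")
                if node.label in seen:
                    raise ValueError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
            elif len(node.children) < 2 and node is not self.root:
                raise ValueError("internal node with a single child")
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")
        if self.root.parent is not None:
            raise ValueError("root must have no parent")
        if len(self.root.children) == 1:
            raise ValueError("root with a single child")

    # -- traversal ------------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> TreeNode:
        for node in self.leaves():
            if node.label == label:
                return node
        raise KeyError(f"leaf {label!r} not in tree")

    def find_node(self, label: str) -> TreeNode:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"node {label!r} not in tree")

    @staticmethod
    def subtree_leaves(node: TreeNode) -> list[TreeNode]:
        out = []
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            if cur.is_leaf:
                out.append(cur)
            else:
                queue.extend(cur.children)
        return out

    # -- metrics --------------------------------------------------------------

    def depths(self, topological: bool = False) -> dict[int, float]:
        """Map ``id(node)`` -> distance from root (branch-length sum, or edge
        count when ``topological`` or any length is missing)."""
        if not topological:
            topological = any(
                n.length is None for n in self.postorder() if n is not self.root
            )
        out: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            step = 1.0 if topological else float(node.length)
            out[id(node)] = out[id(node.parent)] + step
        return out

    def patristic_distance(self, a: str, b: str) -> float:
        """Leaf-to-leaf path length; topological (edge count) when any branch
        length is missing."""
        na, nb = self.find_leaf(a), self.find_leaf(b)
        depths = self.depths()
        ancestors_a = {}
        node = na
        while node is not None:
            ancestors_a[id(node)] = node
            node = node.parent
        node = nb
        while id(node) not in ancestors_a:
            node = node.parent
        lca = node
        return depths[id(na)] + depths[id(nb)] - 2 * depths[id(lca)]

    # -- editing --------------------------------------------------------------

    def pruned(self, drop: set[str]) -> "SpeciesTree":
        """Return a copy with the named leaves removed; unary internal nodes
        created by pruning are collapsed (edge lengths summed)."""

        def copy(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.label in drop:
                    return None
                return TreeNode(label=node.label, length=node.length)
            kept = [c for c in (copy(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None and node.length is not None:
                    child.length += node.length
                elif node is not None:
                    child.length = child.length if child.length is not None else node.length
                return child
            new = TreeNode(label=node.label, length=node.length)
            for c in kept:
                new.add_child(c)
            return new

        new_root = copy(self.root)
        if new_root is None or new_root.is_leaf:
            raise ValueError("pruning removed too many leaves")
        new_root.length = None
        new_root.parent = None
        return SpeciesTree(new_root)

    # -- serialisation --------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.label:
                    body += node.label
            if node.length is not None:
                body += f":{node.length:g}"
            return body

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({self.to_newick()})"
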