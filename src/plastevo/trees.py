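"""Rooted phylogenetic trees: a light array-friendly structure.

Newick parsing/serialization is delegated to dendropy; internally the tree
is a plain node graph ordered for postorder traversal, which is what the
pruning likelihood and the branch-length optimizer need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["Node", "PhyloTree"]


@dataclass(eq=False)  # identity semantics: nodes are unique graph vertices
class Node:
    name: str | None = None
    length: float = 0.0  # branch above this node, substitutions/site
    children: list = field(default_factory=list)
    parent: "Node | None" = None
    index: int = -1  # postorder index, assigned by PhyloTree

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with named leaves and branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        dt = dendropy.Tree.get(path=str(path), schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def build(dnode) -> Node:
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label.replace(" ", "_")
            elif dnode.label:
                name = dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                cn = build(child)
                cn.parent = node
                node.children.append(cn)
            return node

        return cls(build(dt.seed_node))

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(name=node.name, length=node.length)
            for child in node.children:
                cc = clone(child)
                cc.parent = c
                c.children.append(cc)
            return c

        return PhyloTree(clone(self.root))

    # -- bookkeeping ---------------------------------------------------------

    def _reindex(self) -> None:
        self.postorder: list[Node] = []

        def walk(node: Node) -> None:
            for child in node.children:
                walk(child)
            node.index = len(self.postorder)
            self.postorder.append(node)

        walk(self.root)
        self.leaves = [n for n in self.postorder if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_branches(self) -> int:
        return len(self.postorder) - 1  # every node but the root has an edge

    def branch_nodes(self) -> list[Node]:
        return [n for n in self.postorder if n.parent is not None]

    def total_length(self) -> float:
        return sum(n.length for n in self.branch_nodes())

    # -- queries -------------------------------------------------------------

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves:
            if n.name == name:
                return n
        raise KeyError(f"no leaf named {name!r}")

    def mrca(self, taxa: list[str]) -> Node:
        """Most recent common ancestor of a set of leaf names."""
        target = set(taxa)
        missing = target - set(self.taxa)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        cover: dict[int, set] = {}
        for node in self.postorder:
            if node.is_leaf:
                cover[node.index] = {node.name} if node.name in target else set()
            else:
                cover[node.index] = set().union(*(cover[c.index] for c in node.children))
            if cover[node.index] == target:
                return node
        return self.root  # pragma: no cover

    def leaf_names_under(self, node: Node) -> list[str]:
        out = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c in n.children:
                walk(c)

        walk(node)
        return out

    def path_length(self, ancestor: Node, leaf: Node) -> float:
        total = 0.0
        node = leaf
        while node is not ancestor:
            if node.parent is None:
                raise ValueError("leaf is not a descendant of ancestor")
            total += node.length
            node = node.parent
        return total

    # -- output ---------------------------------------------------------------

    def to_newick(self, lengths: bool = True, fmt: str = "%.10g") -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")" + (node.name or "")
            if lengths and node.parent is not None:
                body += ":" + (fmt % node.length)
            return body

        return render(self.root) + ";"

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")
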