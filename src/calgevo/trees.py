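"""Rooted binary trees for ancestral reconstruction and trait mapping.

Newick parsing and serialization are delegated to :mod:`dendropy`; this module
adds the validation and traversal conveniences the reconstruction code needs
(strictly bifurcating rooted topology, unique leaf names, nonnegative branch
lengths in expected substitutions per site, auto-named internal nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["TreeError", "Node", "PhyloTree"]


class TreeError(ValueError):
    """Raised when a tree violates the rooted-binary contract."""


@dataclass
class Node:
    """One node of a rooted tree.

    ``length`` is the branch length of the edge above this node (expected
    substitutions/site); the root's length is 0 by convention.
    """

    name: str
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted, strictly bifurcating tree with uniquely named leaves.

    Internal nodes without labels are assigned stable names ``anc0, anc1, ...``
    in postorder so that reconstructions can always be addressed by name.
    Single-leaf trees are permitted as a degenerate case (used by parsimony).
    """

    def __init__(self, root: Node):
        self.root = root
        self._autoname()
        self.validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, include_lengths: bool = True) -> str:
        return _to_newick(self.root, include_lengths) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- traversal

    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def rec(node: Node) -> None:
            for child in node.children:
                rec(child)
            out.append(node)

        rec(self.root)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def node(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    # ---------------------------------------------------------- validation

    def validate(self) -> None:
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise TreeError("leaf names are not unique")
        for n in self.postorder():
            if n.children and len(n.children) != 2:
                raise TreeError(
                    f"internal node {n.name!r} has {len(n.children)} children; "
                    "tree must be strictly bifurcating"
                )
            if n.length is None or n.length < 0 or n.length != n.length:
                raise TreeError(f"node {n.name!r} has invalid branch length {n.length}")

    def _autoname(self) -> None:
        taken = {n.name for n in self.postorder() if n.name}
        counter = 0
        for n in self.postorder():
            if not n.name:
                while f"anc{counter}" in taken:
                    counter += 1
                n.name = f"anc{counter}"
                taken.add(n.name)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.to_newick()!r})"


def _from_dendropy(dnode) -> Node:
    name = None
    if dnode.taxon is not None:
        name = dnode.taxon.label
    elif dnode.label:
        name = dnode.label
    length = dnode.edge.length if dnode.edge.length is not None else 0.0
    return Node(
        name=name or "",
        length=float(length),
        children=[_from_dendropy(c) for c in dnode.child_nodes()],
    )


def _to_newick(node: Node, include_lengths: bool) -> str:
    label = node.name or ""
    if " " in label:
        label = label.replace(" ", "_")
    if node.is_leaf:
        body = label
    else:
        inner = ",".join(_to_newick(c, include_lengths) for c in node.children)
        body = f"({inner}){label}"
    if include_lengths:
        body += f":{node.length:g}"
    return body
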