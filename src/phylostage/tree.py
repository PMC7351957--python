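"""Rooted binary species trees.

The conservation statistic walks a rooted binary tree whose leaves are the
analyzed species.  Newick parsing is delegated to dendropy; internally the
tree is held as a minimal nested node structure that supports post-order
traversal, pruning to a taxon subset, and per-branch lengths (default 1.0
when the Newick string carries none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

from .errors import ConfigurationError

__all__ = ["TreeNode", "SpeciesTree"]


@dataclass
class TreeNode:
    """One node of a rooted binary tree; leaves carry species names."""

    name: str | None
    length: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


class SpeciesTree:
    """Rooted binary tree over species labels.

    Parameters
    ----------
    root:
        Root node of a fully bifurcating tree.  Every internal node must
        have exactly two children and every leaf a unique species label.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        """Parse a Newick string (dendropy) into a :class:`SpeciesTree`."""
        tree = dendropy.Tree.get(data=text, schema="newick")

        def convert(node: dendropy.Node) -> TreeNode:
            kids = node.child_nodes()
            length = node.edge.length if node.edge.length is not None else 1.0
            if not kids:
                label = node.taxon.label if node.taxon is not None else node.label
                if label is None:
                    raise ConfigurationError("unlabeled leaf in Newick tree")
                return TreeNode(name=str(label).replace(" ", "_"), length=float(length))
            return TreeNode(
                name=None,
                length=float(length),
                children=[convert(k) for k in kids],
            )

        return cls(convert(tree.seed_node))

    # -- properties ------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        """Species labels in left-to-right (Newick) order."""
        return self.root.leaves()

    @property
    def n_internal(self) -> int:
        return sum(1 for _ in self.internal_nodes())

    def internal_nodes(self) -> Iterator[TreeNode]:
        """Post-order iterator over internal nodes."""

        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            if not node.is_leaf:
                yield node

        return walk(self.root)

    # -- operations ------------------------------------------------------

    def restrict(self, species: Iterable[str]) -> "SpeciesTree":
        """Prune the tree to ``species``, collapsing single-child nodes.

        Branch lengths of collapsed chains are summed.  At least two of the
        requested species must be present.
        """
        keep = set(species)
        missing = keep - set(self.leaves)
        if missing:
            raise ConfigurationError(f"species not in tree: {sorted(missing)}")

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.name in keep:
                    return TreeNode(node.name, node.length)
                return None
            kids = [p for p in (prune(c) for c in node.children) if p is not None]
            if not kids:
                return None
            if len(kids) == 1:
                only = kids[0]
                return TreeNode(only.name, only.length + node.length, only.children)
            return TreeNode(None, node.length, kids)

        root = prune(self.root)
        if root is None or root.is_leaf:
            raise ConfigurationError("restriction must retain at least two species")
        return SpeciesTree(root)

    # -- internal --------------------------------------------------------

    def _validate(self) -> None:
        names = self.leaves
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate leaf labels in species tree")
        if len(names) < 2:
            raise ConfigurationError("species tree needs at least two leaves")

        def check(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if len(node.children) != 2:
                raise ConfigurationError(
                    "species tree must be fully bifurcating "
                    f"(found a node with {len(node.children)} children)"
                )
            for child in node.children:
                check(child)

        check(self.root)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpeciesTree(leaves={self.leaves})"
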