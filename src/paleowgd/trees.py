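"""Species-tree wrapper with stable branch identifiers.

Every branch of the rooted species tree is identified by the clade below it:
the ``'+'``-joined, lexicographically sorted leaf labels of the branch's
child node.  The identifier is therefore invariant to node rotation and to
the order in which a newick file lists children.  The root node carries the
identifier of the full leaf set, which doubles as the "root branch" for
duplication events whose descendant species span the whole tree.
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import pandas as pd


class SpeciesTree:
    """Rooted species tree with clade-based branch identifiers.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.  Edge lengths are optional; when
        present, node ages (distance from the root) are computed so the
        simulator can place events in time.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        tree.is_rooted = True
        self._tree = tree
        self._clades: dict[dendropy.Node, frozenset[str]] = {}
        self._leaf_node: dict[str, dendropy.Node] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                name = node.taxon.label if node.taxon else node.label
                self._clades[node] = frozenset([name])
                self._leaf_node[name] = node
            else:
                clade: set[str] = set()
                for child in node.child_nodes():
                    clade |= self._clades[child]
                self._clades[node] = frozenset(clade)
        self._branch_to_node = {
            self.branch_id(node): node for node in tree.preorder_node_iter()
        }
        self._ages: dict[dendropy.Node, float] = {}
        root = tree.seed_node
        self._ages[root] = 0.0
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length if node.edge.length is not None else 0.0
            self._ages[node] = self._ages[node.parent_node] + length

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic accessors ----------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(self._leaf_node))

    def clade(self, node_or_branch) -> frozenset[str]:
        if isinstance(node_or_branch, str):
            node_or_branch = self._branch_to_node[node_or_branch]
        return self._clades[node_or_branch]

    def branch_id(self, node: dendropy.Node) -> str:
        return "+".join(sorted(self._clades[node]))

    def branches(self) -> list[str]:
        """All branch identifiers, root included, in preorder."""
        return [self.branch_id(n) for n in self._tree.preorder_node_iter()]

    def node(self, branch_id: str) -> dendropy.Node:
        return self._branch_to_node[branch_id]

    def has_branch(self, branch_id: str) -> bool:
        return branch_id in self._branch_to_node

    def node_age(self, node_or_branch) -> float:
        if isinstance(node_or_branch, str):
            node_or_branch = self._branch_to_node[node_or_branch]
        return self._ages[node_or_branch]

    @property
    def tip_age(self) -> float:
        return max(self._ages[self._leaf_node[l]] for l in self._leaf_node)

    # -- queries -------------------------------------------------------

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        target = set(species)
        unknown = target - set(self._leaf_node)
        if unknown:
            raise KeyError(
                f"species not in species tree: {', '.join(sorted(unknown))}"
            )
        node = self._leaf_node[next(iter(sorted(target)))]
        while not target <= self._clades[node]:
            node = node.parent_node
        return node

    def mrca_branch(self, species: Iterable[str]) -> str:
        """Identifier of the branch subtending the MRCA of *species*."""
        return self.branch_id(self.mrca(species))

    def branch_table(self) -> pd.DataFrame:
        """One row per non-root branch: identity, time span, size."""
        rows = []
        for node in self._tree.preorder_node_iter():
            if node is self.root:
                continue
            rows.append(
                {
                    "branch": self.branch_id(node),
                    "parent_branch": self.branch_id(node.parent_node),
                    "start_age": self._ages[node.parent_node],
                    "end_age": self._ages[node],
                    "length": self._ages[node] - self._ages[node.parent_node],
                    "n_species": len(self._clades[node]),
                    "is_terminal": node.is_leaf(),
                }
            )
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()
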