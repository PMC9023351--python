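"""Gene-tree duplication scoring and mapping onto species-tree branches.

A gene-tree internal node is scored as a duplication when its two child
subtrees contain genes from at least one shared species (species-overlap
reconciliation).  A duplication is *reliable* when two bootstrap criteria
hold: the node's own support and the support of at least one of its
children are both >= ``min_support`` (50 by default).  Reliable
duplications are mapped to the species-tree branch subtending the MRCA of
the union of the two child species sets; per-branch tallies of events and
of distinct contributing gene families reveal branches with concentrated
duplications -- the phylogenomic signature of a whole-genome duplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import dendropy
import pandas as pd

from paleowgd.trees import SpeciesTree


def default_species_of(gene_id: str) -> str:
    """Species label = gene id up to the first underscore."""
    return gene_id.split("_")[0]


def _parse_support(label) -> float | None:
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


@dataclass
class DuplicationEvent:
    """One species-overlap duplication node in a gene tree."""

    family: str
    node_id: str
    species_set1: frozenset[str]
    species_set2: frozenset[str]
    support: float | None
    max_child_support: float | None
    reliable: bool
    branch: str | None = None  # filled by map_to_species_branch

    @property
    def species_union(self) -> frozenset[str]:
        return self.species_set1 | self.species_set2

    @property
    def leaf_sets(self) -> tuple[frozenset[str], frozenset[str]] | None:
        return getattr(self, "_leaf_sets", None)


# ---------------------------------------------------------------------------
# reading and rooting
# ---------------------------------------------------------------------------


def read_gene_trees(path) -> list[dendropy.Tree]:
    """Read one or more newick gene trees (supports as internal node labels)."""
    trees = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return list(trees)


def root_gene_tree(
    tree: dendropy.Tree,
    outgroup_species: Iterable[str],
    species_of: Callable[[str], str] = default_species_of,
) -> dendropy.Tree:
    """Root a gene tree on its outgroup genes, falling back to midpoint.

    If the genes belonging to ``outgroup_species`` form one side of a
    bipartition of the unrooted tree, the root is placed on that edge
    (at its midpoint); otherwise the tree is midpoint-rooted.  Support
    values travel with their bipartitions: they are held on edges during
    rerooting and written back to node labels afterwards.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("gene tree must have at least 3 leaves to be rooted")
    outgroup = set(outgroup_species)

    # park supports on edge objects: edges persist through rerooting
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.edge.support_value = _parse_support(node.label)

    gene_names = {
        lf: (lf.taxon.label if lf.taxon else lf.label) for lf in leaves
    }
    og_leaves = {lf for lf in leaves if species_of(gene_names[lf]) in outgroup}

    target_edge = None
    if og_leaves and len(og_leaves) < len(leaves):
        all_leaves = set(leaves)
        for edge in tree.preorder_edge_iter():
            head = edge.head_node
            if head is tree.seed_node:
                continue
            below = {lf for lf in head.leaf_iter()}
            if below == og_leaves or (all_leaves - below) == og_leaves:
                target_edge = edge
                break

    if target_edge is not None:
        length = target_edge.length or 0.0
        support = getattr(target_edge, "support_value", None)
        tree.reroot_at_edge(
            target_edge, length1=length / 2.0, length2=length / 2.0,
            suppress_unifurcations=True,
        )
        for child in tree.seed_node.child_edges():
            child.support_value = support
    else:
        tree.reroot_at_midpoint(suppress_unifurcations=True)

    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        sv = getattr(node.edge, "support_value", None)
        node.label = None if sv is None else format(sv, "g")
    tree.seed_node.label = None
    return tree


def resolve_multifurcations(tree: dendropy.Tree) -> dendropy.Tree:
    """Arbitrarily resolve polytomies into zero-length, support-0 branches.

    Support 0 guarantees a resolved node can never satisfy the bootstrap
    reliability criteria.
    """
    polytomies = [
        nd for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2
    ]
    if not polytomies:
        return tree
    for node in polytomies:
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            new = dendropy.Node(label="0")
            new.edge.length = 0.0
            for child in children[:2]:
                node.remove_child(child)
                new.add_child(child)
            node.insert_child(0, new)
    return tree


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_duplications(
    tree: dendropy.Tree,
    family: str = "",
    min_support: float = 50.0,
    species_of: Callable[[str], str] = default_species_of,
    leaf_support: float = 100.0,
    missing_support: float = 0.0,
) -> list[DuplicationEvent]:
    """Score every species-overlap duplication node of a rooted gene tree.

    A node is a duplication when its two child clades share >= 1 species.
    Reliability needs the node's support and the larger of its children's
    supports to both reach ``min_support``; leaf children count as
    ``leaf_support`` (a leaf is not a bootstrap-estimated clade, treating
    it as certain is the permissive convention) and absent supports count
    as ``missing_support`` (conservative: they fail the filter).
    """
    resolve_multifurcations(tree)
    events: list[DuplicationEvent] = []
    species_sets: dict[dendropy.Node, frozenset[str]] = {}
    leaf_sets: dict[dendropy.Node, frozenset[str]] = {}
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            gene = node.taxon.label if node.taxon else node.label
            species_sets[node] = frozenset([species_of(gene)])
            leaf_sets[node] = frozenset([gene])
            continue
        children = node.child_nodes()
        species_sets[node] = frozenset().union(*(species_sets[c] for c in children))
        leaf_sets[node] = frozenset().union(*(leaf_sets[c] for c in children))
        if len(children) != 2:
            continue
        c1, c2 = children
        if not (species_sets[c1] & species_sets[c2]):
            continue
        supports = []
        for child in (c1, c2):
            if child.is_leaf():
                supports.append(leaf_support)
            else:
                sv = _parse_support(child.label)
                supports.append(missing_support if sv is None else sv)
        own = _parse_support(node.label)
        own_val = missing_support if own is None else own
        max_child = max(supports)
        reliable = own_val >= min_support and max_child >= min_support
        event = DuplicationEvent(
            family=family,
            node_id=f"{family}:d{counter}" if family else f"d{counter}",
            species_set1=species_sets[c1],
            species_set2=species_sets[c2],
            support=own,
            max_child_support=max_child,
            reliable=reliable,
        )
        event._leaf_sets = (leaf_sets[c1], leaf_sets[c2])
        events.append(event)
        counter += 1
    return events


def map_to_species_branch(
    event: DuplicationEvent, species_tree: SpeciesTree
) -> str:
    """Branch subtending the MRCA of the union of the event's species sets."""
    branch = species_tree.mrca_branch(event.species_union)
    event.branch = branch
    return branch


def score_and_map(
    trees: Mapping[str, dendropy.Tree],
    species_tree: SpeciesTree,
    min_support: float = 50.0,
    species_of: Callable[[str], str] = default_species_of,
    **kwargs,
) -> list[DuplicationEvent]:
    """Score duplications in many families and map each onto the species tree."""
    events: list[DuplicationEvent] = []
    for family, tree in trees.items():
        fam_events = score_duplications(
            tree, family=family, min_support=min_support,
            species_of=species_of, **kwargs,
        )
        for ev in fam_events:
            map_to_species_branch(ev, species_tree)
        events.extend(fam_events)
    return events


# ---------------------------------------------------------------------------
# branch summaries
# ---------------------------------------------------------------------------


def summarize_branches(
    events: Iterable[DuplicationEvent],
    species_tree: SpeciesTree,
    synteny_families: Mapping[str, bool] | None = None,
    reliable_only: bool = True,
) -> pd.DataFrame:
    """Per-branch tallies of reliable duplications.

    Returns one row per species-tree branch (root included) with the
    reliable event count, the count of distinct gene families contributing
    at least one reliable event, and -- when a ``family -> has synteny
    support`` mapping is supplied -- the count of contributing families
    whose duplicates are also anchors of a collinear block.
    """
    rows = {
        b: {"branch": b, "n_events": 0, "families": set(), "syntenic": set()}
        for b in species_tree.branches()
    }
    for ev in events:
        if reliable_only and not ev.reliable:
            continue
        if ev.branch is None:
            map_to_species_branch(ev, species_tree)
        row = rows[ev.branch]
        row["n_events"] += 1
        row["families"].add(ev.family)
        if synteny_families and synteny_families.get(ev.family, False):
            row["syntenic"].add(ev.family)
    out = pd.DataFrame(
        [
            {
                "branch": r["branch"],
                "n_events": r["n_events"],
                "n_families": len(r["families"]),
                "n_synteny_families": len(r["syntenic"]) if synteny_families else 0,
            }
            for r in rows.values()
        ]
    )
    return out.sort_values("branch", ignore_index=True)


def events_to_frame(events: Iterable[DuplicationEvent]) -> pd.DataFrame:
    rows = [
        {
            "family": ev.family,
            "node_id": ev.node_id,
            "species_set1": "+".join(sorted(ev.species_set1)),
            "species_set2": "+".join(sorted(ev.species_set2)),
            "support": math.nan if ev.support is None else ev.support,
            "max_child_support": (
                math.nan if ev.max_child_support is None else ev.max_child_support
            ),
            "reliable": ev.reliable,
            "branch": ev.branch or "",
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "family", "node_id", "species_set1", "species_set2",
            "support", "max_child_support", "reliable", "branch",
        ],
    )
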