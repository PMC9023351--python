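"""Ground-truth-annotated simulator of gene families under a planted WGD.

The generative model:

* A rooted, ultrametric species tree of ``n_species`` tips (root age 0,
  tips at ``species_tree_height``); topology by recursive random splits,
  internal node ages uniform within the span allowed by ultrametricity.
* Each gene family starts as one gene at the species root and evolves down
  the species tree under a birth--death process: background duplications
  at rate ``birth_rate`` and losses at rate ``loss_rate`` per gene lineage
  per time unit.  On the designated ``wgd_branch`` a single pulse at
  ``wgd_time`` duplicates every lineage then alive with probability
  ``retention``, independently per lineage.  Families extinct in all
  species are resimulated (conditioning on survival, as implicit in any
  observed gene-family set), up to a retry cap.
* Coding sequences evolve along the true gene tree only at third positions
  of fourfold-degenerate codons under Jukes-Cantor at ``syn_rate``
  substitutions per synonymous site per time unit, with the amino-acid
  sequence held fixed; two genes whose divergence time is t therefore have
  expected synonymous divergence 2 * t * syn_rate, which makes the Ks-peak
  location analytically predictable.
* Gene orders: a shuffled ancestral chromosome with one slot per family.
  Species below the WGD branch carry two chromosomes -- the ancestral copy
  and a duplicated copy in which every slot is deleted with probability
  ``fractionation`` (the deleted genes are pruned from the whole dataset,
  emulating post-WGD fractionation).  Extra background-duplicate copies
  are placed adjacent to a family member (tandem-like) or at a random
  position, with equal probability.
* LTR retroelements: pairs of initially identical repeats mutated under
  Jukes-Cantor according to an age drawn uniformly in
  [0, ltr_max_age_years] at ``ltr_rate`` substitutions per site per year.

Every stochastic choice flows from one seeded generator, so a fixed
(config, seed) reproduces byte-identical datasets.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
import yaml

from paleowgd.trees import SpeciesTree

BASES = "ACGT"
# amino acids whose codons are fourfold degenerate at the third position
# and have no synonymous changes at the first two positions
_SAFE_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")  # Ala Gly Pro Thr Val Ser


class ConfigError(ValueError):
    """A simulation parameter is outside its documented domain."""


class FamilyExtinctError(RuntimeError):
    """A family died in all species in every resimulation attempt."""


@dataclass
class SimulationConfig:
    """All generative parameters; see the module docstring for the model."""

    n_species: int = 8
    species_tree_height: float = 1.0
    birth_rate: float = 0.05
    loss_rate: float = 0.05
    wgd_branch: str | None = "auto"
    wgd_time: float | None = None
    retention: float = 0.3
    syn_rate: float = 0.5
    n_families: int = 200
    codons_per_gene: int = 300
    fractionation: float = 0.3
    support_noise: float = 0.0
    seed: int = 0
    min_family_size: int = 1
    max_family_size: int | None = None
    tandem_prob: float = 0.5
    n_ltr_elements: int = 50
    ltr_length: int = 500
    ltr_max_age_years: float = 5.0e6
    ltr_rate: float = 2.2e-9
    retry_cap: int = 100

    def validate(self) -> None:
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        for name in ("retention", "fractionation", "support_noise", "tandem_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("birth_rate", "loss_rate", "syn_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.species_tree_height <= 0:
            raise ConfigError("species_tree_height must be positive")
        if self.codons_per_gene < 30:
            raise ConfigError(
                "codons_per_gene must be >= 30 (shorter genes make the "
                "Ks estimator too noisy to be useful)"
            )
        if self.n_families < 0:
            raise ConfigError("n_families must be non-negative")
        if self.ltr_rate <= 0:
            raise ConfigError("ltr_rate must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def simulate_species_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SpeciesTree:
    """Random rooted ultrametric species tree with root-to-tip height H."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_species
    height = config.species_tree_height
    names = [f"sp{i + 1:02d}" for i in range(n)]
    labels = [names[i] for i in rng.permutation(n)]

    ns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(subset: list[str], node: dendropy.Node, age: float) -> None:
        k = int(rng.integers(1, len(subset)))
        for part in (subset[:k], subset[k:]):
            child = dendropy.Node()
            if len(part) == 1:
                child.taxon = ns.get_taxon(part[0])
                child.edge.length = height - age
                node.add_child(child)
            else:
                child_age = float(rng.uniform(age, height))
                child.edge.length = child_age - age
                node.add_child(child)
                build(part, child, child_age)

    build(labels, tree.seed_node, 0.0)
    tree.is_rooted = True
    return SpeciesTree(tree)


def resolve_wgd_branch(
    config: SimulationConfig, species_tree: SpeciesTree
) -> tuple[str | None, float | None]:
    """Concrete (wgd_branch, wgd_time) for this species tree.

    ``wgd_branch="auto"`` picks the largest internal non-root clade
    (deterministic tie-break on the identifier); ``wgd_time=None``
    defaults to the branch midpoint.
    """
    branch = config.wgd_branch
    if branch is None:
        return None, None
    table = species_tree.branch_table()
    if branch == "auto":
        internal = table[~table["is_terminal"]]
        if internal.empty:
            internal = table
        internal = internal.sort_values(
            ["n_species", "branch"], ascending=[False, True]
        )
        branch = str(internal["branch"].iloc[0])
    if not species_tree.has_branch(branch) or species_tree.node(branch) is species_tree.root:
        raise ConfigError(f"wgd_branch {branch!r} is not a non-root branch")
    node = species_tree.node(branch)
    start = species_tree.node_age(node.parent_node)
    end = species_tree.node_age(node)
    t = config.wgd_time
    if t is None:
        t = 0.5 * (start + end)
    if not (start <= t <= end):
        raise ConfigError(
            f"wgd_time {t} outside the span ({start:.4g}, {end:.4g}] of branch {branch!r}"
        )
    return branch, float(t)


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------


class GeneNode:
    """Node of a (true) gene tree: an event with a time."""

    __slots__ = ("event", "time", "species", "children", "name", "wgd_side", "support")

    def __init__(self, event: str, time: float, species: str | None = None):
        self.event = event  # speciation | duplication | wgd | leaf | loss
        self.time = time
        self.species = species
        self.children: list[GeneNode] = []
        self.name: str | None = None
        self.wgd_side: str | None = None
        self.support: int | None = None

    def leaves(self) -> list["GeneNode"]:
        if not self.children:
            return [self] if self.event == "leaf" else []
        out: list[GeneNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self) -> Iterable["GeneNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Family:
    """One simulated gene family: the pruned true gene tree."""

    family_id: str
    root: GeneNode

    def leaves(self) -> list[GeneNode]:
        return self.root.leaves()

    def gene_ids(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def newick(self) -> str:
        def fmt(node: GeneNode, parent_time: float) -> str:
            length = node.time - parent_time
            if not node.children:
                return f"{node.name}:{length:.6f}"
            inner = ",".join(fmt(c, node.time) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{length:.6f}"

        if not self.root.children:
            return f"({self.root.name}:0.000000);"
        inner = ",".join(fmt(c, self.root.time) for c in self.root.children)
        return f"({inner});"

    def events(self) -> list[dict]:
        out = []
        for node in self.root.walk():
            if len(node.children) == 2:
                out.append(
                    {
                        "type": node.event,
                        "time": node.time,
                        "leaves1": sorted(lf.name for lf in node.children[0].leaves()),
                        "leaves2": sorted(lf.name for lf in node.children[1].leaves()),
                    }
                )
        return out

    def mrca_time(self, gene_a: str, gene_b: str) -> float:
        """Divergence time (age of the MRCA) of two member genes."""

        def find_path(node: GeneNode, target: str, path: list) -> bool:
            path.append(node)
            if node.name == target:
                return True
            for c in node.children:
                if find_path(c, target, path):
                    return True
            path.pop()
            return False

        pa: list[GeneNode] = []
        pb: list[GeneNode] = []
        if not find_path(self.root, gene_a, pa) or not find_path(self.root, gene_b, pb):
            raise KeyError("gene not in family")
        mrca = self.root
        for x, y in zip(pa, pb):
            if x is y:
                mrca = x
        return mrca.time


def _simulate_lineage(
    sp_node: dendropy.Node,
    t: float,
    species_tree: SpeciesTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    wgd_node: dendropy.Node | None,
    wgd_time: float | None,
    side: str | None,
) -> GeneNode:
    """Evolve one gene lineage along the species branch ending at sp_node."""
    end = species_tree.node_age(sp_node)
    lam, mu = config.birth_rate, config.loss_rate
    total = lam + mu
    while True:
        pulse = (
            wgd_time
            if (sp_node is wgd_node and wgd_time is not None and t < wgd_time)
            else None
        )
        t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf
        if pulse is not None and pulse <= min(t_next, end):
            t = pulse
            if rng.random() < config.retention:
                node = GeneNode("wgd", t)
                for child_side in ("A", "B"):
                    node.children.append(
                        _simulate_lineage(
                            sp_node, t, species_tree, config, rng,
                            wgd_node, wgd_time, side or child_side,
                        )
                    )
                return node
            continue
        if t_next < end:
            t = t_next
            if rng.random() < (lam / total if total > 0 else 0.0):
                node = GeneNode("duplication", t)
                for _ in range(2):
                    node.children.append(
                        _simulate_lineage(
                            sp_node, t, species_tree, config, rng,
                            wgd_node, wgd_time, side,
                        )
                    )
                return node
            return GeneNode("loss", t)
        if sp_node.is_leaf():
            leaf = GeneNode("leaf", end, species=sp_node.taxon.label)
            leaf.wgd_side = side
            return leaf
        node = GeneNode("speciation", end)
        for child_sp in sp_node.child_nodes():
            node.children.append(
                _simulate_lineage(
                    child_sp, end, species_tree, config, rng,
                    wgd_node, wgd_time, side,
                )
            )
        return node


def _prune(node: GeneNode) -> GeneNode | None:
    """Drop extinct lineages and splice out single-child internals."""
    if not node.children:
        return node if node.event == "leaf" else None
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def simulate_gene_family(
    species_tree: SpeciesTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    family_id: str = "f0",
    wgd_node: dendropy.Node | None = None,
    wgd_time: float | None = None,
) -> Family:
    """Simulate one gene family conditioned on survival.

    Extinct families (or families outside the min/max size filter) are
    resimulated up to ``config.retry_cap`` attempts.
    """
    for _ in range(config.retry_cap):
        root = GeneNode("speciation", 0.0)
        for child_sp in species_tree.root.child_nodes():
            root.children.append(
                _simulate_lineage(
                    child_sp, 0.0, species_tree, config, rng,
                    wgd_node, wgd_time, None,
                )
            )
        pruned = _prune(root)
        if pruned is None:
            continue
        n = len(pruned.leaves())
        if n < config.min_family_size:
            continue
        if config.max_family_size is not None and n > config.max_family_size:
            continue
        fam = Family(family_id, pruned)
        _name_and_support(fam, config, rng)
        return fam
    raise FamilyExtinctError(
        f"family {family_id}: no surviving genes in {config.retry_cap} attempts"
    )


def _name_and_support(
    family: Family, config: SimulationConfig, rng: np.random.Generator
) -> None:
    counters: dict[str, int] = {}
    for node in family.root.walk():
        if node.event == "leaf":
            k = counters.get(node.species, 0)
            counters[node.species] = k + 1
            node.name = f"{node.species}_{family.family_id}_g{k}"
        elif len(node.children) == 2:
            if config.support_noise > 0 and rng.random() < config.support_noise:
                node.support = int(rng.integers(0, 50))
            else:
                node.support = 100


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def evolve_codon_sequences(
    family: Family, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve in-frame CDS along the true gene tree; returns gene -> CDS.

    Only third positions of fourfold-degenerate codons mutate (Jukes-Cantor
    at ``syn_rate`` per site per time unit); the amino-acid sequence is
    fixed, so the nonsynonymous channel of any pairwise comparison is ~0
    and the expected synonymous divergence of two genes separated by
    divergence time t is 2 * t * syn_rate.  No stop codon is reachable.
    """
    L = config.codons_per_gene
    prefixes = [_SAFE_PREFIXES[i] for i in rng.integers(0, len(_SAFE_PREFIXES), L)]
    root_third = rng.integers(0, 4, L)

    out: dict[str, str] = {}

    def third_to_cds(third: np.ndarray) -> str:
        return "".join(p + BASES[b] for p, b in zip(prefixes, third))

    def evolve_branch(third: np.ndarray, dt: float) -> np.ndarray:
        if dt <= 0:
            return third.copy()
        stay = 0.25 + 0.75 * math.exp(-4.0 / 3.0 * config.syn_rate * dt)
        changed = rng.random(L) >= stay
        new = third.copy()
        n_changed = int(changed.sum())
        if n_changed:
            shift = rng.integers(1, 4, n_changed)
            new[changed] = (new[changed] + shift) % 4
        return new

    def walk(node: GeneNode, third: np.ndarray, t0: float) -> None:
        state = evolve_branch(third, node.time - t0)
        if node.event == "leaf":
            out[node.name] = third_to_cds(state)
            return
        for c in node.children:
            walk(c, state, node.time)

    walk(family.root, root_third, family.root.time)
    return out


# ---------------------------------------------------------------------------
# gene orders, fractionation, homolog pairs
# ---------------------------------------------------------------------------


def fractionate_gene_orders(
    families: list[Family],
    species_tree: SpeciesTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    wgd_branch: str | None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[list]]]:
    """Build per-species gene orders; apply fractionation to WGD copies.

    Mutates ``families``: genes occupying deleted duplicated slots are
    pruned from their gene trees (post-WGD fractionation erases the gene,
    not just its position).  Returns (positions, homolog pairs, true
    anchors per species); anchors are [gene_ancestral, gene_duplicated,
    ancestral_slot] triples ordered along the ancestral chromosome.
    """
    wgd_clade: frozenset[str] = (
        species_tree.clade(wgd_branch) if wgd_branch else frozenset()
    )
    slot_of_family = {
        fam.family_id: slot
        for slot, fam in zip(rng.permutation(len(families)), families)
    }

    # fractionation: per (species, family), drop the duplicated copy
    removed: set[str] = set()
    for fam in families:
        by_species: dict[str, dict[str, list[GeneNode]]] = {}
        for lf in fam.leaves():
            side = "B" if lf.wgd_side == "B" else "A"
            by_species.setdefault(lf.species, {"A": [], "B": []})[side].append(lf)
        for species in sorted(by_species):
            b_leaves = by_species[species]["B"]
            if b_leaves and rng.random() < config.fractionation:
                removed.update(lf.name for lf in b_leaves)

    if removed:
        for fam in families:
            fam.root = _prune_named(fam.root, removed)
    families[:] = [fam for fam in families if fam.root is not None]

    rows: list[dict] = []
    anchors: dict[str, list[list]] = {}
    for species in species_tree.leaves:
        in_wgd = species in wgd_clade
        # chromosome -> list of (sort_key, gene_id)
        chroms: dict[str, list[tuple[float, str, str]]] = {"chr1": []}
        if in_wgd:
            chroms["chr2"] = []
        sp_anchors: list[list] = []
        for fam in families:
            slot = float(slot_of_family[fam.family_id])
            a_genes = sorted(
                lf.name for lf in fam.leaves()
                if lf.species == species and lf.wgd_side != "B"
            )
            b_genes = sorted(
                lf.name for lf in fam.leaves()
                if lf.species == species and lf.wgd_side == "B"
            )
            for chrom, genes in (("chr1", a_genes), ("chr2", b_genes)):
                if not genes or chrom not in chroms:
                    continue
                chroms[chrom].append((slot, genes[0], fam.family_id))
                for j, extra in enumerate(genes[1:]):
                    if rng.random() < config.tandem_prob:
                        key = slot + (j + 1) / (len(genes) + 1.0)
                    else:
                        key = float(rng.uniform(0, len(families)))
                    chroms[chrom].append((key, extra, fam.family_id))
            if a_genes and b_genes:
                sp_anchors.append([a_genes[0], b_genes[0], int(slot)])
        if sp_anchors:
            sp_anchors.sort(key=lambda x: x[2])
            anchors[species] = sp_anchors
        for chrom in sorted(chroms):
            ordered = sorted(chroms[chrom])
            for rank, (_, gene, _fam) in enumerate(ordered):
                start = rank * 1000 + 1
                rows.append(
                    {
                        "gene_id": gene, "species": species, "chrom": chrom,
                        "rank": rank, "start": start, "end": start + 899,
                        "strand": "+",
                    }
                )
    positions = pd.DataFrame(
        rows, columns=["gene_id", "species", "chrom", "rank", "start", "end", "strand"]
    )

    pair_rows = []
    for fam in families:
        genes = sorted(fam.gene_ids())
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                pair_rows.append(
                    {"gene_a": genes[i], "gene_b": genes[j], "score": 100.0}
                )
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "score"])
    return positions, pairs, anchors


def _prune_named(node: GeneNode, removed: set[str]) -> GeneNode | None:
    if not node.children:
        return None if (node.event == "leaf" and node.name in removed) else node
    kept = [c for c in (_prune_named(c, removed) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


# ---------------------------------------------------------------------------
# LTR elements
# ---------------------------------------------------------------------------


def simulate_ltr_elements(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, float]]:
    """Paired 5'/3' LTR sequences with known insertion ages.

    Each element's two repeats start identical and independently accrue
    Jukes-Cantor substitutions for T years at ``ltr_rate`` per site per
    year; the expected corrected 5'-vs-3' divergence is K = 2 * r * T.
    """
    sequences: dict[str, str] = {}
    ages: dict[str, float] = {}
    L = config.ltr_length
    for i in range(config.n_ltr_elements):
        eid = f"ltr{i:04d}"
        age = float(rng.uniform(0.0, config.ltr_max_age_years))
        template = rng.integers(0, 4, L)
        copies = {}
        for side in ("5", "3"):
            stay = 0.25 + 0.75 * math.exp(-4.0 / 3.0 * config.ltr_rate * age)
            changed = rng.random(L) >= stay
            seq = template.copy()
            n_changed = int(changed.sum())
            if n_changed:
                seq[changed] = (seq[changed] + rng.integers(1, 4, n_changed)) % 4
            copies[side] = "".join(BASES[b] for b in seq)
        sequences[f"{eid}_5LTR"] = copies["5"]
        sequences[f"{eid}_3LTR"] = copies["3"]
        ages[eid] = age
    return sequences, ages


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the recovery tests need to score the pipeline."""

    wgd_branch: str | None
    wgd_time: float | None
    tip_age: float
    family_newicks: dict[str, str]
    family_events: dict[str, list[dict]]
    wgd_pairs: list[list]  # [gene_a, gene_b, divergence_time]
    anchors: dict[str, list[list]]  # species -> [[gene_a, gene_b, slot], ...]
    ltr_ages: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class Dataset:
    """A complete simulated input set plus its ground truth."""

    config: SimulationConfig
    species_tree_newick: str
    gene_trees: dict[str, str]  # family id -> newick
    sequences: dict[str, str]  # gene id -> CDS
    positions: pd.DataFrame
    pairs: pd.DataFrame
    ltr_sequences: dict[str, str]
    ground_truth: GroundTruth
    families: list[Family] = field(default_factory=list, repr=False)

    @property
    def species_tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.species_tree_newick)


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the full generative model under one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_species_tree(config, rng)
    wgd_branch, wgd_time = resolve_wgd_branch(config, species_tree)
    wgd_node = species_tree.node(wgd_branch) if wgd_branch else None

    families = [
        simulate_gene_family(
            species_tree, config, rng,
            family_id=f"f{i:04d}", wgd_node=wgd_node, wgd_time=wgd_time,
        )
        for i in range(config.n_families)
    ]
    positions, pairs, anchors = fractionate_gene_orders(
        families, species_tree, config, rng, wgd_branch
    )
    sequences: dict[str, str] = {}
    for fam in families:
        sequences.update(evolve_codon_sequences(fam, config, rng))
    ltr_sequences, ltr_ages = simulate_ltr_elements(config, rng)

    tip_age = species_tree.tip_age
    wgd_pairs: list[list] = []
    family_events: dict[str, list[dict]] = {}
    family_newicks: dict[str, str] = {}
    for fam in families:
        events = fam.events()
        family_events[fam.family_id] = events
        family_newicks[fam.family_id] = fam.newick()
        for ev in events:
            if ev["type"] == "wgd":
                for a in ev["leaves1"]:
                    for b in ev["leaves2"]:
                        wgd_pairs.append([a, b, tip_age - ev["time"]])

    truth = GroundTruth(
        wgd_branch=wgd_branch,
        wgd_time=wgd_time,
        tip_age=tip_age,
        family_newicks=family_newicks,
        family_events=family_events,
        wgd_pairs=wgd_pairs,
        anchors=anchors,
        ltr_ages=ltr_ages,
    )
    return Dataset(
        config=config,
        species_tree_newick=species_tree.to_newick(),
        gene_trees=family_newicks,
        sequences=sequences,
        positions=positions,
        pairs=pairs,
        ltr_sequences=ltr_sequences,
        ground_truth=truth,
        families=families,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FASTA_WIDTH = 60


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_dataset(dataset: Dataset, outdir) -> dict[str, str]:
    """Write all dataset files plus a checksum manifest; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "species_tree.nwk", "w") as fh:
        fh.write(dataset.species_tree_newick.strip() + "\n")
    with open(out / "gene_trees.nwk", "w") as fh:
        for fid in sorted(dataset.gene_trees):
            fh.write(dataset.gene_trees[fid].strip() + "\n")
    _write_fasta(out / "cds.fasta", dict(sorted(dataset.sequences.items())))
    _write_fasta(out / "ltr.fasta", dataset.ltr_sequences)
    dataset.positions.to_csv(out / "positions.tsv", sep="\t", index=False)
    dataset.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(dataset.ground_truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    dataset.config.to_yaml(out / "config.yaml")

    manifest: dict[str, str] = {}
    for name in sorted(
        ["species_tree.nwk", "gene_trees.nwk", "cds.fasta", "ltr.fasta",
         "positions.tsv", "pairs.tsv", "ground_truth.json", "config.yaml"]
    ):
        manifest[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_dataset(directory) -> Dataset:
    """Re-read a written dataset (gene trees come back as newick strings)."""
    d = Path(directory)
    config = SimulationConfig.from_yaml(d / "config.yaml")
    with open(d / "ground_truth.json") as fh:
        truth = GroundTruth.from_dict(json.load(fh))
    with open(d / "species_tree.nwk") as fh:
        species_newick = fh.read().strip()
    gene_trees: dict[str, str] = {}
    with open(d / "gene_trees.nwk") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fid = _family_of_tree(line)
            gene_trees[fid] = line
    sequences = _read_fasta(d / "cds.fasta")
    ltr_sequences = _read_fasta(d / "ltr.fasta")
    positions = pd.read_csv(d / "positions.tsv", sep="\t")
    pairs = pd.read_csv(d / "pairs.tsv", sep="\t")
    return Dataset(
        config=config,
        species_tree_newick=species_newick,
        gene_trees=gene_trees,
        sequences=sequences,
        positions=positions,
        pairs=pairs,
        ltr_sequences=ltr_sequences,
        ground_truth=truth,
    )


def _family_of_tree(newick: str) -> str:
    """Family id recovered from any leaf name (``species_family_gK``)."""
    import re

    m = re.search(r"[(,]([A-Za-z0-9]+_(f\d+)_g\d+)", newick)
    if not m:
        raise ValueError("cannot recover family id from gene tree leaf names")
    return m.group(2)


def family_id_of_gene(gene_id: str) -> str:
    return gene_id.split("_")[1]


def species_of_gene(gene_id: str) -> str:
    return gene_id.split("_")[0]
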