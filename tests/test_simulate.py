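"""Simulator: species trees, gene families, sequences, orders, serialization."""

from __future__ import annotations

import json
import math

import numpy as np
import pytest

from paleowgd import ks
from paleowgd.simulate import (
    ConfigError,
    Family,
    GeneNode,
    SimulationConfig,
    evolve_codon_sequences,
    read_dataset,
    resolve_wgd_branch,
    simulate_dataset,
    simulate_gene_family,
    simulate_species_tree,
    write_dataset,
)

STOPS = {"TAA", "TAG", "TGA"}


def _cfg(**kw) -> SimulationConfig:
    base = dict(n_species=8, n_families=5, codons_per_gene=30, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def test_smallest_tree_has_four_branches_and_is_ultrametric():
    tree = simulate_species_tree(_cfg(n_species=3))
    table = tree.branch_table()
    assert len(table) == 4
    assert int(table["is_terminal"].sum()) == 3
    for leaf in tree.leaves:
        assert tree.node_age(tree.mrca([leaf])) == pytest.approx(1.0, abs=1e-9)


def test_species_tree_determinism():
    a = simulate_species_tree(_cfg(seed=1)).to_newick()
    b = simulate_species_tree(_cfg(seed=1)).to_newick()
    assert a == b
    c = simulate_species_tree(_cfg(seed=2)).to_newick()
    assert a != c


def test_root_to_tip_paths_equal_height():
    cfg = _cfg(n_species=8, species_tree_height=1.0)
    tree = simulate_species_tree(cfg)
    for leaf in tree.leaves:
        assert tree.node_age(tree.mrca([leaf])) == pytest.approx(1.0, abs=1e-9)


def test_too_few_species_rejected():
    with pytest.raises(ConfigError):
        simulate_species_tree(_cfg(n_species=2))


def test_bad_parameters_rejected():
    with pytest.raises(ConfigError):
        _cfg(retention=1.5).validate()
    with pytest.raises(ConfigError):
        _cfg(birth_rate=-0.1).validate()
    with pytest.raises(ConfigError):
        _cfg(codons_per_gene=10).validate()


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------


def test_no_event_limit_reproduces_species_tree():
    cfg = _cfg(birth_rate=0.0, loss_rate=0.0, retention=0.0, wgd_branch=None)
    tree = simulate_species_tree(cfg)
    rng = np.random.default_rng(0)
    fam = simulate_gene_family(tree, cfg, rng, family_id="f0")
    leaves = fam.leaves()
    assert sorted(lf.species for lf in leaves) == sorted(tree.leaves)
    assert all(ev["type"] == "speciation" for ev in fam.events())


def test_certain_retention_doubles_every_species_below_the_branch():
    cfg = _cfg(birth_rate=0.0, loss_rate=0.0, retention=1.0)
    tree = simulate_species_tree(cfg)
    branch, wgd_time = resolve_wgd_branch(cfg, tree)
    rng = np.random.default_rng(0)
    fam = simulate_gene_family(
        tree, cfg, rng, family_id="f0",
        wgd_node=tree.node(branch), wgd_time=wgd_time,
    )
    below = tree.clade(branch)
    per_species: dict[str, int] = {}
    for lf in fam.leaves():
        per_species[lf.species] = per_species.get(lf.species, 0) + 1
    for sp in tree.leaves:
        assert per_species[sp] == (2 if sp in below else 1)
    wgd_events = [ev for ev in fam.events() if ev["type"] == "wgd"]
    assert len(wgd_events) == 1
    assert wgd_events[0]["time"] == pytest.approx(wgd_time)


def _oracle_family_outcome(sp_tree, cfg, rng, wgd_node, wgd_time):
    """Independent re-simulation returning (survives, has retained WGD dup).

    Worklist-free boolean recursion: a lineage reports whether anything
    below it survives and whether any WGD node below it kept survivors on
    both sides; no tree is built and no pruning step is involved.
    """

    def lineage(sp, t):
        end = sp_tree.node_age(sp)
        lam, mu = cfg.birth_rate, cfg.loss_rate
        total = lam + mu
        while True:
            pulse = wgd_time if (sp is wgd_node and t < wgd_time) else None
            t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf
            if pulse is not None and pulse <= min(t_next, end):
                t = pulse
                if rng.random() < cfg.retention:
                    a_alive, a_wgd = lineage(sp, t)
                    b_alive, b_wgd = lineage(sp, t)
                    return (
                        a_alive or b_alive,
                        (a_alive and b_alive) or a_wgd or b_wgd,
                    )
                continue
            if t_next < end:
                t = t_next
                if rng.random() < lam / total:
                    a_alive, a_wgd = lineage(sp, t)
                    b_alive, b_wgd = lineage(sp, t)
                    return a_alive or b_alive, a_wgd or b_wgd
                return False, False
            if sp.is_leaf():
                return True, False
            alive = False
            wgd = False
            for child in sp.child_nodes():
                c_alive, c_wgd = lineage(child, end)
                alive = alive or c_alive
                wgd = wgd or c_wgd
            return alive, wgd

    alive = False
    wgd = False
    for child in sp_tree.root.child_nodes():
        c_alive, c_wgd = lineage(child, 0.0)
        alive = alive or c_alive
        wgd = wgd or c_wgd
    return alive, wgd


def test_wgd_retention_fraction_matches_monte_carlo_oracle():
    """Fraction of surviving families with a retained WGD duplicate."""
    cfg = _cfg(
        birth_rate=0.2, loss_rate=0.2, retention=0.3, n_families=500, seed=7
    )
    tree = simulate_species_tree(cfg)
    branch, wgd_time = resolve_wgd_branch(cfg, tree)
    wgd_node = tree.node(branch)

    rng = np.random.default_rng(7)
    hits = 0
    for i in range(cfg.n_families):
        fam = simulate_gene_family(
            tree, cfg, rng, family_id=f"f{i}",
            wgd_node=wgd_node, wgd_time=wgd_time,
        )
        if any(ev["type"] == "wgd" for ev in fam.events()):
            hits += 1
    observed = hits / cfg.n_families

    oracle_rng = np.random.default_rng(977)
    reps = 20000
    surv = wgd = 0
    for _ in range(reps):
        alive, has_wgd = _oracle_family_outcome(tree, cfg, oracle_rng, wgd_node, wgd_time)
        if alive:
            surv += 1
            if has_wgd:
                wgd += 1
    expected = wgd / surv
    se = math.sqrt(
        expected * (1 - expected) / cfg.n_families
        + expected * (1 - expected) / surv
    )
    assert observed == pytest.approx(expected, abs=3 * se)


def test_background_duplication_count_calibrated_to_tree_length():
    """With no losses, E[duplication nodes] = birth_rate x total tree length."""
    cfg = _cfg(
        n_species=5, birth_rate=0.3, loss_rate=0.0, retention=0.0,
        wgd_branch=None, n_families=1000, seed=4,
    )
    tree = simulate_species_tree(cfg)
    rng = np.random.default_rng(4)
    total_dups = 0
    total_length = 0.0
    for i in range(cfg.n_families):
        fam = simulate_gene_family(tree, cfg, rng, family_id=f"f{i}")
        total_dups += sum(1 for ev in fam.events() if ev["type"] == "duplication")

        def tree_length(node, parent_time):
            out = node.time - parent_time
            for c in node.children:
                out += tree_length(c, node.time)
            return out

        total_length += tree_length(fam.root, fam.root.time)
    expected = cfg.birth_rate * total_length / cfg.n_families
    observed = total_dups / cfg.n_families
    assert observed == pytest.approx(expected, rel=0.1)


def test_wgd_pair_divergence_equals_time_since_pulse(small_dataset):
    truth = small_dataset.ground_truth
    expected = truth.tip_age - truth.wgd_time
    assert truth.wgd_pairs
    for _, _, t in truth.wgd_pairs:
        assert t == pytest.approx(expected, abs=1e-9)


def test_every_wgd_event_sits_on_the_planted_branch(small_dataset):
    """Species below a WGD-labelled node never leave the planted clade."""
    truth = small_dataset.ground_truth
    tree = small_dataset.species_tree
    clade = tree.clade(truth.wgd_branch)
    for events in truth.family_events.values():
        for ev in events:
            if ev["type"] != "wgd":
                continue
            species = {g.split("_")[0] for g in ev["leaves1"] + ev["leaves2"]}
            assert species <= set(clade)


# ---------------------------------------------------------------------------
# codon sequences
# ---------------------------------------------------------------------------


def _two_leaf_family(t: float, fid: str = "f0") -> Family:
    root = GeneNode("speciation", 0.0)
    for i, sp in enumerate(("sp01", "sp02")):
        leaf = GeneNode("leaf", t, species=sp)
        leaf.name = f"{sp}_{fid}_g0"
        root.children.append(leaf)
    root.support = 100
    return Family(fid, root)


def test_sequences_are_in_frame_and_stop_free(small_dataset):
    for gene, cds in small_dataset.sequences.items():
        assert len(cds) % 3 == 0
        codons = {cds[i : i + 3] for i in range(0, len(cds), 3)}
        assert not (codons & STOPS)


def test_zero_time_siblings_have_identical_sequences():
    cfg = _cfg(codons_per_gene=50)
    rng = np.random.default_rng(0)
    seqs = evolve_codon_sequences(_two_leaf_family(0.0), cfg, rng)
    a, b = seqs.values()
    assert a == b
    est = ks.ks_for_pair("a", a, "b", b)
    assert est.dS == 0.0


def test_pairwise_ks_calibrated_to_twice_divergence_time():
    """Sisters at t=0.2 under rate 1.0 should average Ks near 0.4."""
    cfg = _cfg(codons_per_gene=2000, syn_rate=1.0)
    rng = np.random.default_rng(42)
    values = []
    for i in range(200):
        seqs = evolve_codon_sequences(_two_leaf_family(0.2, f"f{i}"), cfg, rng)
        (ga, sa), (gb, sb) = seqs.items()
        est = ks.ks_for_pair(ga, sa, gb, sb)
        values.append(est.dS)
        assert est.dN == pytest.approx(0.0, abs=1e-12)  # amino acids frozen
    assert np.mean(values) == pytest.approx(0.4, rel=0.1)


# ---------------------------------------------------------------------------
# gene orders and fractionation
# ---------------------------------------------------------------------------


def test_no_fractionation_gives_fully_collinear_chromosome_copies():
    cfg = _cfg(
        birth_rate=0.0, loss_rate=0.0, retention=1.0, fractionation=0.0,
        n_families=40,
    )
    ds = simulate_dataset(cfg)
    clade = ds.species_tree.clade(ds.ground_truth.wgd_branch)
    for sp in clade:
        sub = ds.positions[ds.positions["species"] == sp]
        chr1 = sub[sub["chrom"] == "chr1"].sort_values("rank")
        chr2 = sub[sub["chrom"] == "chr2"].sort_values("rank")
        assert len(chr1) == len(chr2) == 40
        fam1 = [g.split("_")[1] for g in chr1["gene_id"]]
        fam2 = [g.split("_")[1] for g in chr2["gene_id"]]
        assert fam1 == fam2  # same family order: perfect collinearity


def test_total_fractionation_erases_all_duplicated_slots():
    cfg = _cfg(
        birth_rate=0.0, loss_rate=0.0, retention=1.0, fractionation=1.0,
        n_families=30,
    )
    ds = simulate_dataset(cfg)
    assert not ds.ground_truth.anchors
    assert "chr2" not in set(ds.positions["chrom"]) or (
        ds.positions[ds.positions["chrom"] == "chr2"].empty
    )
    assert not ds.ground_truth.wgd_pairs  # fractionated copies were pruned


def test_half_fractionation_within_binomial_bounds():
    cfg = _cfg(
        birth_rate=0.0, loss_rate=0.0, retention=1.0, fractionation=0.5,
        n_families=200, seed=3,
    )
    ds = simulate_dataset(cfg)
    # binomial(200, 0.5) 99% bounds: ~100 +- 2.58 * sqrt(50)
    lo, hi = 100 - 2.58 * math.sqrt(50), 100 + 2.58 * math.sqrt(50)
    counts = [len(v) for v in ds.ground_truth.anchors.values()]
    assert counts
    assert lo <= np.mean(counts) <= hi


def test_ranks_are_a_permutation_per_chromosome(small_dataset):
    pos = small_dataset.positions
    for (_, _), sub in pos.groupby(["species", "chrom"]):
        assert sorted(sub["rank"]) == list(range(len(sub)))
        assert (sub["start"] <= sub["end"]).all()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_write_read_round_trip(tmp_path):
    cfg = _cfg(n_families=10, codons_per_gene=30, seed=9)
    ds = simulate_dataset(cfg)
    write_dataset(ds, tmp_path)
    back = read_dataset(tmp_path)
    assert back.species_tree_newick == ds.species_tree_newick
    assert back.gene_trees == ds.gene_trees
    assert back.sequences == ds.sequences
    assert back.ltr_sequences == ds.ltr_sequences
    assert back.positions.equals(ds.positions)
    assert back.pairs.equals(ds.pairs)
    assert back.ground_truth.to_dict() == ds.ground_truth.to_dict()
    assert back.config == cfg


def test_fixed_seed_reproduces_byte_identical_files(tmp_path):
    cfg = _cfg(n_families=8, seed=33)
    m1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
    m2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
    assert m1 == m2  # manifests are content checksums


def test_manifest_checksum_tracks_content(tmp_path):
    cfg = _cfg(n_families=5, seed=2)
    ds = simulate_dataset(cfg)
    manifest = write_dataset(ds, tmp_path)
    with open(tmp_path / "pairs.tsv", "a") as fh:
        fh.write("x\ty\t1.0\n")
    import hashlib

    new = hashlib.sha256((tmp_path / "pairs.tsv").read_bytes()).hexdigest()
    assert new != manifest["pairs.tsv"]
    assert (
        hashlib.sha256((tmp_path / "cds.fasta").read_bytes()).hexdigest()
        == manifest["cds.fasta"]
    )


def test_empty_family_set_still_writes_a_valid_manifest(tmp_path):
    cfg = _cfg(n_families=0)
    ds = simulate_dataset(cfg)
    manifest = write_dataset(ds, tmp_path)
    assert set(manifest) == {
        "species_tree.nwk", "gene_trees.nwk", "cds.fasta", "ltr.fasta",
        "positions.tsv", "pairs.tsv", "ground_truth.json", "config.yaml",
    }
    with open(tmp_path / "ground_truth.json") as fh:
        truth = json.load(fh)
    assert truth["family_newicks"] == {}
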