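"""Collinear-block detection and duplicate-pair classification.

Blocks are chains of homologous gene pairs (anchors) whose ranks run
monotonically along both chromosomal regions.  Chaining maximizes anchor
count by dynamic programming under a rank-gap cap in both genomes, run
separately for the two orientations (parallel and inverted); chains below
``min_block_size`` anchors are discarded and overlapping chains are
resolved greedily by score.  This is a deliberately simplified take on the
MCScanX model: anchor count stands in for the e-value-based block score.

Duplicate pairs are then classified into the five standard arrangement
categories, in priority order:

WGD        anchor pair of an intra-genome collinear block
tandem     same chromosome, adjacent ranks
proximal   same chromosome, rank distance <= proximal_window (10)
transposed exactly one member is an anchor in a block against a
           designated reference genome (an ancestral-locus proxy)
dispersed  everything else
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

POSITION_COLUMNS = ["gene_id", "species", "chrom", "rank", "start", "end", "strand"]
PAIR_COLUMNS = ["gene_a", "gene_b", "score"]

CATEGORIES = ("WGD", "tandem", "proximal", "transposed", "dispersed")


class MissingGeneError(KeyError):
    """A gene named in the pair list has no entry in the position table."""


@dataclass
class SyntenyBlock:
    """One collinear block: an ordered chain of anchor gene pairs."""

    block_id: int
    species_a: str
    chrom_a: str
    species_b: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def score(self) -> int:
        return len(self.anchors)

    @property
    def intra_genome(self) -> bool:
        return self.species_a == self.species_b

    def anchor_pairs(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in self.anchors}


def read_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(POSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"position table missing columns: {sorted(missing)}")
    return df


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair list missing columns: {sorted(missing)}")
    return df


def _position_index(positions: pd.DataFrame) -> dict[str, tuple[str, str, int]]:
    return {
        g: (s, c, int(r))
        for g, s, c, r in zip(
            positions["gene_id"], positions["species"],
            positions["chrom"], positions["rank"],
        )
    }


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _chain_dp(
    anchors: list[tuple[int, int, int]], orientation: str, max_gap: int
) -> list[int]:
    """Best chain (max anchors, ties to the earliest start) by O(n^2) DP.

    ``anchors``: (rank1, rank2, index) sorted by (rank1, rank2).  A chain
    needs strictly increasing rank1, strictly monotone rank2 (increasing
    for "same", decreasing for "inverted") and rank gaps <= max_gap on
    both axes.  Returns indices into ``anchors`` of the best chain.
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        r1j, r2j, _ = anchors[j]
        for i in range(j):
            r1i, r2i, _ = anchors[i]
            gap1 = r1j - r1i
            if gap1 <= 0 or gap1 > max_gap:
                continue
            gap2 = r2j - r2i if orientation == "same" else r2i - r2j
            if gap2 <= 0 or gap2 > max_gap:
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best_len[j], -j)) if n else -1
    if end < 0:
        return []
    chain = []
    while end >= 0:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_blocks(
    pairs: pd.DataFrame,
    positions: pd.DataFrame,
    min_block_size: int = 5,
    max_gap: int = 25,
    self_min_distance: int | None = None,
) -> list[SyntenyBlock]:
    """Chain homologous gene pairs into collinear blocks.

    Pairs are grouped by chromosome pair (self-comparisons included,
    self-matches of a gene with itself excluded) and chained separately in
    the two orientations; the longest chain is extracted, its anchors are
    removed, and chaining repeats until no chain reaches
    ``min_block_size``.

    In a chromosome's comparison against itself, pairs closer than
    ``self_min_distance`` ranks (default: ``max_gap``) are not used as
    anchors: runs of tandem/proximal duplicates from unrelated families
    otherwise chain along the diagonal and masquerade as duplicated
    segments.  Two regions closer than the permitted intra-chain gap are
    one genomic neighbourhood, not a pair of duplicated regions.
    """
    if self_min_distance is None:
        self_min_distance = max_gap
    index = _position_index(positions)
    groups: dict[tuple, list[tuple[int, int, str, str]]] = {}
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        if ga == gb:
            continue
        for g in (ga, gb):
            if g not in index:
                raise MissingGeneError(
                    f"gene {g!r} from the pair list is absent from the position table"
                )
        sa, ca, ra = index[ga]
        sb, cb, rb = index[gb]
        # orient the pair so the group key is canonical
        if (sb, cb) < (sa, ca) or ((sa, ca) == (sb, cb) and rb < ra):
            ga, gb, sa, ca, ra, sb, cb, rb = gb, ga, sb, cb, rb, sa, ca, ra
        if (sa, ca) == (sb, cb) and rb - ra <= self_min_distance:
            continue  # diagonal fuzz in self-comparisons
        groups.setdefault((sa, ca, sb, cb), []).append((ra, rb, ga, gb))

    blocks: list[SyntenyBlock] = []
    block_id = 0
    for (sa, ca, sb, cb) in sorted(groups):
        pool = sorted(set(groups[(sa, ca, sb, cb)]))
        while pool:
            indexed = [(r1, r2, i) for i, (r1, r2, _, _) in enumerate(pool)]
            best_chain: list[int] = []
            best_orient = "same"
            for orientation in ("same", "inverted"):
                chain = _chain_dp(indexed, orientation, max_gap)
                if len(chain) > len(best_chain):
                    best_chain = chain
                    best_orient = orientation
            if len(best_chain) < min_block_size:
                break
            anchors = [(pool[i][2], pool[i][3]) for i in best_chain]
            blocks.append(
                SyntenyBlock(
                    block_id=block_id,
                    species_a=sa, chrom_a=ca,
                    species_b=sb, chrom_b=cb,
                    orientation=best_orient,
                    anchors=anchors,
                )
            )
            block_id += 1
            used = {best_chain[k] for k in range(len(best_chain))}
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def blocks_to_frame(blocks: Iterable[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for k, (ga, gb) in enumerate(b.anchors):
            rows.append(
                {
                    "block_id": b.block_id,
                    "species_a": b.species_a, "chrom_a": b.chrom_a,
                    "species_b": b.species_b, "chrom_b": b.chrom_b,
                    "orientation": b.orientation,
                    "anchor_index": k,
                    "gene_a": ga, "gene_b": gb,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "species_a", "chrom_a", "species_b", "chrom_b",
            "orientation", "anchor_index", "gene_a", "gene_b",
        ],
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_duplicates(
    pairs: pd.DataFrame,
    positions: pd.DataFrame,
    blocks: Iterable[SyntenyBlock],
    proximal_window: int = 10,
    reference_species: str | None = None,
) -> pd.DataFrame:
    """Assign each intra-genome duplicate pair to exactly one category.

    Priority: WGD > tandem > proximal > transposed > dispersed.  The
    transposed test needs ``reference_species``: a pair is transposed when
    exactly one member anchors a block against that genome (the member
    with a syntenic reference locus marks the ancestral copy).  Without a
    reference genome the category is unreachable and such pairs fall
    through to dispersed.  Between-species pairs are not classified.
    """
    index = _position_index(positions)
    blocks = list(blocks)
    intra_anchor_pairs: set[frozenset[str]] = set()
    reference_anchored: set[str] = set()
    for b in blocks:
        if b.intra_genome:
            intra_anchor_pairs |= b.anchor_pairs()
        if reference_species and reference_species in (b.species_a, b.species_b):
            for ga, gb in b.anchors:
                if b.species_a != reference_species:
                    reference_anchored.add(ga)
                if b.species_b != reference_species:
                    reference_anchored.add(gb)

    rows = []
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        if ga == gb:
            continue
        for g in (ga, gb):
            if g not in index:
                raise MissingGeneError(
                    f"gene {g!r} from the pair list is absent from the position table"
                )
        sa, ca, ra = index[ga]
        sb, cb, rb = index[gb]
        if sa != sb:
            continue
        key = frozenset((ga, gb))
        distance = abs(ra - rb) if ca == cb else np.nan
        if key in intra_anchor_pairs:
            category, evidence = "WGD", "block_anchor"
        elif ca == cb and abs(ra - rb) == 1:
            category, evidence = "tandem", f"rank_distance={abs(ra - rb)}"
        elif ca == cb and abs(ra - rb) <= proximal_window:
            category, evidence = "proximal", f"rank_distance={abs(ra - rb)}"
        elif (ga in reference_anchored) != (gb in reference_anchored):
            category, evidence = "transposed", "one_reference_anchor"
        else:
            category, evidence = "dispersed", ""
        rows.append(
            {
                "gene_a": ga, "gene_b": gb, "species": sa,
                "category": category, "evidence": evidence,
                "rank_distance": distance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "species", "category", "evidence", "rank_distance"],
    )


def syntenic_ks_pairs(
    blocks: Iterable[SyntenyBlock],
    ks_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Restrict a Ks table to intra-genome block anchors.

    Returns (anchor Ks rows, per-block median Ks, count of anchor pairs
    with no Ks estimate).  The anchor sample is the input to peak
    detection when dating a WGD: block anchors are the pairs whose
    duplication the collinearity evidence ties to the genome doubling.
    """
    ks_by_pair = {
        frozenset((a, b)): i
        for i, (a, b) in enumerate(zip(ks_table["gene_a"], ks_table["gene_b"]))
    }
    rows_idx: list[int] = []
    seen: set[frozenset[str]] = set()
    per_block = []
    n_missing = 0
    for b in blocks:
        if not b.intra_genome:
            continue
        block_ks: list[float] = []
        for pair in b.anchor_pairs():
            i = ks_by_pair.get(pair)
            if i is None:
                n_missing += 1
                continue
            if pair not in seen:
                seen.add(pair)
                rows_idx.append(i)
            ds = ks_table["dS"].iloc[i]
            if pd.notna(ds):
                block_ks.append(float(ds))
        per_block.append(
            {
                "block_id": b.block_id,
                "n_anchors": b.n_anchors,
                "median_ks": float(np.median(block_ks)) if block_ks else np.nan,
            }
        )
    anchor_ks = ks_table.iloc[sorted(rows_idx)].reset_index(drop=True)
    return anchor_ks, pd.DataFrame(per_block, columns=["block_id", "n_anchors", "median_ks"]), n_missing
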