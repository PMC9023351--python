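"""Pairwise Ka/Ks estimation (Nei-Gojobori 1986) and Ks-peak detection.

The counting method follows the classic NG86 scheme as implemented in
PAML's ``yn00``:

* Each codon contributes fractional synonymous (s) and nonsynonymous (n)
  site counts, with s + n = 3.  At every codon position the three possible
  single-nucleotide changes are examined; changes that would create a stop
  codon are excluded and the remaining changes are rescaled so the position
  still contributes exactly one site.
* For a differing codon pair, all minimal mutational pathways (k! orderings
  of the k differing positions) are enumerated; pathways passing through a
  stop codon are discarded and the synonymous/nonsynonymous step counts are
  averaged over the surviving pathways.
* Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
  the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3); pS >= 3/4 is reported
  as saturated (dS undefined).

Codon alignments are produced by globally aligning the translated proteins
(Needleman-Wunsch, BLOSUM62, affine gap penalties) and back-threading the
codons; gapped or ambiguous columns are masked out of the counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
_AA = dict(standard_dna_table.forward_table)

GAP_CODON = "---"


class CodonError(ValueError):
    """An input codon or CDS violates the coding-sequence contract."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon {codon} has no NG86 site decomposition")
    if codon not in _AA:
        raise CodonError(f"not an unambiguous sense codon: {codon!r}")
    return codon


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    For each of the three positions, the synonymous fraction is the number
    of synonymous single-nucleotide changes divided by the number of
    changes that do not create a stop codon; the position always
    contributes one full site, so s + n = 3 exactly.
    """
    codon = _check_sense(codon)
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            nonstop += 1
            if _AA[mutant] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon pair.

    All k! orderings of the k differing positions are walked; orderings that
    pass through a stop codon are discarded.  Should every ordering be
    blocked (not reachable for sense codons under the standard code, but
    guarded), the average is taken over all orderings instead, scoring a
    step into or out of a stop codon as nonsynonymous.
    """
    codon_a = _check_sense(codon_a)
    codon_b = _check_sense(codon_b)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    surviving: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        syn = non = 0
        current = codon_a
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                if nxt in STOP_CODONS:
                    blocked = True
                non += 1
            elif _AA[nxt] == _AA[current]:
                syn += 1
            else:
                non += 1
            current = nxt
        all_paths.append((syn, non))
        if not blocked:
            surviving.append((syn, non))
    paths = surviving if surviving else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); nan if p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------


@dataclass
class CodonPairAlignment:
    """A pairwise codon alignment with per-column usability flags."""

    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]
    usable: list[bool]

    def __post_init__(self) -> None:
        if not (len(self.codons_a) == len(self.codons_b) == len(self.usable)):
            raise ValueError("alignment columns must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.codons_a)

    @property
    def usable_codons(self) -> int:
        return sum(self.usable)

    def usable_pairs(self) -> Iterable[tuple[str, str]]:
        for ca, cb, ok in zip(self.codons_a, self.codons_b, self.usable):
            if ok:
                yield ca, cb


def _translate_cds(gene: str, cds: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise CodonError(f"{gene}: CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # tolerate a terminal stop
    protein = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise CodonError(f"{gene}: internal stop codon {codon} at codon {i}")
        protein.append(_AA.get(codon, "X"))
    return "".join(protein)


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _is_clean(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in BASES for b in codon)
        and codon not in STOP_CODONS
    )


def align_codon_pair(
    gene_a: str, cds_a: str, gene_b: str, cds_b: str
) -> CodonPairAlignment:
    """Protein-guided global codon alignment of two in-frame CDS.

    Proteins are aligned with Needleman-Wunsch under BLOSUM62 with affine
    gap penalties and the codons are threaded back through the protein
    alignment.  Columns containing a gap, an ambiguous base, or a stop
    codon are flagged unusable.
    """
    cds_a = cds_a.upper().replace("U", "T")
    cds_b = cds_b.upper().replace("U", "T")
    prot_a = _translate_cds(gene_a, cds_a)
    prot_b = _translate_cds(gene_b, cds_b)
    cod_a = [cds_a[i : i + 3] for i in range(0, 3 * len(prot_a), 3)]
    cod_b = [cds_b[i : i + 3] for i in range(0, 3 * len(prot_b), 3)]

    if prot_a == prot_b:
        # identical proteins align residue-to-residue; skip the DP
        aligned_a, aligned_b = cod_a, cod_b
    else:
        alignment = _protein_aligner().align(prot_a, prot_b)[0]
        aligned_a, aligned_b = [], []
        ia = ib = 0
        for col_a, col_b in zip(alignment[0], alignment[1]):
            if col_a == "-":
                aligned_a.append(GAP_CODON)
            else:
                aligned_a.append(cod_a[ia])
                ia += 1
            if col_b == "-":
                aligned_b.append(GAP_CODON)
            else:
                aligned_b.append(cod_b[ib])
                ib += 1

    usable = [_is_clean(ca) and _is_clean(cb) for ca, cb in zip(aligned_a, aligned_b)]
    return CodonPairAlignment(gene_a, gene_b, list(aligned_a), list(aligned_b), usable)


# ---------------------------------------------------------------------------
# NG86 on a pair
# ---------------------------------------------------------------------------


@dataclass
class KsEstimate:
    """NG86 site/difference counts and JC-corrected dS (Ks) and dN (Ka)."""

    gene_a: str
    gene_b: str
    usable_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    flag: str = "ok"  # ok | saturated | no_syn_sites | no_usable

    @property
    def defined(self) -> bool:
        return self.flag == "ok"


def ng86_pair(aln: CodonPairAlignment) -> KsEstimate:
    """NG86 estimate for one aligned pair.

    S and N are the means of the two sequences' per-codon site sums over
    usable columns; Sd and Nd are pathway-averaged difference counts.
    """
    if aln.usable_codons == 0:
        raise CodonError(
            f"{aln.gene_a} vs {aln.gene_b}: no usable codon columns to count"
        )
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    usable = 0
    for ca, cb in aln.usable_pairs():
        usable += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        if ca != cb:
            d_s, d_n = ng86_codon_differences(ca, cb)
            sd += d_s
            nd += d_n
    S = 0.5 * (s_a + s_b)
    N = 0.5 * (n_a + n_b)
    if S <= 0.0:
        return KsEstimate(
            aln.gene_a, aln.gene_b, usable, S, N, sd, nd,
            math.nan, nd / N if N else math.nan, math.nan, math.nan,
            flag="no_syn_sites",
        )
    pS = sd / S
    pN = nd / N if N > 0 else 0.0
    dN = jukes_cantor(pN)
    if pS >= 0.75:
        return KsEstimate(
            aln.gene_a, aln.gene_b, usable, S, N, sd, nd, pS, pN,
            math.nan, dN, flag="saturated",
        )
    dS = jukes_cantor(pS)
    return KsEstimate(aln.gene_a, aln.gene_b, usable, S, N, sd, nd, pS, pN, dS, dN)


def ks_for_pair(gene_a: str, cds_a: str, gene_b: str, cds_b: str) -> KsEstimate:
    """Convenience wrapper: align two CDS and run the NG86 counts."""
    return ng86_pair(align_codon_pair(gene_a, cds_a, gene_b, cds_b))


# ---------------------------------------------------------------------------
# Ks distribution and peak detection
# ---------------------------------------------------------------------------


@dataclass
class KsSample:
    """A filtered Ks sample plus the bookkeeping of what was excluded."""

    values: np.ndarray
    ks_min: float
    ks_max: float
    n_input: int
    n_retained: int
    n_undefined: int
    n_out_of_range: int

    @property
    def empty(self) -> bool:
        return self.n_retained == 0


def build_ks_distribution(
    estimates: Iterable[KsEstimate | float],
    ks_min: float = 0.01,
    ks_max: float = 5.0,
) -> KsSample:
    """Retain defined dS values inside [ks_min, ks_max].

    The lower bound strips the zero-inflation caused by alleles and
    alternative transcripts; the upper bound strips near-saturated pairs.
    """
    if not ks_min < ks_max:
        raise ValueError("ks_min must be smaller than ks_max")
    values = []
    n_input = n_undefined = n_out = 0
    for est in estimates:
        n_input += 1
        ds = est if isinstance(est, (int, float)) else est.dS
        if ds is None or (isinstance(ds, float) and math.isnan(ds)):
            n_undefined += 1
            continue
        if ks_min <= ds <= ks_max:
            values.append(float(ds))
        else:
            n_out += 1
    arr = np.asarray(sorted(values), dtype=float)
    return KsSample(arr, ks_min, ks_max, n_input, len(arr), n_undefined, n_out)


@dataclass
class KsPeakReport:
    """Detected Ks modes with the fraction of pairs attributed to each."""

    modes: list[float]
    masses: list[float]
    ks_min: float
    ks_max: float
    method: str
    n_pairs: int
    metadata: dict = field(default_factory=dict)
    flag: str = "ok"  # ok | insufficient_data | empty

    def to_dict(self) -> dict:
        return {
            "modes": self.modes,
            "masses": self.masses,
            "ks_min": self.ks_min,
            "ks_max": self.ks_max,
            "method": self.method,
            "n_pairs": self.n_pairs,
            "metadata": self.metadata,
            "flag": self.flag,
        }


MIN_PEAK_SAMPLE = 50


def detect_ks_peaks(
    sample: KsSample | np.ndarray,
    method: str = "kde",
    max_components: int = 4,
    grid_size: int = 512,
) -> KsPeakReport:
    """Find modes of a Ks sample on the log scale.

    ``kde``: Gaussian kernel density on ln(Ks) with Silverman bandwidth;
    modes are local maxima of the density mapped back to the Ks scale, and
    per-mode mass is the fraction of pairs nearest (in ln space) to each
    mode.  ``gmm``: Gaussian mixture on ln(Ks) with the component count
    chosen by BIC; modes are the component means and masses the weights.
    """
    if isinstance(sample, KsSample):
        values = sample.values
        ks_min, ks_max = sample.ks_min, sample.ks_max
    else:
        values = np.asarray(sample, dtype=float)
        ks_min = float(values.min()) if values.size else 0.0
        ks_max = float(values.max()) if values.size else 0.0
    n = int(values.size)
    if n == 0:
        return KsPeakReport([], [], ks_min, ks_max, method, 0, flag="empty")
    if n < MIN_PEAK_SAMPLE:
        return KsPeakReport([], [], ks_min, ks_max, method, n, flag="insufficient_data")

    log_ks = np.log(values)
    if method == "kde":
        from scipy.stats import gaussian_kde

        if np.ptp(log_ks) < 1e-12:  # degenerate: all mass at one value
            return KsPeakReport(
                [float(values[0])], [1.0], ks_min, ks_max, "kde", n,
                metadata={"bandwidth": 0.0},
            )
        kde = gaussian_kde(log_ks, bw_method="silverman")
        bw = float(kde.factor * log_ks.std(ddof=1))
        grid = np.linspace(log_ks.min() - 3 * bw, log_ks.max() + 3 * bw, grid_size)
        density = kde(grid)
        interior = np.flatnonzero(
            (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
        ) + 1
        if interior.size == 0:
            interior = np.array([int(np.argmax(density))])
        log_modes = grid[interior]
        assignment = np.argmin(
            np.abs(log_ks[:, None] - log_modes[None, :]), axis=1
        )
        masses = [float(np.mean(assignment == i)) for i in range(log_modes.size)]
        modes = [float(np.exp(m)) for m in log_modes]
        meta = {"bandwidth": bw, "grid_size": grid_size}
    elif method == "gmm":
        from sklearn.mixture import GaussianMixture

        X = log_ks.reshape(-1, 1)
        best = None
        for k in range(1, min(max_components, n) + 1):
            gm = GaussianMixture(n_components=k, random_state=0, n_init=2)
            gm.fit(X)
            bic = gm.bic(X)
            if best is None or bic < best[0]:
                best = (bic, gm)
        gm = best[1]
        modes = [float(np.exp(m)) for m in gm.means_.ravel()]
        masses = [float(w) for w in gm.weights_]
        meta = {"n_components": gm.n_components, "bic": float(best[0])}
    else:
        raise ValueError(f"unknown peak-detection method: {method!r}")

    order = np.argsort(modes)
    return KsPeakReport(
        [modes[i] for i in order],
        [masses[i] for i in order],
        ks_min,
        ks_max,
        method,
        n,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

KS_TABLE_COLUMNS = [
    "gene_a", "gene_b", "usable_codons", "S", "N", "Sd", "Nd",
    "pS", "pN", "dS", "dN", "flag",
]


def estimates_to_frame(estimates: Iterable[KsEstimate]):
    import pandas as pd

    rows = [
        {
            "gene_a": e.gene_a, "gene_b": e.gene_b,
            "usable_codons": e.usable_codons,
            "S": e.S, "N": e.N, "Sd": e.Sd, "Nd": e.Nd,
            "pS": e.pS, "pN": e.pN, "dS": e.dS, "dN": e.dN, "flag": e.flag,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=KS_TABLE_COLUMNS)
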