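"""LTR retrotransposon insertion-time dating.

The two long terminal repeats of a retroelement are identical at the
moment of insertion and diverge afterwards at the neutral rate, so the
corrected 5'/3' LTR divergence K dates the insertion:

    T = K / (2 r)

with r the substitution rate per site per year (default 2.2e-9).  K is
obtained from a global nucleotide alignment: the raw mismatch proportion p
over ungapped columns is corrected for multiple hits with Jukes-Cantor,
K = -(3/4) ln(1 - 4p/3); the Kimura two-parameter correction is available
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

DEFAULT_RATE = 2.2e-9  # substitutions per site per year

_PURINES = {"A", "G"}


@dataclass
class ClockParams:
    """Molecular-clock parameter: substitution rate per site per year."""

    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("substitution rate must be positive")


@dataclass
class LTRElement:
    """One dated retroelement."""

    element_id: str
    p: float
    K: float
    T_years: float
    aligned_length: int
    flag: str = "ok"  # ok | saturated | error


class SaturationError(ValueError):
    """Divergence beyond the validity of the distance correction."""


def _nt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def ltr_divergence(
    seq5: str, seq3: str, correction: str = "jc"
) -> tuple[float, float, int]:
    """Align the two LTRs and return (p, K, ungapped columns).

    p is the mismatch proportion over ungapped alignment columns; K is the
    corrected divergence ("jc" Jukes-Cantor or "k2p" Kimura 2-parameter).
    """
    seq5 = seq5.upper().replace("U", "T")
    seq3 = seq3.upper().replace("U", "T")
    if not seq5 or not seq3:
        raise ValueError("both LTR sequences must be nonempty")
    alignment = _nt_aligner().align(seq5, seq3)[0]
    a, b = str(alignment[0]), str(alignment[1])
    ungapped = 0
    mismatches = 0
    transitions = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        ungapped += 1
        if ca != cb:
            mismatches += 1
            if (ca in _PURINES) == (cb in _PURINES):
                transitions += 1
    if ungapped == 0:
        raise ValueError("alignment has no ungapped columns")
    p = mismatches / ungapped
    if correction == "jc":
        if p >= 0.75:
            raise SaturationError(f"p = {p:.3f} >= 3/4: distance saturated")
        K = -0.75 * math.log1p(-4.0 * p / 3.0)
    elif correction == "k2p":
        P = transitions / ungapped
        Q = (mismatches - transitions) / ungapped
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError("divergence saturated under K2P")
        K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    return p, K, ungapped


def insertion_time(K: float, params: ClockParams | float = DEFAULT_RATE) -> float:
    """Insertion time in years: T = K / (2 r)."""
    rate = params.rate if isinstance(params, ClockParams) else float(params)
    if K < 0:
        raise ValueError("divergence K must be non-negative")
    if not rate > 0:
        raise ValueError("substitution rate must be positive")
    return K / (2.0 * rate)


def pair_ltr_records(records: Iterable) -> dict[str, dict[str, str]]:
    """Group FASTA records named ``<id>_5LTR`` / ``<id>_3LTR`` by element."""
    return pair_ltr_sequences({rec.id: str(rec.seq) for rec in records})


def pair_ltr_sequences(sequences: dict[str, str]) -> dict[str, dict[str, str]]:
    """Group ``<id>_5LTR`` / ``<id>_3LTR`` named sequences by element id."""
    elements: dict[str, dict[str, str]] = {}
    for name, seq in sequences.items():
        for suffix, side in (("_5LTR", "5"), ("_3LTR", "3")):
            if name.endswith(suffix):
                elements.setdefault(name[: -len(suffix)], {})[side] = seq
                break
    return elements


def date_elements(
    fasta_path,
    params: ClockParams | float = DEFAULT_RATE,
    correction: str = "jc",
) -> pd.DataFrame:
    """Date every paired element of a FASTA file; see date_element_sequences."""
    elements = pair_ltr_records(SeqIO.parse(str(fasta_path), "fasta"))
    return date_element_sequences(elements, params=params, correction=correction)


def date_element_sequences(
    elements: dict[str, dict[str, str]],
    params: ClockParams | float = DEFAULT_RATE,
    correction: str = "jc",
) -> pd.DataFrame:
    """Date every element of an ``id -> {"5": seq, "3": seq}`` mapping.

    Elements whose divergence is saturated or whose sequences fail to
    align are retained in the table with a flag, so that
    processed + saturated + errored = input elements.
    """
    rows = []
    for element_id in sorted(elements):
        sides = elements[element_id]
        if "5" not in sides or "3" not in sides:
            rows.append(
                {"element": element_id, "p": math.nan, "K": math.nan,
                 "T_years": math.nan, "flag": "error:unpaired"}
            )
            continue
        try:
            p, K, _ = ltr_divergence(sides["5"], sides["3"], correction=correction)
            T = insertion_time(K, params)
            rows.append({"element": element_id, "p": p, "K": K,
                         "T_years": T, "flag": "ok"})
        except SaturationError:
            rows.append({"element": element_id, "p": math.nan, "K": math.nan,
                         "T_years": math.nan, "flag": "saturated"})
        except ValueError as exc:
            rows.append({"element": element_id, "p": math.nan, "K": math.nan,
                         "T_years": math.nan, "flag": f"error:{exc}"})
    return pd.DataFrame(rows, columns=["element", "p", "K", "T_years", "flag"])
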