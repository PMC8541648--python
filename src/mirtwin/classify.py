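"""Family discrimination for the miR156/miR529 twin families.

miR156 and miR529 are near-twin plant microRNA families that both target
SPL (SQUAMOSA promoter binding protein-like) transcription factors and share
most of their mature sequence.  This module implements the machinery that
tells them apart:

* the 5'-terminal motif rule — a mature sequence in the superfamily that
  starts with ``UGAC`` or ``CGAC`` is miR156; any other 5' end is miR529;
* the MS (mismatch-sensitive) region, mature nucleotides 2–13, the pairing
  region critical for target recognition;
* ungapped best-overlap identity counting between two matures;
* scanning a precursor for an embedded family-like window (miR529-like
  sequences hidden inside annotated miR156 precursors, and vice versa);
* family assignment of a candidate precursor by global-alignment similarity
  to reference pre-miR156/pre-miR529 sets;
* a per-position nucleotide frequency matrix (the tabular equivalent of a
  sequence logo) with information content in bits.

The motif rule is a two-step contract: it is only meaningful for sequences
already established to belong to the miR156/miR529 superfamily (by
provenance or by :func:`assign_family_by_precursor`); applied to arbitrary
small RNAs it would misfire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .io import SequenceRecord, normalize_seq

MIR156 = "MIR156"
MIR529 = "MIR529"
UNKNOWN = "UNKNOWN"

#: 5'-terminal tetranucleotides diagnostic of miR156 within the superfamily.
MIR156_MOTIFS = ("UGAC", "CGAC")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA candidate (19–24 nt) with an optional family label."""

    id: str
    seq: str
    family: str = UNKNOWN

    def __post_init__(self) -> None:
        seq = normalize_seq(self.seq)
        object.__setattr__(self, "seq", seq)
        if not (19 <= len(seq) <= 24):
            raise ValueError(
                f"mature miRNA {self.id!r} length {len(seq)} outside 19–24 nt"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FamilyCall:
    family: str
    rule: str  # "motif" or "precursor_similarity"
    score: float = 0.0


@dataclass(frozen=True)
class OverlapResult:
    """Best ungapped register of sequence b against sequence a.

    ``offset`` follows the convention that position ``i`` of *a* is aligned
    with position ``i + offset`` of *b*; negative offsets slide *b*'s start
    past *a*'s start.  ``n_identical`` is the number of identical aligned
    nucleotides at that register.
    """

    offset: int
    n_identical: int


def five_prime_motif_call(mature: MatureMiRNA | str) -> FamilyCall:
    """Classify a superfamily mature by its first four nucleotides.

    UGAC/CGAC 5' ends are miR156; in all other cases the sequence is miR529.
    Total on valid input — never returns UNKNOWN.
    """
    seq = mature.seq if isinstance(mature, MatureMiRNA) else normalize_seq(mature)
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 nt has no 5' motif")
    family = MIR156 if seq.startswith(MIR156_MOTIFS) else MIR529
    return FamilyCall(family=family, rule="motif", score=0.0)


def ms_region(mature: MatureMiRNA | str) -> str:
    """Mismatch-sensitive region: 1-based positions 2–13 (12 nt)."""
    seq = mature.seq if isinstance(mature, MatureMiRNA) else normalize_seq(mature)
    if len(seq) < 13:
        raise ValueError(f"sequence of {len(seq)} nt has no complete MS region")
    return seq[1:13]


def best_overlap_identity(a: str, b: str) -> OverlapResult:
    """Maximum identical-nucleotide count over all ungapped registers.

    Ties are broken by smallest ``|offset|``, then negative before positive.
    Symmetric: swapping the arguments negates the offset and preserves the
    count.
    """
    a = normalize_seq(a)
    b = normalize_seq(b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best: tuple[int, int, int] | None = None  # (-n, |off|, off>0) for min()
    best_result: OverlapResult | None = None
    for offset in range(-(len(a) - 1), len(b)):
        # a[i] (1-based) pairs b[i + offset]; valid i range:
        lo = max(1, 1 - offset)
        hi = min(len(a), len(b) - offset)
        if hi < lo:
            continue
        n = sum(a[i - 1] == b[i + offset - 1] for i in range(lo, hi + 1))
        key = (-n, abs(offset), 0 if offset < 0 else 1)
        if best is None or key < best:
            best = key
            best_result = OverlapResult(offset=offset, n_identical=n)
    assert best_result is not None
    return best_result


def scan_for_family_window(precursor: str, query: MatureMiRNA | str) -> tuple[int, int]:
    """Best-matching window of a precursor against a mature query.

    Returns ``(start, hamming)`` where start is the 1-based position of the
    length-``len(query)`` window minimizing Hamming distance; ties go to the
    smallest start.  Hamming 0 iff the query is a substring of the precursor.
    """
    precursor = normalize_seq(precursor)
    qseq = query.seq if isinstance(query, MatureMiRNA) else normalize_seq(query)
    k = len(qseq)
    if len(precursor) < k:
        raise ValueError("precursor shorter than query")
    best_start, best_d = 1, k + 1
    for start in range(1, len(precursor) - k + 2):
        window = precursor[start - 1 : start - 1 + k]
        d = sum(x != y for x, y in zip(window, qseq))
        if d < best_d:
            best_start, best_d = start, d
    return best_start, best_d


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def precursor_similarity(candidate: str, reference: str) -> float:
    """Global alignment score (match +1, mismatch −1, gap open −2/extend −1)."""
    return float(_make_aligner().score(normalize_seq(candidate), normalize_seq(reference)))


def assign_family_by_precursor(
    candidate_precursor: str,
    refs156: Sequence[SequenceRecord],
    refs529: Sequence[SequenceRecord],
    min_score: float | None = None,
) -> FamilyCall:
    """Assign a candidate precursor to MIR156 or MIR529 by similarity.

    The candidate is aligned against every reference precursor with the
    precursor-similarity scoring (match +1, mismatch −1, gap open −2,
    extend −1) and free end gaps, so candidates and references of unequal
    extent compare on their shared core; the family of the best-scoring
    reference wins.  A best score below ``min_score`` (default 0.4 ×
    candidate length) yields UNKNOWN.  Exact score ties between the two
    families resolve to MIR156 (deterministic; genuine ties are vanishingly
    rare on real precursors).
    """
    if not refs156 or not refs529:
        raise ValueError("both reference sets must be non-empty")
    candidate = normalize_seq(candidate_precursor)
    if min_score is None:
        min_score = 0.4 * len(candidate)
    aligner = _make_aligner()
    aligner.end_deletion_score = 0.0
    aligner.end_insertion_score = 0.0
    best_family, best_score = UNKNOWN, -math.inf
    for family, refs in ((MIR156, refs156), (MIR529, refs529)):
        for ref in refs:
            score = float(aligner.score(candidate, ref.seq))
            if score > best_score:
                best_family, best_score = family, score
    if best_score < min_score:
        return FamilyCall(family=UNKNOWN, rule="precursor_similarity", score=best_score)
    return FamilyCall(family=best_family, rule="precursor_similarity", score=best_score)


def motif_frequency_matrix(matures: Iterable[MatureMiRNA | str]) -> pd.DataFrame:
    """Per-position A/C/G/U frequencies over 5'-anchored matures.

    Rows are 1-based positions; columns A, C, G, U (frequencies over the
    sequences covering that position, summing to 1), ``coverage`` (number of
    covering sequences) and ``information`` (2 − Shannon entropy, bits).
    The tabular stand-in for a sequence logo.
    """
    seqs = [m.seq if isinstance(m, MatureMiRNA) else normalize_seq(m) for m in matures]
    if not seqs:
        raise ValueError("need at least one sequence")
    length = max(len(s) for s in seqs)
    rows = []
    for pos in range(1, length + 1):
        letters = [s[pos - 1] for s in seqs if len(s) >= pos and s[pos - 1] != "N"]
        total = len(letters)
        freqs = {nt: letters.count(nt) / total if total else 0.0 for nt in "ACGU"}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        rows.append(
            {"position": pos, **freqs, "coverage": total,
             "information": 2.0 - entropy if total else 0.0}
        )
    return pd.DataFrame(rows).set_index("position")
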