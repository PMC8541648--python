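"""Homology-based discovery of miR156/miR529 loci in genomic sequence.

The pipeline mirrors the standard plant-miRNA annotation recipe: known
mature sequences are used as queries in an exhaustive mismatch scan of both
genome strands; each hit is extended by 250 bp of flanking sequence; the
excerpt is folded; and the candidate is kept only if the mature lies in the
duplex region of a proper stem-loop (hairpin).  Accepted loci are assigned
to MIR156 or MIR529 twice — by the 5'-motif rule on the mature and by
precursor similarity on the excerpt — and disagreements are flagged, which
is exactly how misannotated entries (a "miR529" whose precursor and 5' end
both look like miR156) surface.

Folding: the default backend is an internal base-pair-maximization dynamic
program (Watson–Crick + G:U pairs, minimum hairpin loop of 3 unpaired nt).
It is deterministic and exactly verifiable against exhaustive enumeration;
a thermodynamic folder (e.g. ViennaRNA's RNAfold) can be plugged in through
the ``backend`` seam where free-energy fidelity matters.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .classify import (
    FamilyCall,
    MatureMiRNA,
    assign_family_by_precursor,
    five_prime_motif_call,
)
from .io import GenomicLocus, SequenceRecord, revcomp

_ENC = {nt: i for i, nt in enumerate("ACGUN")}

#: Allowed base pairs for the internal folder: Watson–Crick plus G:U wobble.
_CAN_PAIR = np.zeros((5, 5), dtype=bool)
for x, y in (("A", "U"), ("G", "C"), ("G", "U")):
    _CAN_PAIR[_ENC[x], _ENC[y]] = True
    _CAN_PAIR[_ENC[y], _ENC[x]] = True

MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a pair


@dataclass(frozen=True)
class HomologyHit:
    locus: GenomicLocus
    query_id: str
    mismatches: int
    hit_seq: str  # mature-oriented (5'→3' of the query strand)


@dataclass(frozen=True)
class HairpinPrecursor:
    seq: str
    structure: str
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    loop_span: tuple[int, int]
    arm: str  # "5p" or "3p"
    locus: GenomicLocus | None = None


@dataclass(frozen=True)
class HairpinRejection:
    reason: str  # multiloop | low_pairing | big_bulge | in_loop


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def homology_scan(
    genome: Sequence[SequenceRecord],
    queries: Sequence[MatureMiRNA],
    max_mismatch: int = 4,
) -> list[HomologyHit]:
    """Exhaustive ungapped mismatch scan of both strands.

    Every window on either strand matching a query with ≤ ``max_mismatch``
    mismatches is reported with forward-strand coordinates; hits at the same
    locus from different queries are collapsed to the fewest-mismatch one.
    Exact by construction — queries are ≤ 24 nt, so no seeding heuristic is
    needed.
    """
    best: dict[tuple[str, int, int, str], HomologyHit] = {}
    for rec in genome:
        g = _encode(rec.seq)
        n = len(g)
        for query in queries:
            for strand in "+-":
                qseq = query.seq if strand == "+" else revcomp(query.seq)
                q = _encode(qseq)
                k = len(q)
                if n < k:
                    continue
                # mismatch count per window via summed boolean shifts
                mism = np.zeros(n - k + 1, dtype=np.int32)
                for j in range(k):
                    mism += g[j : n - k + 1 + j] != q[j]
                for pos in np.flatnonzero(mism <= max_mismatch):
                    start = int(pos) + 1
                    locus = GenomicLocus(rec.id, start, start + k - 1, strand)
                    window = rec.seq[start - 1 : start - 1 + k]
                    hit = HomologyHit(
                        locus=locus,
                        query_id=query.id,
                        mismatches=int(mism[pos]),
                        hit_seq=revcomp(window) if strand == "-" else window,
                    )
                    key = (rec.id, start, start + k - 1, strand)
                    if key not in best or hit.mismatches < best[key].mismatches:
                        best[key] = hit
    return sorted(
        best.values(),
        key=lambda h: (h.locus.seq_id, h.locus.start, h.locus.strand, h.query_id),
    )


@dataclass(frozen=True)
class FlankedHit:
    """A homology hit with flanking sequence, mature-oriented 5'→3'."""

    record: SequenceRecord
    mature_offset: int  # 1-based start of the mature within record.seq
    hit: HomologyHit
    locus: GenomicLocus | None = None  # excerpt bounds on the forward strand


def extract_flanks(
    genome: Sequence[SequenceRecord],
    hit: HomologyHit,
    flank: int = 250,
) -> FlankedHit:
    """Hit plus up to ``flank`` nt on each side, truncated at sequence ends.

    Minus-strand hits are reverse-complemented so the mature reads 5'→3'.
    """
    by_id = {rec.id: rec for rec in genome}
    rec = by_id[hit.locus.seq_id]
    left = max(1, hit.locus.start - flank)
    right = min(len(rec.seq), hit.locus.end + flank)
    excerpt = rec.seq[left - 1 : right]
    if hit.locus.strand == "-":
        excerpt = revcomp(excerpt)
        mature_offset = right - hit.locus.end + 1
    else:
        mature_offset = hit.locus.start - left + 1
    name = f"{hit.locus.seq_id}:{left}-{right}({hit.locus.strand})"
    return FlankedHit(
        record=SequenceRecord(name, excerpt, f"query={hit.query_id}"),
        mature_offset=mature_offset,
        hit=hit,
        locus=GenomicLocus(hit.locus.seq_id, left, right, hit.locus.strand),
    )


NEG = np.int32(-(10**8))
_K = np.int32(1024)  # combined score = _K * pairs + stacked adjacencies


def _maxpair_tables(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Stacking-refined maximum-pairing DP (Watson–Crick + G:U, min loop 3).

    Among all structures with the maximum number of base pairs, prefer those
    with the most stacked pair adjacencies — long helices over scattered
    isolated pairs.  Combined score = _K·pairs + stacks with _K larger than
    any possible stack count, so the pair count is exactly the Nussinov
    maximum.  Returns (F, P): F[i, j] = best combined score for seq[i..j];
    P[i, j] = best combined score with (i, j) paired (NEG if impossible).
    Computed diagonal-by-diagonal with vectorized bifurcation so that
    250-nt-flank excerpts stay tractable.
    """
    enc = np.array([_ENC[c] for c in seq], dtype=np.int8)
    n = len(enc)
    pair_ok = _CAN_PAIR[enc[:, None], enc[None, :]]
    F = np.zeros((n, n), dtype=np.int32)
    P = np.full((n, n), NEG, dtype=np.int32)
    # diagonals: xs[l][i] = X[i, i+l]
    fs: list[np.ndarray] = [np.zeros(n, dtype=np.int32)]
    ps: list[np.ndarray] = [np.full(n, NEG, dtype=np.int32)]
    os_: list[np.ndarray] = [np.zeros(n, dtype=np.int32)]
    for l in range(1, n):
        m = n - l
        others = np.maximum(fs[l - 1][1 : m + 1], fs[l - 1][:m])  # skip i or j
        for t in range(1, l - 1):
            cand = fs[t][:m] + fs[l - t - 1][t + 1 : t + 1 + m]
            np.maximum(others, cand, out=others)
        if l > MIN_LOOP:
            can = pair_ok[np.arange(m), np.arange(m) + l]
            interior = np.maximum(ps[l - 2][1 : m + 1] + 1, os_[l - 2][1 : m + 1])
            p_diag = np.where(can, _K + interior, NEG)
        else:
            p_diag = np.full(m, NEG, dtype=np.int32)
        f_diag = np.maximum(others, p_diag)
        fs.append(f_diag)
        ps.append(p_diag)
        os_.append(others)
        idx = np.arange(m)
        F[idx, idx + l] = f_diag
        P[idx, idx + l] = p_diag
    return F, P


def _nussinov_table(seq: str) -> np.ndarray:
    """Maximum-pairing counts: dp[i, j] = max pairs in seq[i..j]."""
    F, _ = _maxpair_tables(seq)
    return (F // _K).astype(np.int16)


def _traceback(seq: str, F: np.ndarray, P: np.ndarray) -> list[tuple[int, int]]:
    """Recover one stacking-preferred maximum-pairing structure."""
    pairs: list[tuple[int, int]] = []
    n = len(seq)
    stack: list[tuple[str, int, int]] = [("free", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if state == "paired":
            pairs.append((i, j))
            ii, jj = i + 1, j - 1
            if jj - ii > MIN_LOOP and P[ii, jj] > NEG and P[i, j] == _K + P[ii, jj] + 1:
                stack.append(("paired", ii, jj))
            else:
                stack.append(("free", ii, jj))
            continue
        target = F[i, j]
        if target == 0:
            continue
        if P[i, j] == target:
            stack.append(("paired", i, j))
            continue
        if target == F[i + 1, j]:
            stack.append(("free", i + 1, j))
            continue
        if target == F[i, j - 1]:
            stack.append(("free", i, j - 1))
            continue
        for k in range(i + 1, j - 1):
            if target == F[i, k] + F[k + 1, j]:
                stack.append(("free", i, k))
                stack.append(("free", k + 1, j))
                break
        else:  # pragma: no cover - DP guarantees a case above applies
            raise AssertionError("traceback failed")
    return pairs


def fold(seq: str, backend: str | Callable[[str], str] = "maxpair") -> str:
    """Predict a secondary structure as a dot-bracket string.

    ``backend="maxpair"`` (default) is the internal base-pair-maximization
    dynamic program; ``backend="rnafold"`` shells out to ViennaRNA's RNAfold
    if present on PATH; a callable receives the sequence and must return a
    dot-bracket string of equal length.
    """
    if len(seq) < 10:
        raise ValueError("sequence too short to fold (< 10 nt)")
    if callable(backend):
        structure = backend(seq)
    elif backend == "maxpair":
        F, P = _maxpair_tables(seq)
        structure_list = ["."] * len(seq)
        for i, j in _traceback(seq, F, P):
            structure_list[i] = "("
            structure_list[j] = ")"
        structure = "".join(structure_list)
    elif backend == "rnafold":
        structure = _rnafold(seq)
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    if len(structure) != len(seq):
        raise ValueError("backend returned a structure of the wrong length")
    return structure


def _rnafold(seq: str) -> str:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    return out[1].split()[0]


def pair_table(structure: str) -> dict[int, int]:
    """1-based pairing map from a dot-bracket string (both directions)."""
    stack: list[int] = []
    partner: dict[int, int] = {}
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            i = stack.pop()
            partner[i] = pos
            partner[pos] = i
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


def _smoothed_pairs(partner: dict[int, int], min_helix: int = 3) -> dict[int, int]:
    """Drop helices shorter than ``min_helix`` base pairs.

    Base-pair maximization sprinkles 1–2 bp "helices" into loop regions;
    ignoring them gives a robust read of the stem-loop topology.
    """
    opens = sorted(p for p, q in partner.items() if p < q)
    keep: dict[int, int] = {}
    used: set[int] = set()
    for p in opens:
        if p in used:
            continue
        # extend a stacked run p,q / p+1,q-1 / ...
        run = []
        i, j = p, partner[p]
        while i in partner and partner[i] == j and i < j:
            run.append((i, j))
            i, j = i + 1, j - 1
        for x, _ in run:
            used.add(x)
        if len(run) >= min_helix:
            for x, y in run:
                keep[x] = y
                keep[y] = x
    return keep


def validate_hairpin(
    seq: str,
    structure: str,
    mature_span: tuple[int, int],
    min_paired_frac: float = 0.60,
    max_bulge: int = 4,
    min_helix: int = 3,
    branch_min_bp: int = 8,
    locus: GenomicLocus | None = None,
) -> HairpinPrecursor | HairpinRejection:
    """Check that a mature sits in the duplex region of a proper hairpin.

    The check is duplex-centric: the mature's base-pairing partners must
    all lie on one side of it (a mature pairing into two different arms is
    branched, reason ``multiloop``); at least ``min_paired_frac`` of mature
    nucleotides must be paired (``low_pairing``); no run of more than
    ``max_bulge`` consecutive unpaired nucleotides may interrupt the mature
    (``big_bulge``); and walking inward from the innermost mature base pair
    must reach a single terminal loop.  During that walk, side helices
    shorter than ``branch_min_bp`` base pairs (after smoothing away helices
    of < ``min_helix`` bp) are treated as loop decoration; two or more
    substantial branches mean the mature sits above a multiloop
    (``multiloop``).  A mature overlapping the terminal loop by more than
    ``max_bulge`` nt — or lying wholly within it — is rejected
    (``in_loop``).
    On acceptance the star span is the region paired to the mature,
    extended by the conventional 2-nt 3' overhang.
    """
    if len(seq) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    m_start, m_end = mature_span
    if not (1 <= m_start <= m_end <= len(seq)):
        raise ValueError(f"mature span {mature_span} outside sequence")
    partner = pair_table(structure)
    mature_positions = range(m_start, m_end + 1)
    m_len = len(mature_positions)
    paired = [p for p in mature_positions if p in partner
              and not (m_start <= partner[p] <= m_end)]

    if not paired:
        # unpaired mature: inside a terminal loop, or just unstructured?
        enclosing = [
            (a, b) for a, b in ((a, partner[a]) for a in partner if a < partner[a])
            if a < m_start and m_end < b
        ]
        if enclosing:
            a, b = max(enclosing)  # innermost
            if not any(a < x < b for x in partner):
                return HairpinRejection("in_loop")
        return HairpinRejection("low_pairing")

    # the duplex side is the one capturing most mature pairs; a handful of
    # stray opposite-side pairs is fold noise, not branching
    right_paired = [p for p in paired if partner[p] > m_end]
    left_paired = [p for p in paired if partner[p] < m_start]
    dominant = right_paired if len(right_paired) >= len(left_paired) else left_paired
    right = dominant is right_paired

    if len(dominant) / m_len < min_paired_frac:
        reason = "multiloop" if len(paired) / m_len >= min_paired_frac else "low_pairing"
        return HairpinRejection(reason)

    # bulge check between the outermost duplex-paired mature positions;
    # unpaired mature termini are end-fraying, not bulges
    d_lo, d_hi = min(dominant), max(dominant)
    run = worst = 0
    for p in range(d_lo, d_hi + 1):
        run = 0 if p in dominant else run + 1
        worst = max(worst, run)
    if worst > max_bulge:
        return HairpinRejection("big_bulge")

    smoothed = _smoothed_pairs(partner, min_helix=min_helix)

    # a substantial helix interleaved between two partner runs of the mature
    # means the mature's stem passes over a branch point
    sorted_dom = sorted(dominant)
    for p, p2 in zip(sorted_dom, sorted_dom[1:]):
        gap_lo = min(partner[p], partner[p2])
        gap_hi = max(partner[p], partner[p2])
        interleaved = sum(
            1 for a in smoothed if gap_lo < a < smoothed[a] < gap_hi
        )
        if interleaved >= branch_min_bp:
            return HairpinRejection("multiloop")

    # walk inward from the innermost mature pair toward the terminal loop
    if right:
        inner_p = max(dominant)
        lo, hi = inner_p, partner[inner_p]
    else:
        inner_p = min(dominant)
        lo, hi = partner[inner_p], inner_p
    while True:
        inside = [(a, smoothed[a]) for a in smoothed
                  if lo < a < smoothed[a] < hi]
        maximal = [(a, b) for a, b in inside
                   if not any(x < a and b < y for x, y in inside)]

        def helix_bp(a: int, b: int) -> int:
            return sum(1 for x, y in inside if a <= x < y <= b)

        big = [(a, b) for a, b in maximal if helix_bp(a, b) >= branch_min_bp]
        if len(big) >= 2:
            return HairpinRejection("multiloop")
        if not big:
            break
        lo, hi = big[0]  # strictly shrinking: loop terminates
    loop_span = (lo + 1, hi - 1)

    # an unpaired mature terminus may poke into the terminal loop by up to
    # the bulge allowance (loop-proximal matures are common); more than
    # that, or a mature wholly inside the loop, is not a duplex mature
    overlap = max(0, min(m_end, loop_span[1]) - max(m_start, loop_span[0]) + 1)
    if overlap > max_bulge or (m_start >= loop_span[0] and m_end <= loop_span[1]):
        return HairpinRejection("in_loop")

    star_partners = [partner[p] for p in dominant]
    p_lo, p_hi = min(star_partners), max(star_partners)
    star_span = (p_lo, min(p_hi + 2, len(seq)))
    arm = "5p" if right else "3p"
    return HairpinPrecursor(
        seq=seq,
        structure=structure,
        mature_span=mature_span,
        star_span=star_span,
        loop_span=loop_span,
        arm=arm,
        locus=locus,
    )


@dataclass(frozen=True)
class LocusCall:
    precursor: HairpinPrecursor
    mature: MatureMiRNA
    mature_locus: GenomicLocus
    precursor_locus: GenomicLocus
    motif_call: FamilyCall
    precursor_call: FamilyCall
    flags: tuple[str, ...]

    @property
    def family(self) -> str:
        return self.motif_call.family


def call_loci(
    genome: Sequence[SequenceRecord],
    refs_mature: Sequence[MatureMiRNA],
    refs156_pre: Sequence[SequenceRecord],
    refs529_pre: Sequence[SequenceRecord],
    max_mismatch: int = 4,
    flank: int = 250,
    backend: str | Callable[[str], str] = "maxpair",
) -> list[LocusCall]:
    """Full discovery pipeline: scan → flanks → fold → validate → classify.

    Because the true precursor extent is unknown, each hit is evaluated at
    several nested flank sizes (``flank`` first, then 150/100/60 nt) and
    accepted at the first scale whose fold validates — a small hairpin
    buried in a long excerpt can be missed by a whole-excerpt fold but
    resolves cleanly in a tighter window.  The family of an accepted locus
    is the 5'-motif call on the hit's mature sequence, cross-checked by
    precursor similarity on the flanked excerpt; disagreement is flagged
    ``conflict`` (misannotation candidates), a 3'-arm mature is flagged
    ``3p_arm``.
    """
    if not refs_mature or not refs156_pre or not refs529_pre:
        raise ValueError("reference sets must be non-empty")
    hits = homology_scan(genome, refs_mature, max_mismatch=max_mismatch)
    scales = [flank] + [s for s in (150, 100, 60) if s < flank]
    calls: list[LocusCall] = []
    for hit in hits:
        result = None
        flanked = None
        for scale in scales:
            candidate = extract_flanks(genome, hit, flank=scale)
            structure = fold(candidate.record.seq, backend=backend)
            span = (candidate.mature_offset,
                    candidate.mature_offset + len(hit.hit_seq) - 1)
            attempt = validate_hairpin(candidate.record.seq, structure, span,
                                       locus=hit.locus)
            if isinstance(attempt, HairpinPrecursor):
                result, flanked = attempt, candidate
                break
        if result is None:
            continue
        seq = flanked.record.seq
        mature = MatureMiRNA(id=f"{hit.query_id}@{hit.locus.seq_id}:{hit.locus.start}",
                             seq=hit.hit_seq)
        motif = five_prime_motif_call(mature)
        # cross-check family on the hairpin proper (stem +/- margin), which
        # is length-comparable to reference precursors
        lo = max(1, min(result.mature_span[0], result.star_span[0]) - 40)
        hi = min(len(seq), max(result.mature_span[1], result.star_span[1]) + 40)
        pre = assign_family_by_precursor(seq[lo - 1 : hi], refs156_pre, refs529_pre)
        flags: list[str] = []
        if pre.family != "UNKNOWN" and pre.family != motif.family:
            flags.append("conflict")
        if result.arm == "3p":
            flags.append("3p_arm")
        calls.append(
            LocusCall(precursor=result, mature=mature, mature_locus=hit.locus,
                      precursor_locus=flanked.locus, motif_call=motif,
                      precursor_call=pre, flags=tuple(flags))
        )
    return calls
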