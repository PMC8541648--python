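"""Seeded synthetic-data generators with recorded ground truth.

Every downstream analysis in the toolkit can be exercised offline against
data whose truth is known by construction: genomes with planted hairpin
precursors, tissue-biased small-RNA read sets, PARE tag sets with planted
cleavage peaks, and multiple sequence alignments with planted conservation
blocks.  Generators are pure functions of their arguments plus a seed, and
each returns a truth object sufficient to score the corresponding module
without re-deriving anything.

What the generators emulate — and what they do not: backgrounds are uniform
over A/C/G/U (a ``gc_bias`` knob exists for stress tests); reads carry end
shifts but no sequencing errors; alignments are generated column-wise
independently with no indel process.  Passing tests on these fixtures
demonstrate algorithmic correctness and parameter recovery, not robustness
to the full error structure of real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import MatureMiRNA
from .express import DEFAULT_ADAPTER
from .io import AnchorAnnotation, GenomicLocus, SequenceRecord, revcomp

NUCLEOTIDES = np.array(list("ACGU"))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_rna(length: int, rng: np.random.Generator, gc_bias: float = 0.0) -> str:
    """Uniform random RNA; ``gc_bias`` in [-0.25, 0.25] shifts G/C mass."""
    p = np.array([0.25 - gc_bias / 2, 0.25 + gc_bias / 2, 0.25 + gc_bias / 2, 0.25 - gc_bias / 2])
    return "".join(rng.choice(NUCLEOTIDES, size=length, p=p / p.sum()))


@dataclass(frozen=True)
class PrecursorTruth:
    record: SequenceRecord
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    loop_span: tuple[int, int]
    family: str
    structure: str  # intended duplex structure of the construction
    seed: int


def make_precursor(
    mature: MatureMiRNA,
    family: str,
    loop_len: int = 8,
    star_mismatches: int = 2,
    flank: int = 60,
    seed: int = 0,
) -> PrecursorTruth:
    """Build a hairpin precursor around a mature on the 5p arm.

    Layout: random 5' flank + mature + loop + star + random 3' flank, where
    the star is the reverse complement of the mature with
    ``star_mismatches`` substitutions (kept ≥ 3 nt apart so mismatches stay
    isolated bulges) and the conventional 2-nt 3' overhang.  The intended
    duplex structure of the construction is recorded alongside, so hairpin
    validation can be scored without re-folding.
    """
    rng = _rng(seed)
    m = mature.seq
    n = len(m)
    star = list(revcomp(m))
    # substitution positions on the star: pairwise separation >= 3 while
    # possible (isolated bulges), then any remaining distinct positions
    positions: list[int] = []
    attempts = 0
    while len(positions) < min(star_mismatches, n) and attempts < 10_000:
        cand = int(rng.integers(0, n))
        if all(abs(cand - p) >= 3 for p in positions):
            positions.append(cand)
        attempts += 1
    if len(positions) < min(star_mismatches, n):
        pool = [i for i in range(n) if i not in positions]
        extra = rng.choice(len(pool), size=min(star_mismatches, n) - len(positions),
                           replace=False)
        positions.extend(pool[i] for i in extra)
    for pos in positions:
        current = star[pos]
        choices = [c for c in "ACGU" if c != current]
        star[pos] = choices[int(rng.integers(0, 3))]
    star_seq = "".join(star)
    loop = random_rna(loop_len, rng)
    flank5 = random_rna(flank, rng)
    flank3 = random_rna(flank, rng)
    seq = flank5 + m + loop + star_seq + flank3

    m_start = flank + 1
    m_end = flank + n
    loop_span = (m_end + 1, m_end + loop_len)
    star_start = loop_span[1] + 1
    star_span = (star_start, star_start + n - 1)

    # intended structure: mature position k pairs star position n − k + 1,
    # except at substituted star positions (0-based index -> star pos idx+1)
    struct = ["."] * len(seq)
    broken = {n - idx for idx in positions}  # 1-based mature positions unpaired
    for k in range(1, n + 1):
        if k in broken:
            continue
        struct[m_start - 1 + k - 1] = "("
        struct[star_start - 1 + (n - k)] = ")"
    truth = PrecursorTruth(
        record=SequenceRecord(f"{mature.id}_precursor", seq, f"family={family}"),
        mature_span=(m_start, m_end),
        star_span=star_span,
        loop_span=loop_span,
        family=family,
        structure="".join(struct),
        seed=seed,
    )
    return truth


def make_mir156j_like_precursor(
    mature_156: MatureMiRNA,
    mature_529: MatureMiRNA,
    n_differences: int = 3,
    seed: int = 0,
) -> tuple[SequenceRecord, int, str]:
    """Synthetic stand-in for an annotated pre-miR156 that carries an
    embedded miR529-like window just behind the mature miR156.

    Returns ``(precursor record, 1-based start of the planted window, the
    planted window sequence)``.  The window is the miR529 mature with
    ``n_differences`` substitutions.  This is a constructed object that
    mirrors the documented layout of such precursors; it is synthetic, not
    a database sequence.
    """
    rng = _rng(seed)
    planted = list(mature_529.seq)
    positions = rng.choice(len(planted), size=n_differences, replace=False)
    for pos in positions:
        choices = [c for c in "ACGU" if c != planted[pos]]
        planted[pos] = choices[int(rng.integers(0, 3))]
    window = "".join(planted)
    flank5 = random_rna(20, rng)
    linker = random_rna(4, rng)
    tail = random_rna(40, rng)
    seq = flank5 + mature_156.seq + linker + window + tail
    start = len(flank5) + len(mature_156.seq) + len(linker) + 1
    rec = SequenceRecord(
        "synthetic_pre-miR156j-like", seq,
        "synthetic precursor with embedded miR529-like window",
    )
    return rec, start, window


@dataclass(frozen=True)
class GenomeTruth:
    genome: SequenceRecord
    loci: tuple  # of (GenomicLocus of precursor, GenomicLocus of mature, family, mature seq)
    seed: int


def make_genome(
    precursors: Sequence[PrecursorTruth],
    length: int = 100_000,
    seed: int = 0,
    margin: int = 300,
) -> GenomeTruth:
    """Uniform-random genome with precursors inserted at non-overlapping
    positions on random strands; truth coordinates recorded (forward
    strand, mature locus strand-aware)."""
    rng = _rng(seed)
    background = list(random_rna(length, rng))
    taken: list[tuple[int, int]] = []
    entries = []
    for pre in precursors:
        plen = len(pre.record.seq)
        for _ in range(10_000):
            start = int(rng.integers(margin, length - plen - margin))
            if all(start + plen + margin < s or start > e + margin for s, e in taken):
                break
        else:  # pragma: no cover - genome too crowded
            raise RuntimeError("could not place all precursors without overlap")
        taken.append((start, start + plen))
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = pre.record.seq if strand == "+" else revcomp(pre.record.seq)
        background[start : start + plen] = list(inserted)
        pre_locus = GenomicLocus("chr_sim", start + 1, start + plen, strand)
        m_lo, m_hi = pre.mature_span
        if strand == "+":
            mat_locus = GenomicLocus("chr_sim", start + m_lo, start + m_hi, "+")
        else:
            mat_locus = GenomicLocus(
                "chr_sim", start + plen - m_hi + 1, start + plen - m_lo + 1, "-"
            )
        mature_seq = pre.record.seq[m_lo - 1 : m_hi]
        entries.append((pre_locus, mat_locus, pre.family, mature_seq))
    genome = SequenceRecord("chr_sim", "".join(background), "synthetic genome")
    return GenomeTruth(genome=genome, loci=tuple(entries), seed=seed)


@dataclass(frozen=True)
class ReadsTruth:
    samples: Mapping[str, tuple]  # sample -> tuple of SequenceRecord reads
    profiles: Mapping[str, Mapping[str, float]]  # sample -> miRNA -> mean RPM weight
    seed: int


def make_sra_reads(
    matures: Sequence[MatureMiRNA],
    sample_profiles: Mapping[str, Mapping[str, float]],
    depth: int = 100_000,
    shift_rate: float = 0.10,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
) -> ReadsTruth:
    """Multinomial small-RNA read sets with a planted per-sample profile.

    Each read is a mature sequence (10% carry a 1-nt trim at one end,
    exercising the assignment shift rule) with the adapter appended.
    """
    rng = _rng(seed)
    by_id = {m.id: m for m in matures}
    samples: dict[str, tuple] = {}
    for sample, profile in sample_profiles.items():
        ids = list(profile)
        weights = np.array([profile[i] for i in ids], dtype=float)
        if (weights < 0).any() or weights.sum() == 0:
            raise ValueError(f"invalid profile for sample {sample!r}")
        counts = rng.multinomial(depth, weights / weights.sum())
        reads = []
        r = 0
        for mid, count in zip(ids, counts):
            seq = by_id[mid].seq
            for _ in range(count):
                read = seq
                if rng.random() < shift_rate:
                    read = read[1:] if rng.random() < 0.5 else read[:-1]
                reads.append(SequenceRecord(f"{sample}_r{r}", read + adapter))
                r += 1
        order = rng.permutation(len(reads))
        samples[sample] = tuple(reads[i] for i in order)
    return ReadsTruth(samples=samples, profiles=sample_profiles, seed=seed)


@dataclass(frozen=True)
class PareTruth:
    tags: tuple  # of SequenceRecord
    cleavage_positions: Mapping[int, float]
    background_rate: float
    seed: int


def make_pare(
    transcript: SequenceRecord,
    cleavage_positions: Mapping[int, float],
    background_rate: float = 0.1,
    depth: int = 1000,
    tag_length: int = 20,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
) -> PareTruth:
    """PARE tag set with 5' ends planted at given positions (weighted) and a
    uniform positional background; adapter appended to every tag."""
    rng = _rng(seed)
    max_start = len(transcript.seq) - tag_length + 1
    if max_start < 1:
        raise ValueError("transcript shorter than the tag length")
    planted = [p for p in cleavage_positions if not (1 <= p <= max_start)]
    if planted:
        raise ValueError(f"cleavage positions out of range: {planted}")
    ids = list(cleavage_positions)
    weights = np.array([cleavage_positions[p] for p in ids], dtype=float)
    tags = []
    for i in range(depth):
        if rng.random() < background_rate or not ids:
            pos = int(rng.integers(1, max_start + 1))
        else:
            pos = ids[int(rng.choice(len(ids), p=weights / weights.sum()))]
        seq = transcript.seq[pos - 1 : pos - 1 + tag_length]
        tags.append(SequenceRecord(f"tag{i}", seq + adapter))
    return PareTruth(tags=tuple(tags), cleavage_positions=cleavage_positions,
                     background_rate=background_rate, seed=seed)


@dataclass(frozen=True)
class MsaTruth:
    rows: tuple  # of SequenceRecord (gapless, all equal length)
    anchors: tuple  # of AnchorAnnotation
    region_lengths: Mapping[str, int]
    conservation_spec: Mapping[str, float]
    seed: int


def make_msa(
    n_seqs: int,
    frame_spec: Mapping[str, int],
    conservation_spec: Mapping[str, float | Sequence[float]],
    seed: int = 0,
) -> MsaTruth:
    """Alignment with per-region planted conservation.

    ``frame_spec`` gives region lengths for flank5/mirna5p/loop/mirna3p/
    flank3; ``conservation_spec`` gives, per region, either one target
    modal fraction or a per-column sequence of targets.  Each column draws
    its consensus nucleotide, then every row carries the consensus with the
    target probability and a uniform other nucleotide otherwise (realized
    modal fractions track the target closely for targets ≥ ~0.4).
    """
    rng = _rng(seed)
    order = ("flank5", "mirna5p", "loop", "mirna3p", "flank3")
    col_targets: list[float] = []
    for region in order:
        length = int(frame_spec.get(region, 0))
        spec = conservation_spec[region] if region in conservation_spec else 0.25
        if isinstance(spec, (int, float)):
            col_targets.extend([float(spec)] * length)
        else:
            if len(spec) != length:
                raise ValueError(f"per-column spec for {region} has wrong length")
            col_targets.extend(float(x) for x in spec)
    ncol = len(col_targets)
    columns = np.empty((n_seqs, ncol), dtype="<U1")
    for c, target in enumerate(col_targets):
        consensus = str(rng.choice(NUCLEOTIDES))
        others = [x for x in "ACGU" if x != consensus]
        draw = rng.random(n_seqs)
        col = np.where(
            draw < target,
            consensus,
            np.array([others[i] for i in rng.integers(0, 3, size=n_seqs)]),
        )
        columns[:, c] = col
    lengths = {r: int(frame_spec.get(r, 0)) for r in order}
    p5_start = lengths["flank5"] + 1
    p5_end = p5_start + lengths["mirna5p"] - 1
    p3_start = p5_end + lengths["loop"] + 1
    p3_end = p3_start + lengths["mirna3p"] - 1
    rows = []
    anchors = []
    for i in range(n_seqs):
        rid = f"seq{i}"
        rows.append(SequenceRecord(rid, "".join(columns[i])))
        anchors.append(AnchorAnnotation(rid, p5_start, p5_end, p3_start, p3_end))
    return MsaTruth(rows=tuple(rows), anchors=tuple(anchors), region_lengths=lengths,
                    conservation_spec=dict(conservation_spec), seed=seed)
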