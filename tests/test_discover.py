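"""Discovery pipeline: scan, flanks, folding (vs exhaustive oracle), hairpin
validation, and planted-locus recovery."""

import numpy as np
import pytest

from mirtwin import classify, discover, fixtures
from mirtwin.io import GenomicLocus, SequenceRecord, revcomp

MATURE = "UGACAGAAGAGAGUGAGCAC"


def _mature(seq=MATURE, mid="q1"):
    return classify.MatureMiRNA(mid, seq)


# ------------------------------------------------------------ homology scan
def test_scan_finds_planted_query_on_both_strands():
    rng = np.random.default_rng(0)
    bg = fixtures.random_rna(2000, rng)
    genome_fwd = SequenceRecord("g", bg[:500] + MATURE + bg[500:])
    hits = discover.homology_scan([genome_fwd], [_mature()], max_mismatch=0)
    assert [(h.locus.start, h.locus.strand, h.mismatches) for h in hits] == [(501, "+", 0)]

    genome_rev = SequenceRecord("g", bg[:500] + revcomp(MATURE) + bg[500:])
    hits = discover.homology_scan([genome_rev], [_mature()], max_mismatch=0)
    assert [(h.locus.strand, h.hit_seq) for h in hits] == [("-", MATURE)]


def test_scan_respects_mismatch_budget():
    rng = np.random.default_rng(1)
    mutated = list(MATURE)
    for pos in rng.choice(len(MATURE), size=5, replace=False):
        mutated[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[pos]]
    genome = SequenceRecord("g", fixtures.random_rna(300, rng) + "".join(mutated))
    assert discover.homology_scan([genome], [_mature()], max_mismatch=4) == []
    hits = discover.homology_scan([genome], [_mature()], max_mismatch=5)
    assert any(h.mismatches == 5 for h in hits)


def test_scan_collapses_same_locus_to_best_query():
    genome = SequenceRecord("g", "GCAU" * 20 + MATURE + "AUGC" * 20)
    near = MATURE[:-1] + ("A" if MATURE[-1] != "A" else "C")
    hits = discover.homology_scan(
        [genome], [_mature(MATURE, "exact"), _mature(near, "near")], max_mismatch=4
    )
    at_locus = [h for h in hits if h.locus.start == 81]
    assert len(at_locus) == 1 and at_locus[0].query_id == "exact"


# ------------------------------------------------------------- flank excerpt
def test_flank_extraction_lengths_and_truncation():
    rng = np.random.default_rng(2)
    genome = SequenceRecord("g", fixtures.random_rna(1000, rng))
    hit = discover.HomologyHit(GenomicLocus("g", 300, 320, "+"), "q", 0,
                               genome.seq[299:320])
    fl = discover.extract_flanks([genome], hit, flank=250)
    assert len(fl.record.seq) == 521 and fl.mature_offset == 251

    near_edge = discover.HomologyHit(GenomicLocus("g", 10, 30, "+"), "q", 0,
                                     genome.seq[9:30])
    fl2 = discover.extract_flanks([genome], near_edge, flank=250)
    assert fl2.mature_offset == 10 and len(fl2.record.seq) == 30 + 250


def test_flank_extraction_minus_strand_is_reverse_complement_of_forward():
    rng = np.random.default_rng(3)
    genome = SequenceRecord("g", fixtures.random_rna(1000, rng))
    plus = discover.HomologyHit(GenomicLocus("g", 300, 320, "+"), "q", 0, "")
    minus = discover.HomologyHit(GenomicLocus("g", 300, 320, "-"), "q", 0, "")
    fplus = discover.extract_flanks([genome], plus, flank=100)
    fminus = discover.extract_flanks([genome], minus, flank=100)
    assert fminus.record.seq == revcomp(fplus.record.seq)


# ------------------------------------------------------------------- folding
def brute_max_pairs(seq: str) -> int:
    """Exhaustive enumeration of nested structures (min loop 3, WC + G:U)."""
    ok = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def rec(i: int, j: int) -> int:
        if j - i <= discover.MIN_LOOP:
            return 0
        best = rec(i + 1, j)
        for k in range(i + discover.MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in ok:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def test_fold_examples():
    assert discover.fold("GGGAAAACCC") == "(((....)))"
    assert discover.fold("AAAAAAAAAA") == "." * 10
    with pytest.raises(ValueError):
        discover.fold("ACGUACGUA")  # < 10 nt


def test_fold_pair_count_matches_exhaustive_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(10, 15))
        seq = fixtures.random_rna(n, rng)
        structure = discover.fold(seq)
        assert structure.count("(") == brute_max_pairs(seq), seq


def test_fold_pair_count_monotone_under_extension():
    rng = np.random.default_rng(7)
    seq = fixtures.random_rna(40, rng)
    prev = 0
    for n in range(10, 41, 5):
        pairs = discover.fold(seq[:n]).count("(")
        assert pairs >= prev
        prev = pairs


def test_fold_structure_is_balanced_and_well_formed():
    rng = np.random.default_rng(11)
    for _ in range(10):
        seq = fixtures.random_rna(int(rng.integers(20, 80)), rng)
        structure = discover.fold(seq)
        assert len(structure) == len(seq)
        discover.pair_table(structure)  # raises if unbalanced


def test_rnafold_backend_seam_accepts_callable():
    calls = []

    def fake_backend(seq: str) -> str:
        calls.append(seq)
        return "." * len(seq)

    assert discover.fold("ACGUACGUAC", backend=fake_backend) == "." * 10
    assert calls == ["ACGUACGUAC"]


# --------------------------------------------------------- hairpin validation
def perfect_hairpin(mature=MATURE, loop="AAAAAA"):
    seq = mature + loop + revcomp(mature)
    structure = "(" * len(mature) + "." * len(loop) + ")" * len(mature)
    return seq, structure


def test_perfect_duplex_accepted_on_5p_arm():
    seq, structure = perfect_hairpin()
    res = discover.validate_hairpin(seq, structure, (1, len(MATURE)))
    assert isinstance(res, discover.HairpinPrecursor)
    assert res.arm == "5p"
    assert res.loop_span == (len(MATURE) + 1, len(MATURE) + 6)
    assert res.star_span[0] == len(MATURE) + 7


def test_mature_on_3p_arm_recorded():
    seq, structure = perfect_hairpin()
    span = (len(MATURE) + 7, len(seq))
    res = discover.validate_hairpin(seq, structure, span)
    assert isinstance(res, discover.HairpinPrecursor) and res.arm == "3p"


def test_mature_inside_terminal_loop_rejected():
    mature = "A" * 21
    stem = "GGCGGCGGCGGC"
    seq = stem + mature + revcomp(stem)
    structure = "(" * 12 + "." * 21 + ")" * 12
    res = discover.validate_hairpin(seq, structure, (13, 33))
    assert res == discover.HairpinRejection("in_loop")


def test_low_pairing_rejected():
    # 11 of 21 mature nt paired: alternate pairing, built by construction
    t = fixtures.make_precursor(_mature("UGACAGAAGAGAGUGAGCACA"), "MIR156",
                                star_mismatches=10, seed=0)
    res = discover.validate_hairpin(t.record.seq, t.structure, t.mature_span)
    assert res == discover.HairpinRejection("low_pairing")


def test_mature_split_across_arms_rejected_as_multiloop():
    # half the mature pairs upstream, half downstream: branched placement
    half1, half2 = MATURE[:10], MATURE[10:]
    seq = revcomp(half1) + "AAAA" + half1 + half2 + "AAAA" + revcomp(half2)
    structure = "(" * 10 + "...." + ")" * 10 + "(" * 10 + "...." + ")" * 10
    res = discover.validate_hairpin(seq, structure, (15, 34))
    assert res == discover.HairpinRejection("multiloop")


def test_branch_inside_mature_stem_rejected_as_multiloop():
    # a >= 8 bp hairpin sits between the two partner runs of the mature
    half1, half2 = MATURE[:10], MATURE[10:]
    branch = "GGCGGCGGC"  # 9 bp side helix
    seq = (half1 + half2 + "AAAA" + revcomp(half2) + branch + "AAAA"
           + revcomp(branch) + revcomp(half1))
    structure = ("(" * 20 + "...." + ")" * 10 + "(" * 9 + "...." + ")" * 9
                 + ")" * 10)
    res = discover.validate_hairpin(seq, structure, (1, 20))
    assert res == discover.HairpinRejection("multiloop")


def test_big_bulge_rejected():
    mature = "UGACAGAAGAGAGUGAGCACA"  # 21 nt
    left, right = mature[:8], mature[13:]
    seq = mature + "AAAAAA" + revcomp(right) + revcomp(left)
    structure = ("(" * 8 + "." * 5 + "(" * 8 + "." * 6 + ")" * 8 + ")" * 8)
    res = discover.validate_hairpin(seq, structure, (1, 21))
    assert res == discover.HairpinRejection("big_bulge")


def test_span_out_of_range_is_an_error():
    seq, structure = perfect_hairpin()
    with pytest.raises(ValueError):
        discover.validate_hairpin(seq, structure, (0, 10))
    with pytest.raises(ValueError):
        discover.validate_hairpin(seq, structure, (1, len(seq) + 1))


# ------------------------------------------------------------ full pipeline
def _planted_genome(seed=5, n156=3, n529=2, length=30_000):
    m156 = _mature(MATURE, "ref156")
    m529 = _mature("AGAAGAGAGAGAGUACAGCUU", "ref529")
    pres = []
    for i in range(n156 + n529):
        base = m156 if i < n156 else m529
        fam = "MIR156" if i < n156 else "MIR529"
        pres.append(
            fixtures.make_precursor(
                classify.MatureMiRNA(f"p{i}", base.seq, fam), fam, seed=seed * 100 + i
            )
        )
    gt = fixtures.make_genome(pres, length=length, seed=seed)
    refs156 = [p.record for p in pres if p.family == "MIR156"][:1]
    refs529 = [p.record for p in pres if p.family == "MIR529"][:1]
    return gt, m156, m529, refs156, refs529


def test_pipeline_recovers_planted_loci_with_exact_coordinates():
    gt, m156, m529, r156, r529 = _planted_genome()
    calls = discover.call_loci([gt.genome], [m156, m529], r156, r529)
    truth = {(mat.start, mat.end, mat.strand): fam for _, mat, fam, _ in gt.loci}
    found = {
        (c.mature_locus.start, c.mature_locus.end, c.mature_locus.strand): c.family
        for c in calls
    }
    for key, fam in truth.items():
        assert key in found, f"planted locus {key} not recovered"
        assert found[key] == fam


def test_pipeline_flags_motif_precursor_conflict():
    # a mature starting UGAC planted inside a MIR529-like precursor context
    conflict_mature = classify.MatureMiRNA("x", "UGAC" + "AGAGAGAGUACAGCUU", "UNKNOWN")
    t = fixtures.make_precursor(conflict_mature, "MIR529", seed=3)
    genome = fixtures.make_genome([t], length=5000, seed=3)
    r529 = [t.record]
    r156 = [fixtures.make_precursor(
        classify.MatureMiRNA("y", MATURE, "MIR156"), "MIR156", seed=9).record]
    calls = discover.call_loci([genome.genome], [conflict_mature], r156, r529)
    assert calls and any("conflict" in c.flags for c in calls)
    flagged = next(c for c in calls if "conflict" in c.flags)
    assert flagged.motif_call.family == "MIR156"
    assert flagged.precursor_call.family == "MIR529"


def test_pipeline_pure_random_genome_yields_no_loci():
    rng = np.random.default_rng(12)
    genome = SequenceRecord("g", fixtures.random_rna(50_000, rng))
    _, m156, m529, r156, r529 = _planted_genome(seed=8, length=5000)
    calls = discover.call_loci([genome], [m156, m529], r156, r529)
    assert calls == []


def test_pipeline_strand_flip_invariance():
    gt, m156, m529, r156, r529 = _planted_genome(seed=6, length=20_000)
    flipped = SequenceRecord(gt.genome.id, revcomp(gt.genome.seq))
    calls = discover.call_loci([gt.genome], [m156, m529], r156, r529)
    calls_flip = discover.call_loci([flipped], [m156, m529], r156, r529)
    n = len(gt.genome.seq)

    def normalize(call_set, flip):
        out = set()
        for c in call_set:
            lo, hi, strand = (c.mature_locus.start, c.mature_locus.end,
                              c.mature_locus.strand)
            if flip:
                lo, hi = n - hi + 1, n - lo + 1
                strand = "+" if strand == "-" else "-"
            out.add((lo, hi, strand))
        return out

    assert normalize(calls, False) == normalize(calls_flip, True)
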