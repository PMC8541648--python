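"""PARE target finding, cleavage categories, permutation significance."""

import random
from statistics import median

import numpy as np
import pytest

from mirtwin import degradome, express, fixtures
from mirtwin.classify import MatureMiRNA
from mirtwin.io import SequenceRecord, revcomp

MIR156 = "UGACAGAAGAGAGUGAGCAC"
MIR529 = "AGAAGAGAGAGAGUACAGCUU"


def _m(seq=MIR156, mid="m156"):
    return MatureMiRNA(mid, seq)


def _transcript_with_site(mirna_seq=MIR156, pos=400, length=800, seed=2):
    rng = np.random.default_rng(seed)
    bg = fixtures.random_rna(length, rng)
    site = revcomp(mirna_seq)
    seq = bg[: pos - 1] + site + bg[pos - 1 + len(site):]
    return SequenceRecord("tx", seq)


# ------------------------------------------------------------------ find_sites
def test_perfect_site_zero_mismatch_and_cleavage_position():
    tx = _transcript_with_site(pos=401)
    sites = degradome.find_sites(_m(), tx)
    perfect = [s for s in sites if s.total_mismatch == 0]
    assert len(perfect) == 1
    site = perfect[0]
    assert site.span == (401, 420)
    # miRNA position 10 pairs the transcript nt at span_start + L - 10
    assert site.cleavage_pos == 401 + len(MIR156) - 10


def test_three_mismatches_in_seed_region_rejected():
    tx_seq = revcomp(MIR156)
    window = list(tx_seq)
    L = len(MIR156)
    for k in (2, 3, 4):  # miRNA positions 2,3,4 pair window index L-k
        i = L - k
        window[i] = {"A": "C", "C": "A", "G": "U", "U": "G"}[window[i]]
    tx = SequenceRecord("t", "GGGG" + "".join(window) + "CCCC")
    sites = degradome.find_sites(_m(), tx)
    assert all(s.mismatch5 < 3 for s in sites)
    assert not any(s.span == (5, 4 + L) for s in sites)


def test_five_mismatches_in_three_prime_region_accepted():
    tx_seq = revcomp(MIR156)
    window = list(tx_seq)
    L = len(MIR156)
    for k in (12, 13, 14, 15, 16):
        i = L - k
        window[i] = {"A": "C", "C": "A", "G": "U", "U": "G"}[window[i]]
    tx = SequenceRecord("t", "GGGG" + "".join(window) + "CCCC")
    sites = degradome.find_sites(_m(), tx)
    hit = [s for s in sites if s.span == (5, 4 + L)]
    assert len(hit) == 1
    assert hit[0].mismatch3 == 5.0 and hit[0].mismatch5 == 0.0


def test_gu_wobble_scores_half():
    # miRNA G opposite transcript U is half a mismatch
    mirna = _m("G" * 6 + "AAAAA" + "GGGGGGGGG", "gu")  # 20 nt
    # perfect complement then mutate the nt paired to miRNA position 1 (G->U)
    window = list(revcomp(mirna.seq))
    window[-1] = "U"  # pairs miRNA position 1
    tx = SequenceRecord("t", "AAAA" + "".join(window) + "AAAA")
    sites = degradome.find_sites(mirna, tx)
    s = next(s for s in sites if s.span == (5, 24))
    assert s.mismatch5 == pytest.approx(0.5)


def test_threshold_monotonicity_superset():
    tx = _transcript_with_site(seed=9)
    wide = degradome.find_sites(_m(), tx)
    spans_wide = {s.span for s in wide}
    narrow = [s for s in wide if s.mismatch5 < 1 and s.mismatch3 < 1]
    assert {s.span for s in narrow} <= spans_wide


# ------------------------------------------------------------ cleavage offset
def test_cleavage_offset_identity_and_antisymmetry():
    assert degradome.cleavage_offset(MIR156, MIR156) == 0
    a, b = MIR156, MIR529
    assert degradome.cleavage_offset(a, b) == -degradome.cleavage_offset(b, a)


def test_cleavage_offset_constructed_register():
    a = MIR156 + "A"  # 21 nt
    b = a[4:] + "GCAU"  # trim 4 from 5', append 4 at 3'
    assert abs(degradome.cleavage_offset(a, b)) == 4


def test_mir156_mir529_cleavage_sites_4nt_apart():
    assert abs(degradome.cleavage_offset(MIR156, MIR529)) == 4


# -------------------------------------------------------------- pare profile
def test_profile_counts_at_five_prime_position():
    tx = _transcript_with_site(seed=4)
    tag = tx.seq[99:119]
    profile = degradome.pare_profile([tag] * 10, tx)
    assert profile.count_at(100) == pytest.approx(10.0)
    assert profile.total_tags == 10


def test_unmapped_tag_excluded_but_counted_in_total():
    tx = SequenceRecord("t", "ACGU" * 30)
    profile = degradome.pare_profile(["GGGGGGGGGGGGGGGGGGGG"], tx)
    assert sum(profile.counts.values()) == 0.0 and profile.total_tags == 1


def test_multi_position_tag_split_equally():
    tx = SequenceRecord("t", "AAGGCCUUAAGGCCUU" + "CGCGCGCG")
    tag = "AAGGCCUU"
    profile = degradome.pare_profile([tag], tx)
    assert profile.count_at(1) == pytest.approx(0.5)
    assert profile.count_at(9) == pytest.approx(0.5)


# --------------------------------------------------------------- categorize
def _site(cleavage_pos, transcript_id="t"):
    return degradome.TargetSite(transcript_id, (1, 20), "m", 0, 0, cleavage_pos)


def _profile(counts, transcript_id="t"):
    return degradome.DegradomeProfile(transcript_id, counts, int(sum(counts.values())))


def test_category_ladder_examples():
    peak = _profile({50: 50.0, 10: 2.0, 20: 1.0})
    assert degradome.categorize(_site(50), peak) == 0
    tied = _profile({50: 30.0, 80: 30.0, 10: 2.0})
    assert degradome.categorize(_site(50), tied) == 1
    single = _profile({50: 1.0})
    assert degradome.categorize(_site(50), single) == 4
    above_median = _profile({50: 5.0, 10: 9.0, 20: 1.0, 30: 1.0, 40: 1.0})
    assert degradome.categorize(_site(50), above_median) == 2
    at_or_below = _profile({50: 2.0, 10: 9.0, 20: 8.0, 30: 7.0, 40: 2.0})
    assert degradome.categorize(_site(50), at_or_below) == 3
    assert degradome.categorize(_site(999), peak) == 4  # no signal at site


def brute_categorize(site, profile):
    window = [profile.count_at(p) for p in
              range(site.cleavage_pos - 1, site.cleavage_pos + 2)]
    c = max(window) if window else 0.0
    if c <= 1.0:
        return 4
    positives = [v for v in profile.counts.values() if v > 0]
    m = max(positives)
    if c == m:
        return 0 if sum(1 for v in positives if v == m) == 1 else 1
    return 2 if c > median(positives) else 3


def test_categorize_agrees_with_brute_force_on_random_profiles():
    rng = random.Random(0)
    for _ in range(1000):
        n_pos = rng.randint(1, 12)
        counts = {rng.randint(1, 60): float(rng.choice([1, 1, 2, 3, 5, 10, 40]))
                  for _ in range(n_pos)}
        profile = _profile(counts)
        pos = rng.randint(1, 60)
        assert degradome.categorize(_site(pos), profile) == brute_categorize(
            _site(pos), profile)


# ----------------------------------------------------------------- p-values
def test_perfect_site_with_peak_is_significant():
    tx = _transcript_with_site(pos=401, seed=5)
    site = next(s for s in degradome.find_sites(_m(), tx) if s.total_mismatch == 0)
    pare = fixtures.make_pare(tx, {site.cleavage_pos: 1.0},
                              background_rate=0.1, depth=300, seed=6)
    tags = [t.seq for t in (express.trim_adapter(r.seq) for r in pare.tags) if t.seq]
    profile = degradome.pare_profile(tags, tx)
    p = degradome.site_pvalue(_m(), tx, site, profile, n_shuffles=1000, seed=1)
    assert p <= 0.05


def test_pvalue_degenerate_cases():
    tx = _transcript_with_site(seed=7)
    site = next(s for s in degradome.find_sites(_m(), tx) if s.total_mismatch == 0)
    empty = degradome.DegradomeProfile("tx", {}, 0)
    assert degradome.site_pvalue(_m(), tx, site, empty, n_shuffles=1000, seed=1) == 1.0
    some = degradome.DegradomeProfile("tx", {site.cleavage_pos: 5.0}, 5)
    assert degradome.site_pvalue(_m(), tx, site, some, n_shuffles=0, seed=1) == 1.0


def test_pvalue_deterministic_given_seed():
    tx = _transcript_with_site(seed=8)
    site = next(s for s in degradome.find_sites(_m(), tx) if s.total_mismatch == 0)
    profile = degradome.DegradomeProfile("tx", {site.cleavage_pos: 5.0, 10: 1.0}, 6)
    p1 = degradome.site_pvalue(_m(), tx, site, profile, n_shuffles=200, seed=9)
    p2 = degradome.site_pvalue(_m(), tx, site, profile, n_shuffles=200, seed=9)
    assert p1 == p2


def test_dinucleotide_shuffle_preserves_composition():
    rng = random.Random(3)
    seq = MIR156
    for _ in range(20):
        shuffled = degradome.dinucleotide_shuffle(seq, rng)
        assert sorted(shuffled) == sorted(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]
        pairs = sorted(shuffled[i : i + 2] for i in range(len(shuffled) - 1))
        assert pairs == sorted(seq[i : i + 2] for i in range(len(seq) - 1))


def test_shuffled_tag_positions_destroy_the_call():
    tx = _transcript_with_site(pos=401, seed=10)
    site = next(s for s in degradome.find_sites(_m(), tx) if s.total_mismatch == 0)
    # all signal far from the cleavage site, no peak at the site
    profile = degradome.DegradomeProfile("tx", {50: 3.0, 700: 2.0}, 5)
    assert degradome.categorize(site, profile) == 4


# -------------------------------------------------------------- t-plot table
def test_tplot_two_mirnas_cleaving_4nt_apart(tmp_path):
    rng = np.random.default_rng(11)
    bg = fixtures.random_rna(600, rng)
    # one shared target region complementary to miR156; miR529 binds the
    # overlapping register so its cleavage site is offset by 4
    seq = bg[:300] + revcomp(MIR156) + bg[300 + len(MIR156):]
    tx = SequenceRecord("spl", seq)
    s156 = next(s for s in degradome.find_sites(_m(), tx) if s.total_mismatch == 0)
    sites529 = degradome.find_sites(_m(MIR529, "m529"), tx)
    assert sites529, "miR529 should find the overlapping SPL-like site"
    s529 = min(sites529, key=lambda s: s.total_mismatch)
    assert abs(s156.cleavage_pos - s529.cleavage_pos) == 4
    pare = fixtures.make_pare(
        tx, {s156.cleavage_pos: 2.0, s529.cleavage_pos: 1.0},
        background_rate=0.05, depth=400, seed=12)
    tags = [t.seq for t in (express.trim_adapter(r.seq) for r in pare.tags) if t.seq]
    profile = degradome.pare_profile(tags, tx)
    calls = [
        degradome.CleavageCall(s156, degradome.categorize(s156, profile), 0.001,
                               profile.count_at(s156.cleavage_pos)),
        degradome.CleavageCall(s529, degradome.categorize(s529, profile), 0.001,
                               profile.count_at(s529.cleavage_pos)),
    ]
    path = tmp_path / "tplot.tsv"
    degradome.tplot_table(profile, calls, path, transcript_length=len(tx.seq))
    lines = path.read_text().splitlines()
    call_rows = [ln.split("\t") for ln in lines if ln.startswith("call\t")]
    assert len(call_rows) == 2
    positions = sorted(int(r[2]) for r in call_rows)
    assert positions[1] - positions[0] == 4
    n_pos_rows = sum(1 for ln in lines if ln.startswith("position\t"))
    assert n_pos_rows == len(tx.seq)


def test_tplot_empty_calls_positions_only(tmp_path):
    profile = degradome.DegradomeProfile("t", {3: 2.0}, 2)
    path = tmp_path / "t.tsv"
    degradome.tplot_table(profile, [], path, transcript_length=5)
    lines = path.read_text().splitlines()
    assert not any(ln.startswith("call\t") for ln in lines)
    assert sum(1 for ln in lines if ln.startswith("position\t")) == 5
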