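"""Degradome (PARE) analysis: target sites, cleavage calls, T-plot tables.

PARE (parallel analysis of RNA ends) sequencing captures the 5' ends of
uncapped cleavage products; a pile-up of tag 5' ends on a transcript marks
a miRNA-guided cleavage site.  This module

* finds candidate target sites by ungapped antisense complementarity, with
  G:U wobble scored as half a mismatch and the limits < 3 weighted
  mismatches opposite miRNA positions 1–10 and < 6 opposite positions
  11–end;
* records the expected cleavage position as the transcript nucleotide
  paired to miRNA position 10 (slicing occurs across the 10/11 bond);
* builds per-transcript tag profiles, assigns CleaveLand-style cleavage
  categories 0–4, and attaches a permutation p-value from
  dinucleotide-preserving shuffles of the miRNA;
* emits the machine-readable T-plot (per-position tag counts plus calls).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from .classify import MatureMiRNA, best_overlap_identity
from .io import SequenceRecord, normalize_seq

#: Watson–Crick complements (miRNA nt → transcript nt), for mismatch weights.
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: G:U wobble pairs (miRNA nt, transcript nt), half-mismatch weight.
_WOBBLE = {("G", "U"), ("U", "G")}

MAX_MISMATCH_5 = 3.0  # strict upper bound, miRNA positions 1–10
MAX_MISMATCH_3 = 6.0  # strict upper bound, miRNA positions 11–end
CLEAVAGE_JITTER = 1  # ± nt tolerance when reading PARE profiles


def pair_weight(mirna_nt: str, transcript_nt: str) -> float:
    """0 for Watson–Crick, 0.5 for G:U wobble, 1 otherwise."""
    if _WC.get(mirna_nt) == transcript_nt:
        return 0.0
    if (mirna_nt, transcript_nt) in _WOBBLE:
        return 0.5
    return 1.0


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    span: tuple[int, int]  # 1-based closed interval on the transcript
    mirna_id: str
    mismatch5: float
    mismatch3: float
    cleavage_pos: int  # transcript position paired to miRNA position 10

    @property
    def total_mismatch(self) -> float:
        return self.mismatch5 + self.mismatch3


def _site_mismatches(mirna: str, window: str) -> tuple[float, float]:
    """Weighted mismatches of an antisense register, split at position 10.

    miRNA position k (5'→3') pairs the window position ``len − k + 1``
    (the window read 5'→3' on the transcript).
    """
    n = len(mirna)
    m5 = m3 = 0.0
    for k in range(1, n + 1):
        w = pair_weight(mirna[k - 1], window[n - k])
        if k <= 10:
            m5 += w
        else:
            m3 += w
    return m5, m3


def find_sites(mirna: MatureMiRNA, transcript: SequenceRecord) -> list[TargetSite]:
    """All ungapped antisense windows within the complementarity limits.

    Sites are sorted by total weighted mismatch (ties by position).
    """
    mseq = mirna.seq
    tseq = transcript.seq
    n = len(mseq)
    if len(tseq) < n:
        raise ValueError("transcript shorter than miRNA")
    sites: list[TargetSite] = []
    for start in range(1, len(tseq) - n + 2):
        window = tseq[start - 1 : start - 1 + n]
        m5, m3 = _site_mismatches(mseq, window)
        if m5 < MAX_MISMATCH_5 and m3 < MAX_MISMATCH_3:
            # miRNA position 10 pairs window position n − 10 + 1
            cleavage = start + (n - 10)
            sites.append(
                TargetSite(
                    transcript_id=transcript.id,
                    span=(start, start + n - 1),
                    mirna_id=mirna.id,
                    mismatch5=m5,
                    mismatch3=m3,
                    cleavage_pos=cleavage,
                )
            )
    return sorted(sites, key=lambda s: (s.total_mismatch, s.span[0]))


def cleavage_offset(mirna_a: MatureMiRNA | str, mirna_b: MatureMiRNA | str) -> int:
    """Signed difference of the two miRNAs' cleavage positions on a common
    target, equal to their 5'-end offset at the best mutual register.

    Antisymmetric: ``cleavage_offset(a, b) == -cleavage_offset(b, a)``.
    For the miR156/miR529 pair the magnitude is 4: miR529 slices its shared
    SPL target sites 4 nt away from the miR156 site.
    """
    a = mirna_a.seq if isinstance(mirna_a, MatureMiRNA) else normalize_seq(mirna_a)
    b = mirna_b.seq if isinstance(mirna_b, MatureMiRNA) else normalize_seq(mirna_b)
    return best_overlap_identity(a, b).offset


@dataclass(frozen=True)
class DegradomeProfile:
    transcript_id: str
    counts: Mapping[int, float]  # 1-based 5'-end position → tag count
    total_tags: int

    def count_at(self, pos: int) -> float:
        return float(self.counts.get(pos, 0.0))


def pare_profile(tags: Sequence[str | SequenceRecord], transcript: SequenceRecord) -> DegradomeProfile:
    """Map adapter-trimmed PARE tags to a transcript by exact full-length
    sense match; counts attach to the tag's 5'-end position, multi-position
    tags split equally."""
    counts: dict[int, float] = {}
    tseq = transcript.seq
    for tag in tags:
        seq = tag.seq if isinstance(tag, SequenceRecord) else normalize_seq(tag)
        if not seq:
            continue
        positions = []
        idx = tseq.find(seq)
        while idx >= 0:
            positions.append(idx + 1)
            idx = tseq.find(seq, idx + 1)
        if positions:
            w = 1.0 / len(positions)
            for pos in positions:
                counts[pos] = counts.get(pos, 0.0) + w
    return DegradomeProfile(transcript_id=transcript.id, counts=counts, total_tags=len(tags))


@dataclass(frozen=True)
class CleavageCall:
    site: TargetSite
    category: int
    p_value: float
    site_count: float


def categorize(site: TargetSite, profile: DegradomeProfile) -> int:
    """CleaveLand-style cleavage category ladder.

    With c = tag count at the cleavage position (max over a ±1 nt window,
    because PARE 5' ends jitter by one nucleotide), M = transcript-wide
    maximum and med = median of positive positions:
    category 4 if c ≤ 1; 0 if c equals a uniquely attained M; 1 if c = M
    attained more than once; 2 if c > med; else 3.
    """
    window = [
        profile.count_at(p)
        for p in range(site.cleavage_pos - CLEAVAGE_JITTER, site.cleavage_pos + CLEAVAGE_JITTER + 1)
    ]
    c = max(window) if window else 0.0
    if c <= 1.0:
        return 4
    positives = [v for v in profile.counts.values() if v > 0]
    m = max(positives)
    if c == m:
        return 0 if sum(1 for v in positives if v == m) == 1 else 1
    return 2 if c > median(positives) else 3


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    dinucleotide multigraph, Altschul–Erickson style)."""
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(200):  # retry until a full Eulerian walk is found
        trial = {k: v[:] for k, v in edges.items()}
        for v in trial.values():
            rng.shuffle(v)
        path = [seq[0]]
        node = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            succ = trial.get(node)
            if not succ:
                ok = False
                break
            node = succ.pop()
            path.append(node)
        if ok:
            return "".join(path)
    return seq  # pathological composition; fall back to identity


def _mismatch_scan(mirna: str, transcript: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (mismatch5, mismatch3) for every antisense window start."""
    n = len(mirna)
    t = transcript
    nwin = len(t) - n + 1
    m5 = np.zeros(nwin)
    m3 = np.zeros(nwin)
    for k in range(1, n + 1):
        col = t[n - k : n - k + nwin]
        nt = mirna[k - 1]
        w = np.ones(nwin)
        w[col == ord(_WC.get(nt, "N"))] = 0.0
        if nt == "G":
            w[col == ord("U")] = np.minimum(w[col == ord("U")], 0.5)
        elif nt == "U":
            w[col == ord("G")] = np.minimum(w[col == ord("G")], 0.5)
        if k <= 10:
            m5 += w
        else:
            m3 += w
    return m5, m3


def site_pvalue(
    mirna: MatureMiRNA,
    transcript: SequenceRecord,
    site: TargetSite,
    profile: DegradomeProfile,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value from dinucleotide-preserving miRNA shuffles.

    p = (1 + k) / (1 + n) where k counts shuffles that achieve, anywhere on
    the transcript with PARE signal at the implied cleavage position, a site
    within the complementarity limits whose total weighted mismatch is ≤ the
    observed site's.  Returns 1.0 when the transcript carries no signal or
    ``n_shuffles`` is 0.
    """
    if n_shuffles <= 0:
        return 1.0
    has_signal = [p for p, v in profile.counts.items() if v > 0]
    if not has_signal:
        return 1.0
    rng = random.Random(seed)
    t = np.frombuffer(transcript.seq.encode("ascii"), dtype=np.uint8)
    n = len(mirna.seq)
    nwin = len(t) - n + 1
    if nwin <= 0:
        return 1.0
    # windows whose implied cleavage position carries signal
    starts = np.arange(1, nwin + 1)
    cleavage = starts + (n - 10)
    signal_mask = np.isin(cleavage, has_signal)
    observed = site.total_mismatch
    k_better = 0
    for _ in range(n_shuffles):
        shuffled = dinucleotide_shuffle(mirna.seq, rng)
        m5, m3 = _mismatch_scan(shuffled, t)
        ok = (m5 < MAX_MISMATCH_5) & (m3 < MAX_MISMATCH_3) & signal_mask
        if np.any(ok & ((m5 + m3) <= observed)):
            k_better += 1
    return (1 + k_better) / (1 + n_shuffles)


def call_cleavage(
    mirna: MatureMiRNA,
    transcript: SequenceRecord,
    tags: Sequence[str | SequenceRecord],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[CleavageCall]:
    """End-to-end: sites → profile → category → permutation p-value."""
    profile = pare_profile(tags, transcript)
    calls = []
    for site in find_sites(mirna, transcript):
        category = categorize(site, profile)
        p = site_pvalue(mirna, transcript, site, profile, n_shuffles=n_shuffles, seed=seed)
        window = [
            profile.count_at(q)
            for q in range(site.cleavage_pos - CLEAVAGE_JITTER, site.cleavage_pos + CLEAVAGE_JITTER + 1)
        ]
        calls.append(CleavageCall(site=site, category=category, p_value=p,
                                  site_count=max(window)))
    return calls


def tplot_table(
    profile: DegradomeProfile,
    calls: Sequence[CleavageCall],
    path: str | Path,
    transcript_length: int | None = None,
) -> None:
    """Machine-readable T-plot: per-position tag counts plus call rows."""
    length = transcript_length or (max(profile.counts) if profile.counts else 0)
    with open(path, "wt", encoding="utf-8") as out:
        out.write("record\ttranscript\tposition\tcount\tmirna\tcategory\tp_value\n")
        for pos in range(1, length + 1):
            out.write(
                f"position\t{profile.transcript_id}\t{pos}\t{profile.count_at(pos):.6g}\t.\t.\t.\n"
            )
        for call in calls:
            out.write(
                f"call\t{call.site.transcript_id}\t{call.site.cleavage_pos}\t"
                f"{call.site_count:.6g}\t{call.site.mirna_id}\t{call.category}\t"
                f"{call.p_value:.6g}\n"
            )
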