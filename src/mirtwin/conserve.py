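"""Precursor conservation profiling in the 40bp-5p/loop/3p-40bp frame.

Alignments of miRNA precursor regions (40 nt of upstream flank, the
miRNA-5p arm, the loop, the miRNA-3p arm, 40 nt of downstream flank) are
reduced to a per-position conservation profile.  Conservation at a column
is the fraction of rows carrying the modal non-gap nucleotide (gaps count
in the denominator), banded into four classes: <20%, 20–40%, 40–70% and
>70%.  Runs of high-conservation positions ("conserved blocks") are the
quantitative counterpart of the qualitative contrast between the two twin
families: miR156 precursors are conserved mainly inside the hairpin
(5p/loop/3p), miR529 precursors carry additional conserved blocks in the
flanks just outside the hairpin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import AnchorAnnotation, SequenceRecord

REGIONS = ("flank5", "mirna5p", "loop", "mirna3p", "flank3")
BANDS = ("lt20", "lt40", "b40_70", "gt70")
_BAND_RANK = {b: i for i, b in enumerate(BANDS)}


def band_of(conservation: float) -> str:
    """Band label for a conservation fraction.

    The four classes partition [0, 1]: <0.20 → lt20; [0.20, 0.40) → lt40;
    [0.40, 0.70] → b40_70; >0.70 → gt70.
    """
    if not (0.0 <= conservation <= 1.0):
        raise ValueError(f"conservation {conservation} outside [0, 1]")
    if conservation < 0.20:
        return "lt20"
    if conservation < 0.40:
        return "lt40"
    if conservation <= 0.70:
        return "b40_70"
    return "gt70"


@dataclass(frozen=True)
class FrameColumn:
    column: int  # 1-based alignment column
    region: str
    frame_pos: int  # negative in flank5 (−flank..−1), 1-based elsewhere


@dataclass(frozen=True)
class ConservationProfile:
    columns: tuple  # of (region, frame_pos, conservation, band)
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.columns), columns=["region", "frame_pos", "conservation", "band"]
        )


def _row_frame_map(anchor: AnchorAnnotation, length: int, flank: int) -> dict[int, tuple[str, int]]:
    """Map ungapped 1-based positions of one row to (region, frame_pos)."""
    if anchor.p3_end > length:
        raise ValueError(f"anchor {anchor.seq_id} outside row of length {length}")
    mapping: dict[int, tuple[str, int]] = {}
    for pos in range(max(1, anchor.p5_start - flank), anchor.p5_start):
        mapping[pos] = ("flank5", pos - anchor.p5_start)  # −flank .. −1
    for pos in range(anchor.p5_start, anchor.p5_end + 1):
        mapping[pos] = ("mirna5p", pos - anchor.p5_start + 1)
    for pos in range(anchor.p5_end + 1, anchor.p3_start):
        mapping[pos] = ("loop", pos - anchor.p5_end)
    for pos in range(anchor.p3_start, anchor.p3_end + 1):
        mapping[pos] = ("mirna3p", pos - anchor.p3_start + 1)
    for pos in range(anchor.p3_end + 1, min(length, anchor.p3_end + flank) + 1):
        mapping[pos] = ("flank3", pos - anchor.p3_end)
    return mapping


def frame_alignment(
    alignment: Sequence[SequenceRecord],
    anchors: Sequence[AnchorAnnotation],
    flank: int = 40,
) -> list[FrameColumn]:
    """Label alignment columns with the frame region/position of the
    majority of their non-gap residues.

    Columns with > 50% gaps, or whose residues all fall outside the frame,
    are dropped.  Majority ties resolve by region order then smallest
    frame position.
    """
    by_id = {a.seq_id: a for a in anchors}
    missing = [r.id for r in alignment if r.id not in by_id]
    if missing:
        raise ValueError(f"rows without anchors: {missing}")
    row_maps = []
    for rec in alignment:
        ungapped_len = sum(1 for c in rec.seq if c != "-")
        row_maps.append(_row_frame_map(by_id[rec.id], ungapped_len, flank))
    ncol = len(alignment[0].seq)
    nrows = len(alignment)
    counters = [0] * nrows  # ungapped position per row
    out: list[FrameColumn] = []
    for col in range(1, ncol + 1):
        labels: list[tuple[str, int]] = []
        gaps = 0
        for r, rec in enumerate(alignment):
            ch = rec.seq[col - 1]
            if ch == "-":
                gaps += 1
                continue
            counters[r] += 1
            label = row_maps[r].get(counters[r])
            if label is not None:
                labels.append(label)
        if gaps > nrows / 2 or not labels:
            continue
        votes = Counter(labels)
        top = max(votes.values())
        winner = min(
            (lab for lab, v in votes.items() if v == top),
            key=lambda lab: (REGIONS.index(lab[0]), lab[1]),
        )
        out.append(FrameColumn(column=col, region=winner[0], frame_pos=winner[1]))
    return out


def conservation_profile(
    alignment: Sequence[SequenceRecord],
    frame_map: Sequence[FrameColumn],
) -> ConservationProfile:
    """Modal-residue conservation per retained column, banded.

    Conservation = count of the modal non-gap nucleotide / total rows
    (gaps count in the denominator).  Order-invariant in the rows.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned rows")
    nrows = len(alignment)
    cols = []
    for fc in frame_map:
        residues = [rec.seq[fc.column - 1] for rec in alignment if rec.seq[fc.column - 1] != "-"]
        modal = Counter(residues).most_common(1)[0][1] if residues else 0
        cons = modal / nrows
        cols.append((fc.region, fc.frame_pos, cons, band_of(cons)))
    return ConservationProfile(columns=tuple(cols), n_sequences=nrows)


@dataclass(frozen=True)
class ConservedBlock:
    region: str
    start_pos: int  # frame coordinates
    end_pos: int
    length: int
    min_conservation: float

    def label(self) -> str:
        return f"{self.region}[{self.start_pos}..{self.end_pos}]"


def conserved_blocks(
    profile: ConservationProfile,
    min_conservation_band: str = "gt70",
    min_run: int = 5,
    contiguity: str = "frame",
) -> list[ConservedBlock]:
    """Maximal runs of ≥ ``min_run`` positions at or above a band.

    ``contiguity="frame"`` requires consecutive frame positions (dropped
    gap-heavy columns break runs); ``contiguity="retained"`` only requires
    adjacency among retained profile columns.  Runs never cross frame-region
    boundaries.
    """
    if min_conservation_band not in _BAND_RANK:
        raise ValueError(f"unknown band {min_conservation_band!r}")
    if contiguity not in ("frame", "retained"):
        raise ValueError("contiguity must be 'frame' or 'retained'")
    threshold = _BAND_RANK[min_conservation_band]
    blocks: list[ConservedBlock] = []
    run: list[tuple[str, int, float]] = []

    def flush() -> None:
        if len(run) >= min_run:
            blocks.append(
                ConservedBlock(
                    region=run[0][0],
                    start_pos=run[0][1],
                    end_pos=run[-1][1],
                    length=len(run),
                    min_conservation=min(x[2] for x in run),
                )
            )
        run.clear()

    for region, pos, cons, band in profile.columns:
        qualifies = _BAND_RANK[band] >= threshold
        contiguous = bool(run) and run[-1][0] == region and (
            contiguity == "retained" or pos == run[-1][1] + 1
        )
        if qualifies and (not run or contiguous):
            run.append((region, pos, cons))
        else:
            flush()
            if qualifies:
                run.append((region, pos, cons))
    flush()
    return blocks


def profile_report(
    profile: ConservationProfile,
    blocks: Sequence[ConservedBlock],
    path: str | Path,
) -> None:
    """Write the profile (and blocks, if any) as a TSV report."""
    with open(path, "wt", encoding="utf-8") as out:
        out.write(f"# n_sequences={profile.n_sequences}\n")
        out.write("record\tregion\tframe_pos\tconservation\tband\n")
        for region, pos, cons, band in profile.columns:
            out.write(f"position\t{region}\t{pos}\t{cons:.6g}\t{band}\n")
        for blk in blocks:
            out.write(
                f"block\t{blk.region}\t{blk.start_pos}\t{blk.min_conservation:.6g}\t"
                f"len={blk.length};end={blk.end_pos}\n"
            )


def read_profile_report(path: str | Path) -> ConservationProfile:
    """Re-read the position rows of a :func:`profile_report` TSV."""
    n_sequences = 0
    cols = []
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("# n_sequences="):
                n_sequences = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("record"):
                continue
            fields = line.split("\t")
            if fields[0] != "position":
                continue
            cols.append((fields[1], int(fields[2]), float(fields[3]), fields[4]))
    return ConservationProfile(columns=tuple(cols), n_sequences=n_sequences)
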