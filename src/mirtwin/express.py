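"""Small-RNA quantification: adapter trimming, read assignment, RPM.

Reads are truncated at the sequencing adapter, assigned to mature miRNAs
allowing a 1-nt shift at either end (isomiR tolerance), and normalized to
reads per million assigned reads (RPM).  Reads compatible with several
matures are split fractionally and equally.  Differential testing is out of
scope; :func:`tissue_contrast` produces the descriptive per-group means and
log2 ratios used to compare vegetative and reproductive tissues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import MatureMiRNA
from .io import SequenceRecord, normalize_seq

#: Default 3' sequencing adapter (RNA alphabet; TGGAATTCTCGGG in DNA).
DEFAULT_ADAPTER = "UGGAAUUCUCGGG"

MIN_TRIMMED_LEN = 18
MIN_ADAPTER_PREFIX = 8


@dataclass(frozen=True)
class TrimResult:
    seq: str | None  # None when rejected
    status: str  # "trimmed", "untrimmed" or "too_short"


def trim_adapter(read: str, adapter: str = DEFAULT_ADAPTER) -> TrimResult:
    """Truncate a read at the leftmost adapter occurrence.

    Full-adapter matches anywhere, or a ≥ 8-nt adapter prefix reaching the
    read's 3' end, count as adapter evidence.  Reads without evidence pass
    through flagged ``untrimmed``; trimmed reads shorter than 18 nt are
    rejected (``too_short``).
    """
    read = normalize_seq(read)
    adapter = normalize_seq(adapter)
    if not read:
        raise ValueError("empty read")
    cut = read.find(adapter)
    if cut < 0:
        for k in range(min(len(adapter) - 1, len(read)), MIN_ADAPTER_PREFIX - 1, -1):
            if read[-k:] == adapter[:k]:
                cut = len(read) - k
                break
        else:
            return TrimResult(read, "untrimmed")
    trimmed = read[:cut]
    if len(trimmed) < MIN_TRIMMED_LEN:
        return TrimResult(None, "too_short")
    return TrimResult(trimmed, "trimmed")


def _assignment_window(
    mature: MatureMiRNA,
    precursor: SequenceRecord | None,
    shift: int,
) -> tuple[str, int]:
    """(window sequence, offset of mature start within window, 0-based)."""
    if precursor is None:
        return mature.seq, 0
    idx = precursor.seq.find(mature.seq)
    if idx < 0:
        return mature.seq, 0
    lo = max(0, idx - shift)
    hi = min(len(precursor.seq), idx + len(mature.seq) + shift)
    return precursor.seq[lo:hi], idx - lo


def matches_mature(
    read: str,
    mature: MatureMiRNA,
    precursor: SequenceRecord | None = None,
    shift: int = 1,
) -> bool:
    """True iff the read equals the mature up to ``shift`` nt at each end.

    With precursor context the read may also extend into the precursor by
    up to ``shift`` nt per end; without context only end-trimmed variants
    can match.
    """
    window, m_off = _assignment_window(mature, precursor, shift)
    m_len = len(mature.seq)
    for start in range(max(0, m_off - shift), m_off + shift + 1):
        end = start + len(read)  # exclusive, window coords
        if end > len(window):
            continue
        if abs(start - m_off) > shift or abs(end - (m_off + m_len)) > shift:
            continue
        if window[start:end] == read:
            return True
    return False


def assign_reads(
    reads: Sequence[str | SequenceRecord],
    matures: Sequence[MatureMiRNA],
    precursors: Sequence[SequenceRecord] | None = None,
    shift: int = 1,
) -> pd.Series:
    """Count reads per mature (fractional for multi-matching reads).

    Returns a Series indexed by mature id; the ``total_assigned`` is the sum
    of the series.  Precursor context, when given, is matched to matures by
    exact substring search.
    """
    pre_by_mature: dict[str, SequenceRecord | None] = {}
    for m in matures:
        pre_by_mature[m.id] = None
        for p in precursors or ():
            if m.seq in p.seq:
                pre_by_mature[m.id] = p
                break
    counts = pd.Series(0.0, index=[m.id for m in matures])
    for read in reads:
        seq = read.seq if isinstance(read, SequenceRecord) else normalize_seq(read)
        hits = [m.id for m in matures if matches_mature(seq, m, pre_by_mature[m.id], shift)]
        if hits:
            for mid in hits:
                counts[mid] += 1.0 / len(hits)
    return counts


@dataclass
class ExpressionTable:
    """miRNA × sample table of raw (possibly fractional) counts and RPM."""

    counts: pd.DataFrame  # rows: miRNA ids; columns: sample ids
    totals: pd.Series | None = None  # per-sample totals for normalization

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)

    @property
    def rpm(self) -> pd.DataFrame:
        totals = self.totals.reindex(self.counts.columns)
        zero = totals == 0
        if zero.any():
            warnings.warn(
                f"samples with zero assigned reads: {list(totals.index[zero])}; RPM set to 0",
                stacklevel=2,
            )
        safe = totals.replace(0, 1)
        out = self.counts.div(safe, axis=1) * 1e6
        out.loc[:, zero] = 0.0
        return out

    def to_tsv(self, path) -> None:
        rpm = self.rpm
        merged = pd.concat(
            {"count": self.counts, "rpm": rpm}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1)
        merged.to_csv(path, sep="\t")


def rpm_table(
    counts: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    totals: Mapping[str, float] | None = None,
) -> ExpressionTable:
    """Build an :class:`ExpressionTable` from per-sample count columns.

    ``counts`` maps sample id → (miRNA id → count), or is an equivalent
    DataFrame (miRNA rows, sample columns).  By default RPM normalizes to
    the per-sample assigned total.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame({s: pd.Series(c) for s, c in counts.items()}).fillna(0.0)
    totals_series = pd.Series(totals) if totals is not None else None
    return ExpressionTable(counts=counts.astype(float), totals=totals_series)


def tissue_contrast(
    table: ExpressionTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-miRNA mean RPM in two sample groups and log2((a+1)/(b+1))."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    unknown = (set(group_a) | set(group_b)) - set(table.counts.columns)
    if unknown:
        raise ValueError(f"unknown sample id(s): {sorted(unknown)}")
    rpm = table.rpm
    mean_a = rpm[list(group_a)].mean(axis=1)
    mean_b = rpm[list(group_b)].mean(axis=1)
    log2_ratio = ((mean_a + 1.0) / (mean_b + 1.0)).map(math.log2)
    return pd.DataFrame(
        {"mean_rpm_a": mean_a, "mean_rpm_b": mean_b, "log2_ratio": log2_ratio}
    )
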