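"""Readers and writers for the external formats the toolkit touches.

Everything downstream works on :class:`SequenceRecord` and friends; the
internal alphabet is RNA (``A C G U N``), uppercase.  DNA input (``T``) is
accepted and converted, since miRBase and genome FASTA files mix conventions.
All coordinates are 1-based inclusive (GFF3 convention) throughout the
package.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import AlignIO, Phylo

RNA_ALPHABET = set("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def normalize_seq(raw: str, *, allow_gaps: bool = False, line: int | None = None) -> str:
    """Uppercase, convert T to U, and reject letters outside {A,C,G,U,N}.

    Idempotent: normalizing twice equals normalizing once.
    """
    seq = raw.strip().upper().replace("T", "U")
    allowed = RNA_ALPHABET | ({"-", "."} if allow_gaps else set())
    bad = set(seq) - allowed
    if bad:
        where = f" at line {line}" if line is not None else ""
        raise ParseError(f"illegal sequence character(s) {sorted(bad)}{where}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence (id, sequence, free-text description)."""

    id: str
    seq: str
    desc: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass(frozen=True)
class GenomicLocus:
    """1-based inclusive interval on a named sequence, with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid locus coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnchorAnnotation:
    """miRNA-5p / miRNA-3p positions within one (unaligned) precursor sequence.

    These anchors define the 40bp-5p/loop/3p-40bp coordinate frame used for
    conservation profiling.
    """

    seq_id: str
    p5_start: int
    p5_end: int
    p3_start: int
    p3_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.p5_start <= self.p5_end < self.p3_start <= self.p3_end):
            raise ValueError(
                f"anchors must satisfy p5_start <= p5_end < p3_start <= p3_end, "
                f"got {self.p5_start},{self.p5_end},{self.p3_start},{self.p3_end}"
            )


def _open_text(path: str | Path) -> TextIO:
    if str(path) == "-":
        return sys.stdin
    return open(path, "rt", encoding="utf-8")


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a (possibly wrapped) FASTA file into normalized records.

    Raises :class:`ParseError` naming the line number for malformed headers,
    illegal characters or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: tuple[str, str, int] | None = None  # id, desc, line no
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc, line_no = header
        seq = "".join(chunks)
        records.append(SequenceRecord(rid, seq, desc))

    handle = _open_text(path)
    try:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                fields = line[1:].split(maxsplit=1)
                if not fields or not fields[0]:
                    raise ParseError(f"empty FASTA header at line {line_no}")
                rid = fields[0]
                if rid in seen:
                    raise ParseError(f"duplicate record id {rid!r} at line {line_no}")
                seen.add(rid)
                header = (rid, fields[1] if len(fields) > 1 else "", line_no)
            else:
                if header is None:
                    raise ParseError(f"sequence before first FASTA header at line {line_no}")
                chunks.append(normalize_seq(line, allow_gaps=allow_gaps, line=line_no))
        flush()
    finally:
        if handle is not sys.stdin:
            handle.close()
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line FASTQ records; qualities are checked for length, then dropped."""
    records: list[SequenceRecord] = []
    handle = _open_text(path)
    try:
        lines = [ln.rstrip("\n") for ln in handle]
    finally:
        if handle is not sys.stdin:
            handle.close()
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(f"truncated FASTQ record near line {len(lines)}")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        line_no = i + 1
        if not head.startswith("@"):
            raise ParseError(f"expected '@' header at line {line_no}")
        if not plus.startswith("+"):
            raise ParseError(f"expected '+' separator at line {line_no + 2}")
        if len(seq) != len(qual):
            raise ParseError(
                f"sequence/quality length mismatch ({len(seq)} vs {len(qual)}) at line {line_no + 3}"
            )
        fields = head[1:].split(maxsplit=1)
        if not fields or not fields[0]:
            raise ParseError(f"empty FASTQ header at line {line_no}")
        records.append(
            SequenceRecord(fields[0], normalize_seq(seq, line=line_no + 1),
                           fields[1] if len(fields) > 1 else "")
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        for rec in records:
            desc = f" {rec.desc}" if rec.desc else ""
            out.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def write_gff3(loci: Sequence[tuple[GenomicLocus, dict]], path: str | Path) -> None:
    """Write precursor loci as GFF3.

    Each entry is ``(locus, attributes)``; attributes must contain ``ID`` and
    ``family`` and may contain ``mature`` as a child-locus
    (:class:`GenomicLocus`) for the mature miRNA within the precursor.
    """
    with open(path, "wt", encoding="utf-8") as out:
        out.write("##gff-version 3\n")
        for locus, attrs in loci:
            if "ID" not in attrs or "family" not in attrs:
                raise ValueError("GFF3 attributes must include ID and family")
            extra = {k: v for k, v in attrs.items() if k not in ("ID", "family", "mature")}
            attr_str = ";".join(
                [f"ID={attrs['ID']}", f"family={attrs['family']}"]
                + [f"{k}={v}" for k, v in extra.items()]
            )
            out.write(
                "\t".join(
                    [locus.seq_id, "mirtwin", "miRNA_primary_transcript",
                     str(locus.start), str(locus.end), ".", locus.strand, ".", attr_str]
                )
                + "\n"
            )
            mature = attrs.get("mature")
            if mature is not None:
                out.write(
                    "\t".join(
                        [mature.seq_id, "mirtwin", "miRNA",
                         str(mature.start), str(mature.end), ".", mature.strand, ".",
                         f"ID={attrs['ID']}.mature;Parent={attrs['ID']};family={attrs['family']}"]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[tuple[GenomicLocus, dict]]:
    """Read back the subset of GFF3 that :func:`write_gff3` emits."""
    entries: list[tuple[GenomicLocus, dict]] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"bad GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            locus = GenomicLocus(cols[0], int(cols[3]), int(cols[4]), cols[6])
            attrs["type"] = cols[2]
            entries.append((locus, attrs))
    return entries


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA or Clustal file; rows must share one length.

    Gap characters ``-`` are preserved.  Returns rows in file order; use
    ``len(rows[0].seq)`` for the column count.
    """
    with _open_text(path) as handle:
        text = handle.read()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(StringIO(text), fmt)
    except ValueError as exc:
        raise ParseError(f"bad alignment ({fmt}): {exc}") from exc
    rows = [
        SequenceRecord(rec.id, normalize_seq(str(rec.seq), allow_gaps=True),
                       getattr(rec, "description", "") or "")
        for rec in aln
    ]
    ncol = len(rows[0].seq)
    if any(len(r.seq) != ncol for r in rows):
        raise ParseError("alignment rows have unequal lengths")
    return rows


def write_alignment(rows: Sequence[SequenceRecord], path: str | Path) -> None:
    if rows:
        ncol = len(rows[0].seq)
        if any(len(r.seq) != ncol for r in rows):
            raise ValueError("alignment rows have unequal lengths")
    write_fasta(rows, path, width=10**9)


def read_anchors(path: str | Path) -> list[AnchorAnnotation]:
    """Read a TSV of per-sequence 5p/3p anchors.

    Columns: seq_id, p5_start, p5_end, p3_start, p3_end (header optional).
    """
    anchors: list[AnchorAnnotation] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "seq_id":
                continue
            if len(cols) < 5:
                raise ParseError(f"anchor TSV needs 5 columns at line {line_no}")
            try:
                anchors.append(
                    AnchorAnnotation(cols[0], int(cols[1]), int(cols[2]), int(cols[3]), int(cols[4]))
                )
            except ValueError as exc:
                raise ParseError(f"bad anchor at line {line_no}: {exc}") from exc
    return anchors


def write_anchors(anchors: Iterable[AnchorAnnotation], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("seq_id\tp5_start\tp5_end\tp3_start\tp3_end\n")
        for a in anchors:
            out.write(f"{a.seq_id}\t{a.p5_start}\t{a.p5_end}\t{a.p3_start}\t{a.p3_end}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a Bio.Phylo tree as Newick (support values as internal labels)."""
    for leaf in tree.get_terminals():
        if not leaf.name:
            raise ValueError("cannot write a tree with unlabeled leaves")
    Phylo.write(tree, str(path), "newick")


def read_newick(path: str | Path):
    return Phylo.read(str(path), "newick")


def fetch_locus(genome: Sequence[SequenceRecord], locus: GenomicLocus) -> str:
    """Sequence of a locus, reverse-complemented for minus-strand loci."""
    by_id = {rec.id: rec for rec in genome}
    if locus.seq_id not in by_id:
        raise KeyError(f"unknown sequence id {locus.seq_id!r}")
    rec = by_id[locus.seq_id]
    if locus.end > len(rec.seq):
        raise ValueError(f"locus {locus} exceeds sequence length {len(rec.seq)}")
    seq = rec.seq[locus.start - 1 : locus.end]
    return revcomp(seq) if locus.strand == "-" else seq
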