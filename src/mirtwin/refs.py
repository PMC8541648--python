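"""Bundled reference sequences.

A small curated set of canonical miR156/miR529 mature sequences
(transcribed from miRBase 22; the miR156 mature core is invariant across
monocots and Arabidopsis).  The family label is the first description
token.  For anything beyond these exemplars, point the tools at your own
miRBase FASTA download.
"""

from __future__ import annotations

from importlib import resources

from .classify import MatureMiRNA
from .io import SequenceRecord, read_fasta


def load_reference_matures() -> list[MatureMiRNA]:
    """Bundled miR156/miR529 matures as labeled :class:`MatureMiRNA`."""
    path = resources.files("mirtwin.data") / "mirbase22_matures.fa"
    with resources.as_file(path) as fp:
        records = read_fasta(fp)
    return [
        MatureMiRNA(id=rec.id, seq=rec.seq, family=rec.desc.split()[0])
        for rec in records
    ]


def reference_mature(mirna_id: str) -> MatureMiRNA:
    for m in load_reference_matures():
        if m.id == mirna_id:
            return m
    raise KeyError(f"no bundled mature named {mirna_id!r}")
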