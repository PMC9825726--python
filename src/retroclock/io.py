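"""FASTA and BED input/output.

FASTA goes through Biopython; coordinates in BED files are 0-based,
half-open, matching the package-internal convention.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

FASTA_WRAP = 80


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | os.PathLike, wrap: int = FASTA_WRAP) -> None:
    """Write sequences as FASTA wrapped at ``wrap`` columns."""
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)
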