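"""FASTA reading/writing (thin wrapper over Biopython's SeqIO)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records in file order, uppercasing sequences.

    Duplicate ids and empty sequences are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"empty sequence for {rec.id!r} in {path}")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str] | SequenceRecord],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SequenceRecord):
                name, seq = rec.id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
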