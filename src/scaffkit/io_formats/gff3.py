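"""Minimal GFF3 reading/writing (1-based inclusive on disk)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


class Gff3Error(ValueError):
    pass


@dataclass(frozen=True)
class Gff3Feature:
    seqid: str
    source: str
    ftype: str
    start: int  # 1-based inclusive
    end: int
    score: str
    strand: str
    phase: str
    attributes: str

    def to_line(self) -> str:
        return "\t".join([self.seqid, self.source, self.ftype, str(self.start),
                          str(self.end), self.score, self.strand, self.phase,
                          self.attributes])


def read_gff3(path: str | Path,
              sequence_lengths: dict[str, int] | None = None) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise Gff3Error(f"{path}:{lineno}: {len(f)} columns")
            feat = Gff3Feature(f[0], f[1], f[2], int(f[3]), int(f[4]), f[5], f[6], f[7], f[8])
            if feat.start < 1 or feat.end < feat.start:
                raise Gff3Error(f"{path}:{lineno}: bad coordinates {feat.start}..{feat.end}")
            if sequence_lengths is not None:
                length = sequence_lengths.get(feat.seqid)
                if length is None:
                    raise Gff3Error(f"{path}:{lineno}: unknown sequence {feat.seqid!r}")
                if feat.end > length:
                    raise Gff3Error(
                        f"{path}:{lineno}: feature end {feat.end} > length {length} of {feat.seqid}"
                    )
            feats.append(feat)
    return feats


def write_gff3(path: str | Path, features: Iterable[Gff3Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.to_line() + "\n")
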