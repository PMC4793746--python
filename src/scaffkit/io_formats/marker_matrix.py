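"""Genotype matrix TSV for an F2-type selfed population.

Dialect: header ``marker_id\ttype\t<ind1>...<indN>``, one row per marker,
codes in {a,h,b,c,d,u} (c = not-a, d = not-b, u = missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

VALID_TYPES = ("codominant", "dominant_a", "dominant_b")
VALID_CODES = frozenset("ahbcdu")
# observable code universe per marker type
TYPE_CODES = {
    "codominant": frozenset("ahbu"),
    "dominant_b": frozenset("acu"),  # {h,b} collapsed to c
    "dominant_a": frozenset("bdu"),  # {a,h} collapsed to d
}


class MarkerMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerMatrixRow:
    marker_id: str
    marker_type: str
    genotypes: str  # one code character per individual

    def __post_init__(self):
        if self.marker_type not in VALID_TYPES:
            raise MarkerMatrixError(f"{self.marker_id}: unknown type {self.marker_type!r}")
        bad = set(self.genotypes) - TYPE_CODES[self.marker_type]
        if bad:
            raise MarkerMatrixError(
                f"{self.marker_id}: codes {sorted(bad)} invalid for {self.marker_type}"
            )


def read_marker_matrix(path: str | Path) -> tuple[list[str], list[MarkerMatrixRow]]:
    """Returns (individual names, rows)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["marker_id", "type"]:
            raise MarkerMatrixError(f"bad header in {path}: {header[:2]}")
        individuals = header[2:]
        rows: list[MarkerMatrixRow] = []
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 2 + len(individuals):
                raise MarkerMatrixError(
                    f"{path}:{lineno}: {len(f) - 2} genotype columns, expected {len(individuals)}"
                )
            codes = "".join(f[2:])
            bad = set(codes) - VALID_CODES
            if bad:
                col = next(i for i, c in enumerate(f[2:]) if c in bad)
                raise MarkerMatrixError(
                    f"{path}:{lineno}: unknown code {f[2 + col]!r} in column {col + 3}"
                )
            rows.append(MarkerMatrixRow(f[0], f[1], codes))
    return individuals, rows


def write_marker_matrix(path: str | Path, individuals: list[str],
                        rows: Iterable[MarkerMatrixRow]) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\ttype\t" + "\t".join(individuals) + "\n")
        for row in rows:
            fh.write(f"{row.marker_id}\t{row.marker_type}\t" + "\t".join(row.genotypes) + "\n")
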