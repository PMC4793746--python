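"""AGP v2.0 reading/writing and object-sequence reconstruction."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from ..assembly import revcomp


class AgpError(ValueError):
    pass


@dataclass(frozen=True)
class AgpRow:
    object_id: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # W scaffold, U/N gap
    # W rows
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # +, -, ?
    # gap rows
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage: str = "yes"
    linkage_evidence: str = "map"

    def to_line(self) -> str:
        base = f"{self.object_id}\t{self.object_beg}\t{self.object_end}\t{self.part_number}\t{self.component_type}"
        if self.component_type == "W":
            return (f"{base}\t{self.component_id}\t{self.component_beg}\t"
                    f"{self.component_end}\t{self.orientation}")
        return (f"{base}\t{self.gap_length}\t{self.gap_type}\t{self.linkage}\t"
                f"{self.linkage_evidence}")


def validate_tiling(rows: list[AgpRow]) -> None:
    """Parts must tile each object contiguously without overlap."""
    expect: dict[str, int] = {}
    parts: dict[str, int] = {}
    for row in rows:
        nxt = expect.get(row.object_id, 1)
        if row.object_beg != nxt:
            raise AgpError(
                f"object {row.object_id}: part {row.part_number} begins at "
                f"{row.object_beg}, expected {nxt} (hole or overlap)"
            )
        if row.object_end < row.object_beg:
            raise AgpError(f"object {row.object_id}: inverted part coordinates")
        if row.component_type in ("U", "N"):
            if row.gap_length != row.object_end - row.object_beg + 1:
                raise AgpError(f"object {row.object_id}: gap length mismatch at part {row.part_number}")
        nxt_part = parts.get(row.object_id, 0) + 1
        if row.part_number != nxt_part:
            raise AgpError(f"object {row.object_id}: part_number {row.part_number} != {nxt_part}")
        parts[row.object_id] = row.part_number
        expect[row.object_id] = row.object_end + 1


def write_agp(path: str | Path, rows: Iterable[AgpRow]) -> None:
    rows = list(rows)
    validate_tiling(rows)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise AgpError(f"AGP row with {len(f)} columns: {line!r}")
            if f[4] == "W":
                rows.append(AgpRow(f[0], int(f[1]), int(f[2]), int(f[3]), "W",
                                   component_id=f[5], component_beg=int(f[6]),
                                   component_end=int(f[7]), orientation=f[8]))
            elif f[4] in ("U", "N"):
                rows.append(AgpRow(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                                   gap_length=int(f[5]), gap_type=f[6],
                                   linkage=f[7], linkage_evidence=f[8]))
            else:
                raise AgpError(f"unsupported component type {f[4]!r}")
    validate_tiling(rows)
    return rows


def agp_to_sequences(rows: list[AgpRow], components: dict[str, str]) -> dict[str, str]:
    """Rebuild object sequences from AGP rows plus component sequences."""
    out: dict[str, str] = {}
    for row in rows:
        cur = out.get(row.object_id, "")
        if row.component_type == "W":
            seq = components[row.component_id][row.component_beg - 1:row.component_end]
            if row.orientation == "-":
                seq = revcomp(seq)
            cur += seq
        else:
            cur += "N" * row.gap_length
        out[row.object_id] = cur
    return out
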