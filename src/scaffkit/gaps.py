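"""Gap (N-run) detection and insert-size based length re-estimation.

A gap's new length is chosen so that correctly oriented pairs spanning it
recover the library's expected median insert:

    new = max(min_gap, current + expected_median - median(observed insert))

Libraries are applied sequentially in increasing insert-size order, each
with its own support threshold (30 / 2 / 1 pairs for the 5 kb / 10 kb /
BAC-end tiers of the source data).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import Assembly
from .readpairs import LibraryStats, PairAlignment, _oriented

MIN_GAP = 10


@dataclass
class GapRecord:
    scaffold: str
    start: int  # 0-based half-open over the N-run
    end: int
    current_length: int
    new_length: int | None = None
    n_support_pairs: int = 0
    library_used: str | None = None
    terminal: bool = False  # N-run touching a scaffold end; not resizable

    @property
    def resized(self) -> bool:
        return self.new_length is not None and self.new_length != self.current_length


def find_gaps(scaffold: str, sequence: str) -> list[GapRecord]:
    """All maximal N-runs, left to right; terminal runs are flagged."""
    out = []
    for m in re.finditer(r"N+", sequence):
        out.append(GapRecord(scaffold, m.start(), m.end(), m.end() - m.start(),
                             terminal=m.start() == 0 or m.end() == len(sequence)))
    return out


def reestimate_gap(gap: GapRecord, pairs: Sequence[PairAlignment],
                   stats: LibraryStats, min_pairs: int,
                   min_gap: int = MIN_GAP) -> GapRecord:
    """Fill in new_length/support for one gap from expected-orientation
    pairs whose outer span fully covers the N-run."""
    inward = ("+", "-") if stats.expected_orientation == "FR" else ("-", "+")
    inserts = []
    for p in pairs:
        if p.scaffold_1 != gap.scaffold or p.scaffold_2 != gap.scaffold:
            continue
        if _oriented(p) != inward:
            continue
        lo = min(p.pos_1, p.pos_2)
        hi = max(p.pos_1, p.pos_2) + p.read_length
        if lo < gap.start and hi > gap.end:
            inserts.append(hi - lo)
    gap.n_support_pairs = len(inserts)
    if gap.terminal or len(inserts) < min_pairs:
        gap.new_length = None
        return gap
    observed = float(np.median(inserts))
    gap.new_length = max(min_gap,
                         int(round(gap.current_length + stats.expected_median_insert - observed)))
    gap.library_used = stats.name
    return gap


def reestimate_all(assembly: Assembly,
                   libraries: Sequence[tuple[LibraryStats, Sequence[PairAlignment], int]],
                   min_gap: int = MIN_GAP) -> list[GapRecord]:
    """Re-estimate every gap, one pass per library in increasing insert
    order.  ``libraries``: (stats, pairs aligned to the CURRENT assembly,
    min support pairs).  Later libraries see coordinates lifted through the
    resizes of earlier ones (handled by the caller via the ledger).

    Returns the per-gap report of the final state.
    """
    from .remodler import lift_pairs  # avoid import cycle at module load

    ordered = sorted(libraries, key=lambda t: t[0].expected_median_insert)
    report: list[GapRecord] = []
    start_step = len(assembly.ledger)
    for stats, pairs, min_pairs in ordered:
        new_records = assembly.ledger.records[start_step:]
        if new_records:
            pairs = lift_pairs(new_records, pairs)
        scaffold_gaps = []
        for scaf, seq in assembly.sequences.items():
            for gap in find_gaps(scaf, seq):
                scaffold_gaps.append(reestimate_gap(gap, pairs, stats, min_pairs, min_gap))
        # apply right-to-left per scaffold so earlier coordinates stay valid
        for gap in sorted(scaffold_gaps, key=lambda g: (g.scaffold, -g.start)):
            if gap.resized:
                assembly.resize_gap(gap.scaffold, gap.start, gap.end, gap.new_length)
        report.extend(scaffold_gaps)
    return report
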