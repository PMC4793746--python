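"""Chimeric-scaffold detection and splitting.

Candidates come from linkage-group conflicts along a scaffold (two or more
contiguous marker blocks from different groups); the breakpoint is then
localised inside the inter-block interval where spanning mate-pair
coverage vanishes or the discordant-read fraction spikes, preferring an
existing N-gap for the actual cut.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import Assembly
from .markers import MarkerPlacement, _lg_blocks
from .readpairs import Track


@dataclass
class ConflictCandidate:
    scaffold: str
    interval_start: int  # last marker of the left block
    interval_end: int    # first marker of the right block
    left_lg: str
    right_lg: str


@dataclass
class BreakpointCall:
    scaffold: str
    interval_start: int
    interval_end: int
    left_lg: str
    right_lg: str
    min_spanning: float
    max_discordant: float
    chosen_split_pos: int | None  # None when unresolved
    reason: str = ""


def find_conflict_candidates(placements: Sequence[MarkerPlacement],
                             candidate_scaffolds: Sequence[str],
                             min_block: int = 3) -> list[ConflictCandidate]:
    """One candidate per adjacent pair of opposite-LG marker blocks."""
    out: list[ConflictCandidate] = []
    for scaf in candidate_scaffolds:
        ps = sorted((p for p in placements
                     if p.scaffold == scaf and p.linkage_group is not None
                     and p.status in ("kept", "discarded_discrepant")),
                    key=lambda p: (p.position, p.marker_id))
        blocks = [b for b in _lg_blocks([p.linkage_group for p in ps])
                  if b[2] - b[1] + 1 >= min_block]
        for left, right in zip(blocks, blocks[1:]):
            if left[0] == right[0]:
                continue
            out.append(ConflictCandidate(
                scaf, ps[left[2]].position, ps[right[1]].position,
                left[0], right[0]))
    return out


def _qualifying_runs(qualify: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, q in enumerate(qualify):
        if q and start is None:
            start = i
        elif not q and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(qualify)))
    return runs


def _longest_n_run(seq: str, start: int, end: int) -> tuple[int, int] | None:
    best = None
    for m in re.finditer(r"N+", seq[start:end]):
        if best is None or (m.end() - m.start()) > (best[1] - best[0]):
            best = (start + m.start(), start + m.end())
    return best


def locate_breakpoint(candidate: ConflictCandidate, sequence: str,
                      spanning: Track, discordant: Track,
                      span_floor: float = 0.0,
                      disc_ceiling: float = 0.5) -> BreakpointCall:
    """Pick the split position inside the conflict interval.

    Qualifying windows have spanning coverage <= ``span_floor`` or
    discordant fraction >= ``disc_ceiling``; the longest qualifying run is
    selected and the cut is the midpoint of the longest N-run inside it
    (midpoint of the run if it contains no Ns).
    """
    w = spanning.window
    w0 = candidate.interval_start // w
    w1 = max(w0 + 1, -(-candidate.interval_end // w))
    w1 = min(w1, spanning.n_windows())
    span = spanning.values[w0:w1]
    disc = discordant.values[w0:w1]
    min_span = float(np.nanmin(span)) if len(span) else float("nan")
    with np.errstate(invalid="ignore"):
        max_disc = float(np.nanmax(disc)) if np.isfinite(disc).any() else 0.0
    qualify = (span <= span_floor) | (np.nan_to_num(disc, nan=0.0) >= disc_ceiling)
    runs = _qualifying_runs(qualify)
    if not runs:
        return BreakpointCall(candidate.scaffold, candidate.interval_start,
                              candidate.interval_end, candidate.left_lg,
                              candidate.right_lg, min_span, max_disc, None,
                              "no window with missing spanning coverage or "
                              "elevated discordance")
    runs.sort(key=lambda r: (-(r[1] - r[0]), r[0]))
    a, b = runs[0]
    run_start = (w0 + a) * w
    run_end = min((w0 + b) * w, len(sequence))
    nrun = _longest_n_run(sequence, run_start, run_end)
    pos = (nrun[0] + nrun[1]) // 2 if nrun else (run_start + run_end) // 2
    return BreakpointCall(candidate.scaffold, candidate.interval_start,
                          candidate.interval_end, candidate.left_lg,
                          candidate.right_lg, min_span, max_disc, pos)


def split_scaffold(assembly: Assembly, scaffold: str, pos: int,
                   child_names: tuple[str, str] | None = None) -> tuple[str, str]:
    """Split with N-trimming at the cut (delegates to the ledgered edit)."""
    return assembly.split(scaffold, pos, child_names)
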