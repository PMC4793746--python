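"""Mate-pair classification, deduplication and windowed evidence tracks.

Pair classes follow the standard structural-variant signature palette:
concordant, insert too small / too large, reverse-reverse, forward-forward,
complete-reverse (RF when FR is expected), and trans (mates on different
scaffolds).  Insert size is the outer distance, leftmost start to rightmost
end (the SAM TLEN convention).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class PairClass(enum.Enum):
    CONCORDANT = "concordant"
    DISC_SMALLER = "disc_smaller"
    DISC_GREATER = "disc_greater"
    REVERSE_REVERSE = "reverse_reverse"
    FORWARD_FORWARD = "forward_forward"
    COMPLETE_REVERSE = "complete_reverse"
    TRANS = "trans"


@dataclass(frozen=True)
class PairAlignment:
    pair_id: str
    scaffold_1: str
    pos_1: int  # leftmost aligned base, 0-based
    strand_1: str
    scaffold_2: str
    pos_2: int
    strand_2: str
    read_length: int
    library: str = "lib"

    def coordinate_key(self) -> tuple:
        return (self.scaffold_1, self.pos_1, self.strand_1,
                self.scaffold_2, self.pos_2, self.strand_2)


@dataclass
class LibraryStats:
    name: str
    expected_median_insert: float
    insert_min: float
    insert_max: float
    expected_orientation: str = "FR"

    def __post_init__(self):
        if not self.insert_min < self.expected_median_insert < self.insert_max:
            raise ValueError(
                f"library {self.name}: bounds {self.insert_min}/{self.insert_max} "
                f"do not bracket median {self.expected_median_insert}"
            )
        if self.expected_orientation not in ("FR", "RF"):
            raise ValueError(f"unsupported orientation {self.expected_orientation!r}")


def outer_insert(pair: PairAlignment) -> int:
    lo = min(pair.pos_1, pair.pos_2)
    hi = max(pair.pos_1, pair.pos_2) + pair.read_length
    return hi - lo


def _oriented(pair: PairAlignment) -> tuple[str, str]:
    """Strands of (leftmost, rightmost) mate on the shared scaffold."""
    if pair.pos_1 <= pair.pos_2:
        return pair.strand_1, pair.strand_2
    return pair.strand_2, pair.strand_1


def classify_pair(pair: PairAlignment, stats: LibraryStats) -> PairClass:
    if pair.scaffold_1 != pair.scaffold_2:
        return PairClass.TRANS
    left, right = _oriented(pair)
    inward = ("+", "-") if stats.expected_orientation == "FR" else ("-", "+")
    outward = ("-", "+") if stats.expected_orientation == "FR" else ("+", "-")
    if (left, right) == inward:
        ins = outer_insert(pair)
        if ins < stats.insert_min:
            return PairClass.DISC_SMALLER
        if ins > stats.insert_max:
            return PairClass.DISC_GREATER
        return PairClass.CONCORDANT
    if (left, right) == outward:
        return PairClass.COMPLETE_REVERSE
    if left == "+":
        return PairClass.FORWARD_FORWARD
    return PairClass.REVERSE_REVERSE


def estimate_library_stats(pairs: Iterable[PairAlignment], name: str = "lib",
                           expected_orientation: str = "FR",
                           min_pairs: int = 1000,
                           min_half_width: float = 500.0) -> LibraryStats:
    """Median insert from same-scaffold, expected-orientation pairs; bounds
    median +/- 3 * 1.4826 * MAD (floored at ``min_half_width``)."""
    inward = ("+", "-") if expected_orientation == "FR" else ("-", "+")
    inserts = [outer_insert(p) for p in pairs
               if p.scaffold_1 == p.scaffold_2 and _oriented(p) == inward]
    if len(inserts) < min_pairs:
        raise ValueError(
            f"only {len(inserts)} usable pairs (< {min_pairs}); supply explicit "
            "insert bounds instead of estimating them"
        )
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    half = max(3 * 1.4826 * mad, min_half_width)
    return LibraryStats(name, med, med - half, med + half, expected_orientation)


def dedup_pairs(pairs: Iterable[PairAlignment]) -> list[PairAlignment]:
    """Keep the first pair seen per exact coordinate/strand signature."""
    seen: set[tuple] = set()
    out: list[PairAlignment] = []
    for p in pairs:
        key = p.coordinate_key()
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


@dataclass
class Track:
    """Windowed per-scaffold signal; windows tile from 0, last partial kept."""

    scaffold: str
    window: int
    values: np.ndarray  # float; NaN marks windows with no data

    def n_windows(self) -> int:
        return len(self.values)

    def window_bounds(self, i: int, scaffold_length: int | None = None) -> tuple[int, int]:
        start = i * self.window
        end = start + self.window
        if scaffold_length is not None:
            end = min(end, scaffold_length)
        return start, end

    def to_rows(self, scaffold_length: int | None = None) -> list[tuple[str, int, int, float]]:
        return [(self.scaffold, *self.window_bounds(i, scaffold_length), float(v))
                for i, v in enumerate(self.values)]


def default_window(stats: LibraryStats) -> int:
    return max(1, int(stats.expected_median_insert // 3))


def _n_windows(length: int, window: int) -> int:
    return max(1, math.ceil(length / window))


def discordant_fraction_track(pairs: Sequence[PairAlignment],
                              classes: Sequence[PairClass],
                              scaffold: str, scaffold_length: int,
                              window: int) -> Track:
    """Per window: reads of discordant pairs / reads of all pairs.

    Reads (not pairs) are counted; windows with no reads are NaN.
    """
    nw = _n_windows(scaffold_length, window)
    total = np.zeros(nw)
    disc = np.zeros(nw)
    for pair, cls in zip(pairs, classes):
        is_disc = cls is not PairClass.CONCORDANT
        for scaf, pos in ((pair.scaffold_1, pair.pos_1), (pair.scaffold_2, pair.pos_2)):
            if scaf != scaffold:
                continue
            w0 = pos // window
            w1 = (pos + pair.read_length - 1) // window
            for w in range(max(0, w0), min(nw - 1, w1) + 1):
                total[w] += 1
                if is_disc:
                    disc[w] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, disc / np.maximum(total, 1), np.nan)
    return Track(scaffold, window, frac)


def spanning_coverage_track(pairs: Sequence[PairAlignment],
                            classes: Sequence[PairClass],
                            scaffold: str, scaffold_length: int,
                            window: int) -> Track:
    """Per window: count of concordant pairs whose outer span fully covers
    the window."""
    nw = _n_windows(scaffold_length, window)
    diff = np.zeros(nw + 1)
    for pair, cls in zip(pairs, classes):
        if cls is not PairClass.CONCORDANT or pair.scaffold_1 != scaffold:
            continue
        lo = min(pair.pos_1, pair.pos_2)
        hi = max(pair.pos_1, pair.pos_2) + pair.read_length
        first = math.ceil(lo / window)          # first window starting at/after lo
        last = hi // window - 1                 # last window ending at/before hi
        # the final partial window ends at scaffold_length
        if last == nw - 2 and hi >= scaffold_length:
            last = nw - 1
        if first <= last:
            diff[first] += 1
            diff[last + 1] -= 1
    return Track(scaffold, window, np.cumsum(diff[:-1]))


def classify_all(pairs: Sequence[PairAlignment], stats: LibraryStats) -> list[PairClass]:
    return [classify_pair(p, stats) for p in pairs]


def discordant_fraction(classes: Sequence[PairClass]) -> float:
    if not classes:
        return 0.0
    disc = sum(1 for c in classes if c is not PairClass.CONCORDANT)
    return disc / len(classes)
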