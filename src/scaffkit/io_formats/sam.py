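"""Name-paired SAM consumption and emission (via pysam).

Only pairs with both mates mapped, primary, non-supplementary and at or
above the mapping-quality floor (the standard proxy for uniquely mapped
reads) are emitted.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from ..readpairs import PairAlignment

log = logging.getLogger(__name__)

DEFAULT_MAPQ_FLOOR = 20


def read_sam_pairs(path: str | Path, library_name: str = "lib",
                   mapq_floor: int = DEFAULT_MAPQ_FLOOR) -> Iterator[PairAlignment]:
    """Stream qualifying read pairs from a SAM file.

    Input need not be name-sorted: mates are buffered until both are seen.
    Orphan mates remaining at EOF produce a warning and are dropped.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            pair = _make_pair(mate, rec, library_name, mapq_floor)
            if pair is not None:
                yield pair
    if pending:
        warnings.warn(f"{len(pending)} orphan mates dropped at EOF of {path}")


def _make_pair(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment,
               library: str, mapq_floor: int) -> PairAlignment | None:
    if r1.is_unmapped or r2.is_unmapped:
        return None
    if r1.mapping_quality < mapq_floor or r2.mapping_quality < mapq_floor:
        return None
    if r1.is_read2:
        r1, r2 = r2, r1
    return PairAlignment(
        pair_id=r1.query_name,
        scaffold_1=r1.reference_name, pos_1=r1.reference_start,
        strand_1="-" if r1.is_reverse else "+",
        scaffold_2=r2.reference_name, pos_2=r2.reference_start,
        strand_2="-" if r2.is_reverse else "+",
        read_length=r1.query_length or r1.infer_read_length() or 0,
        library=library,
    )


def write_sam_pairs(path: str | Path, pairs: Iterable[PairAlignment],
                    sequences: dict[str, str]) -> None:
    """Emit pairs as a SAM file with one record per mate (100M CIGARs)."""
    names = list(sequences)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(sequences[n])} for n in names],
    })
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            for which in (1, 2):
                a = pysam.AlignedSegment(header)
                a.query_name = pair.pair_id
                if which == 1:
                    scaf, pos, strand = pair.scaffold_1, pair.pos_1, pair.strand_1
                    mscaf, mpos, mstrand = pair.scaffold_2, pair.pos_2, pair.strand_2
                    flag = 0x1 | 0x40
                else:
                    scaf, pos, strand = pair.scaffold_2, pair.pos_2, pair.strand_2
                    mscaf, mpos, mstrand = pair.scaffold_1, pair.pos_1, pair.strand_1
                    flag = 0x1 | 0x80
                if strand == "-":
                    flag |= 0x10
                if mstrand == "-":
                    flag |= 0x20
                a.flag = flag
                a.reference_id = tid[scaf]
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{pair.read_length}M"
                a.next_reference_id = tid[mscaf]
                a.next_reference_start = mpos
                if scaf == mscaf:
                    lo = min(pos, mpos)
                    hi = max(pos, mpos) + pair.read_length
                    a.template_length = (hi - lo) if pos <= mpos else -(hi - lo)
                a.query_sequence = sequences[scaf][pos:pos + pair.read_length]
                a.query_qualities = None
                out.write(a)
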