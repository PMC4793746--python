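"""Discordant-pair clustering, scaffold fusion/junction proposals,
application and validation.

A fusion inserts a free scaffold into an N-gap of a recipient scaffold; a
junction end-joins two scaffolds across a fixed 100-N gap.  Proposals are
derived from clusters of trans-mapped (or gapped oversized-insert) pairs
and accepted only in the relative orientation that renders their
supporting pairs concordant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembly import Assembly, LiftedInterval, _lift_one
from .readpairs import (LibraryStats, PairAlignment, PairClass, classify_pair,
                        discordant_fraction)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterLocus:
    scaffold: str
    start: int
    end: int
    strand: str


@dataclass
class DiscordantCluster:
    locus_1: ClusterLocus
    locus_2: ClusterLocus
    pairs: list[PairAlignment] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _canonical(pair: PairAlignment) -> tuple:
    a = (pair.scaffold_1, pair.pos_1, pair.strand_1)
    b = (pair.scaffold_2, pair.pos_2, pair.strand_2)
    return (a, b) if a <= b else (b, a)


def cluster_discordant(pairs: Sequence[PairAlignment], classes: Sequence[PairClass],
                       stats: LibraryStats, min_cluster: int = 5) -> list[DiscordantCluster]:
    """Group trans pairs (and gapped oversized-insert pairs) by scaffold
    pair and orientation signature, single-linkage on mate positions."""
    linkish: list[tuple[tuple, tuple, PairAlignment]] = []
    for pair, cls in zip(pairs, classes):
        if cls is PairClass.TRANS:
            a, b = _canonical(pair)
            linkish.append((a, b, pair))
        elif cls is PairClass.DISC_GREATER:
            lo = min(pair.pos_1, pair.pos_2)
            hi = max(pair.pos_1, pair.pos_2)
            if hi - (lo + pair.read_length) > 0:
                a, b = _canonical(pair)
                linkish.append((a, b, pair))
    groups: dict[tuple, list[tuple[int, int, PairAlignment]]] = {}
    for a, b, pair in linkish:
        key = (a[0], b[0], a[2], b[2])
        groups.setdefault(key, []).append((a[1], b[1], pair))

    out: list[DiscordantCluster] = []
    gap = stats.insert_max
    for (s1, s2, st1, st2), members in groups.items():
        members.sort()
        current: list[tuple[int, int, PairAlignment]] = []
        def flush():
            if len(current) >= min_cluster:
                rl = current[0][2].read_length
                p1 = [m[0] for m in current]
                p2 = [m[1] for m in current]
                out.append(DiscordantCluster(
                    ClusterLocus(s1, min(p1), max(p1) + rl, st1),
                    ClusterLocus(s2, min(p2), max(p2) + rl, st2),
                    [m[2] for m in current]))
        for m in members:
            if current and (m[0] - current[-1][0] > gap or abs(m[1] - current[-1][1]) > gap):
                flush()
                current = []
            current.append(m)
        flush()
    out.sort(key=lambda c: (c.locus_1.scaffold, c.locus_1.start,
                            c.locus_2.scaffold, c.locus_2.start))
    return out


# ---------------------------------------------------------------------------
# proposals


@dataclass
class EditProposal:
    kind: str  # fusion | junction
    donor: str
    recipient: str
    orientation: str = "+"
    gap_start: int | None = None        # fusion insertion gap (recipient coords)
    gap_end: int | None = None
    left: str | None = None             # junction layout
    right: str | None = None
    left_flip: bool = False
    right_flip: bool = False
    clusters: list[DiscordantCluster] = field(default_factory=list)
    n_pairs: int = 0
    n_made_concordant: int = 0
    status: str = "proposed"            # proposed/accepted/rejected/applied/validated
    reason: str = ""
    joints: list[int] = field(default_factory=list)  # post-edit joint coords
    result: str | None = None


def _edit_record(proposal: EditProposal, assembly: Assembly, min_pad: int = 10) -> dict:
    """Build the ledger record the edit WOULD produce, without applying it."""
    if proposal.kind == "fusion":
        donor_len = assembly.length_of(proposal.donor)
        residual = (proposal.gap_end - proposal.gap_start) - donor_len
        if residual < 2 * min_pad:
            lp = rp = min_pad
        else:
            lp = residual // 2
            rp = residual - lp
        return {"op": "fusion", "donor": proposal.donor, "recipient": proposal.recipient,
                "gap_start": proposal.gap_start, "gap_end": proposal.gap_end,
                "orientation": proposal.orientation, "left_pad": lp,
                "right_pad": rp, "donor_len": donor_len}
    return {"op": "junction", "left": proposal.left, "right": proposal.right,
            "left_flip": proposal.left_flip, "right_flip": proposal.right_flip,
            "gap": 100, "result": proposal.left,
            "left_len": assembly.length_of(proposal.left),
            "right_len": assembly.length_of(proposal.right)}


def lift_pair(records: Iterable[dict], pair: PairAlignment) -> PairAlignment | None:
    """Lift both mates through ledger records; None if a read no longer has
    an exact single-interval image."""
    ends = []
    for scaf, pos, strand in ((pair.scaffold_1, pair.pos_1, pair.strand_1),
                              (pair.scaffold_2, pair.pos_2, pair.strand_2)):
        frags = [LiftedInterval(scaf, pos, pos + pair.read_length)]
        for rec in records:
            nxt = []
            for fr in frags:
                nxt.extend(_lift_one(rec, fr))
            frags = nxt
        if len(frags) != 1 or frags[0].flags:
            return None
        fr = frags[0]
        ends.append((fr.scaffold, fr.start,
                     strand if not fr.flipped else ("-" if strand == "+" else "+")))
    (s1, p1, st1), (s2, p2, st2) = ends
    return PairAlignment(pair.pair_id, s1, p1, st1, s2, p2, st2,
                         pair.read_length, pair.library)


def lift_pairs(records: Iterable[dict], pairs: Iterable[PairAlignment]) -> list[PairAlignment]:
    records = list(records)
    out = []
    for p in pairs:
        lifted = lift_pair(records, p)
        if lifted is not None:
            out.append(lifted)
    return out


def _count_concordant_after(proposal: EditProposal, assembly: Assembly,
                            stats: LibraryStats,
                            pairs: Iterable[PairAlignment]) -> int:
    rec = _edit_record(proposal, assembly)
    n = 0
    for pair in pairs:
        lifted = lift_pair([rec], pair)
        if lifted is not None and classify_pair(lifted, stats) is PairClass.CONCORDANT:
            n += 1
    return n


def _near_end(locus: ClusterLocus, length: int, reach: float) -> str | None:
    center = (locus.start + locus.end) / 2
    d_left, d_right = center, length - center
    if min(d_left, d_right) > reach:
        return None
    return "left" if d_left <= d_right else "right"


def _gaps_between(seq: str, lo: int, hi: int) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"N+", seq)
            if m.start() >= lo and m.end() <= hi]


def propose_edits(clusters: Sequence[DiscordantCluster], assembly: Assembly,
                  stats: LibraryStats, min_cluster: int = 5,
                  min_support_fraction: float = 0.8) -> list[EditProposal]:
    """Turn discordant clusters into fusion/junction proposals.

    Fusion: both ends of a donor scaffold link to two loci of one recipient
    flanking an N-gap (or within one insert of each other).  Junction:
    terminal windows of two scaffolds link end-to-end.  The orientation
    making the supporting pairs concordant is chosen; contradictions reject
    the proposal.
    """
    reach = stats.insert_max
    by_pair: dict[tuple[str, str], list[DiscordantCluster]] = {}
    for cl in clusters:
        if cl.locus_1.scaffold == cl.locus_2.scaffold:
            continue
        by_pair.setdefault((cl.locus_1.scaffold, cl.locus_2.scaffold), []).append(cl)

    proposals: list[EditProposal] = []
    for (sa, sb), cls_list in sorted(by_pair.items()):
        la, lb = assembly.length_of(sa), assembly.length_of(sb)
        ends_a = [_near_end(c.locus_1, la, reach) for c in cls_list]
        ends_b = [_near_end(c.locus_2, lb, reach) for c in cls_list]
        n_pairs = sum(c.n_pairs for c in cls_list)

        # candidate donor: every cluster terminal on one side, and both of
        # that scaffold's ends represented, while the other side is interior
        for donor, recip, d_ends, r_ends, flip in (
                (sb, sa, ends_b, ends_a, True), (sa, sb, ends_a, ends_b, False)):
            if None in d_ends or len(set(d_ends)) < 2:
                continue
            if any(e is not None for e in r_ends):
                continue
            r_loci = [c.locus_1 if flip else c.locus_2 for c in cls_list]
            lo = min(l.start for l in r_loci)
            hi = max(l.end for l in r_loci)
            inner_lo = min(l.end for l in r_loci)
            inner_hi = max(l.start for l in r_loci)
            gaps = _gaps_between(assembly.sequences[recip], inner_lo, inner_hi)
            if gaps:
                gaps.sort(key=lambda g: -(g[1] - g[0]))
                g0, g1 = gaps[0]
            elif inner_hi - inner_lo <= reach:
                g0 = g1 = (inner_lo + inner_hi) // 2
            else:
                continue
            support = [p for c in cls_list for p in c.pairs]
            best = None
            for orient in ("+", "-"):
                prop = EditProposal("fusion", donor, recip, orient, g0, g1,
                                    clusters=list(cls_list), n_pairs=n_pairs)
                n_ok = _count_concordant_after(prop, assembly, stats, support)
                if best is None or n_ok > best[0]:
                    best = (n_ok, prop)
            n_ok, prop = best
            prop.n_made_concordant = n_ok
            if n_ok < min_support_fraction * n_pairs:
                prop.status = "rejected"
                prop.reason = (f"no orientation renders supporting pairs concordant "
                               f"({n_ok}/{n_pairs})")
            proposals.append(prop)
            break
        else:
            # junction: every cluster terminal on both sides, consistent ends
            if None in ends_a or None in ends_b:
                continue
            if len(set(ends_a)) != 1 or len(set(ends_b)) != 1:
                continue
            end_a, end_b = ends_a[0], ends_b[0]
            if end_a == "right":
                left, right = sa, sb
                left_flip = False
                right_flip = end_b == "right"
            else:
                left, right = sb, sa
                left_flip = end_b == "left"
                right_flip = False
            orientation = "-" if (left_flip or right_flip) else "+"
            prop = EditProposal("junction", donor=sb, recipient=sa,
                                orientation=orientation, left=left, right=right,
                                left_flip=left_flip, right_flip=right_flip,
                                clusters=list(cls_list), n_pairs=n_pairs)
            support = [p for c in cls_list for p in c.pairs]
            n_ok = _count_concordant_after(prop, assembly, stats, support)
            prop.n_made_concordant = n_ok
            if n_ok < min_support_fraction * n_pairs:
                prop.status = "rejected"
                prop.reason = (f"end-to-end geometry inconsistent with pair "
                               f"orientations ({n_ok}/{n_pairs})")
            proposals.append(prop)
    return proposals


# ---------------------------------------------------------------------------
# application and validation


def apply_edit(assembly: Assembly, proposal: EditProposal,
               max_overfill: int = 2000) -> None:
    """Apply an accepted proposal; records joint coordinates for validation."""
    if proposal.status == "rejected":
        raise ValueError(f"refusing to apply rejected proposal: {proposal.reason}")
    if proposal.kind == "fusion":
        donor_len = assembly.length_of(proposal.donor)
        gap_len = proposal.gap_end - proposal.gap_start
        if donor_len > gap_len + max_overfill:
            proposal.status = "rejected"
            proposal.reason = (f"donor ({donor_len} bp) overfills gap ({gap_len} bp) "
                               f"beyond slack {max_overfill}")
            return
        assembly.fuse(proposal.donor, proposal.recipient, proposal.gap_start,
                      proposal.gap_end, proposal.orientation)
        rec = assembly.ledger.records[-1]
        j1 = rec["gap_start"] + rec["left_pad"]
        proposal.joints = [j1, j1 + rec["donor_len"]]
        proposal.result = proposal.recipient
    else:
        result = assembly.join(proposal.left, proposal.right, proposal.left_flip,
                               proposal.right_flip)
        rec = assembly.ledger.records[-1]
        proposal.joints = [rec["left_len"] + rec["gap"] // 2]
        proposal.result = result
    proposal.status = "applied"


@dataclass
class ValidationVerdict:
    passed: bool
    reason: str
    per_joint_support: list[int]
    local_discordant: float
    baseline_discordant: float


def validate_edit(proposal: EditProposal, lifted_pairs: Sequence[PairAlignment],
                  stats: LibraryStats, min_validate: int = 5,
                  disc_margin: float = 0.15) -> ValidationVerdict:
    """PASS iff every new joint is spanned by >= ``min_validate`` concordant
    lifted pairs and local discordance stays near the scaffold baseline."""
    scaf = proposal.result
    on_scaf = [p for p in lifted_pairs
               if p.scaffold_1 == scaf or p.scaffold_2 == scaf]
    classes = [classify_pair(p, stats) for p in on_scaf]
    baseline = discordant_fraction(classes)
    support = []
    local_disc = 0.0
    reach = stats.insert_max
    for joint in proposal.joints:
        n_span = 0
        n_local = 0
        n_local_disc = 0
        for p, cls in zip(on_scaf, classes):
            if p.scaffold_1 != scaf or p.scaffold_2 != scaf:
                near = any(abs(pos - joint) <= reach for s, pos in
                           ((p.scaffold_1, p.pos_1), (p.scaffold_2, p.pos_2))
                           if s == scaf)
                if near:
                    n_local += 1
                    n_local_disc += 1
                continue
            lo = min(p.pos_1, p.pos_2)
            hi = max(p.pos_1, p.pos_2) + p.read_length
            if lo <= joint <= hi:
                n_span += 1 if cls is PairClass.CONCORDANT else 0
            if lo - reach <= joint <= hi + reach:
                n_local += 1
                if cls is not PairClass.CONCORDANT:
                    n_local_disc += 1
        support.append(n_span)
        if n_local:
            local_disc = max(local_disc, n_local_disc / n_local)
    if not any(support):
        return ValidationVerdict(False, "no evidence: no pairs span the new joint",
                                 support, local_disc, baseline)
    if min(support) < min_validate:
        return ValidationVerdict(False, f"only {min(support)} concordant spanning "
                                 f"pairs (< {min_validate})", support, local_disc, baseline)
    if local_disc > baseline + disc_margin:
        return ValidationVerdict(False, f"local discordant fraction {local_disc:.2f} "
                                 f"exceeds baseline {baseline:.2f} + {disc_margin}",
                                 support, local_disc, baseline)
    return ValidationVerdict(True, "", support, local_disc, baseline)


# ---------------------------------------------------------------------------
# textual region report (tabular stand-in for the circos view)


def region_report(scaffold: str, scaffold_length: int,
                  pairs: Sequence[PairAlignment], classes: Sequence[PairClass],
                  window: int) -> dict:
    """Windowed pair-class counts plus the inter-locus link list."""
    import pandas as pd

    nw = max(1, -(-scaffold_length // window))
    counts = {cls.value: np.zeros(nw, dtype=int) for cls in PairClass}
    links: dict[tuple, int] = {}
    for pair, cls in zip(pairs, classes):
        for scaf, pos in ((pair.scaffold_1, pair.pos_1), (pair.scaffold_2, pair.pos_2)):
            if scaf == scaffold:
                w = min(pos // window, nw - 1)
                counts[cls.value][w] += 1
        if cls is not PairClass.CONCORDANT and scaffold in (pair.scaffold_1, pair.scaffold_2):
            key = (cls.value, pair.scaffold_1, pair.pos_1 // window,
                   pair.scaffold_2, pair.pos_2 // window)
            links[key] = links.get(key, 0) + 1
    windows = pd.DataFrame({
        "scaffold": scaffold,
        "start": [i * window for i in range(nw)],
        "end": [min((i + 1) * window, scaffold_length) for i in range(nw)],
        **counts,
    })
    link_rows = sorted(({"class": k[0], "scaffold_1": k[1],
                         "window_1": k[2] * window, "scaffold_2": k[3],
                         "window_2": k[4] * window, "n_reads": v}
                        for k, v in links.items()),
                       key=lambda r: (r["class"], -r["n_reads"], r["scaffold_1"],
                                      r["window_1"], r["scaffold_2"], r["window_2"]))
    return {"windows": windows, "links": pd.DataFrame(link_rows)}
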