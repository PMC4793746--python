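"""End-to-end orchestration plus the ledger-based liftover utilities.

Stage order mirrors the improvement workflow: misassembly splitting,
fusion/junction remodelling, gap re-estimation, optional super-scaffolding
from a genome-map placement table, renaming by length, and anchoring into
pseudo-molecules.  Every stage is optional and everything it does is
recorded in the assembly's edit ledger.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence


from . import anchoring, gaps, markers, misassembly, remodler
from .assembly import Assembly, EditLedger
from .io_formats.agp import AgpRow
from .io_formats.gff3 import Gff3Feature
from .io_formats.marker_matrix import MarkerMatrixRow
from .readpairs import (LibraryStats, PairAlignment, classify_all, default_window,
                        discordant_fraction, discordant_fraction_track,
                        dedup_pairs, estimate_library_stats,
                        spanning_coverage_track)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    # stage toggles
    do_split: bool = True
    do_remodel: bool = True
    do_gaps: bool = True
    do_superscaffold: bool = False
    do_rename: bool = True
    do_anchor: bool = True
    # thresholds
    lod_threshold: float = 10.0
    majority: float = 2 / 3
    min_block: int = 3
    span_floor: float = 0.0
    disc_ceiling: float = 0.5
    min_cluster: int = 5
    min_validate: int = 5
    gap_min_pairs: int = 30
    min_orient_markers: int = 2
    anchor_seed: int = 42
    anchor_restarts: int = 10
    library_stats: LibraryStats | None = None  # estimated when None


@dataclass
class PipelineResult:
    assembly: Assembly
    stats: LibraryStats
    breakpoints: list = field(default_factory=list)
    proposals: list = field(default_factory=list)
    verdicts: list = field(default_factory=list)
    gap_report: list = field(default_factory=list)
    orders: list = field(default_factory=list)
    agp_rows: list[AgpRow] = field(default_factory=list)
    unanchored: list[str] = field(default_factory=list)
    discordant_before: float = 0.0
    discordant_after: float = 0.0


def lift_placements(records: Sequence[dict],
                    placements: Sequence[markers.MarkerPlacement]) -> list[markers.MarkerPlacement]:
    """Lift marker placements through ledger records (flagged/lost ones are
    dropped)."""
    from .assembly import LiftedInterval, _lift_one

    out = []
    for p in placements:
        if p.scaffold is None:
            out.append(p)
            continue
        frags = [LiftedInterval(p.scaffold, p.position, p.position + 1)]
        for rec in records:
            nxt = []
            for fr in frags:
                nxt.extend(_lift_one(rec, fr))
            frags = nxt
        if len(frags) != 1 or frags[0].flags:
            continue
        fr = frags[0]
        strand = p.strand
        if fr.flipped and strand in ("+", "-"):
            strand = "-" if strand == "+" else "+"
        out.append(markers.MarkerPlacement(p.marker_id, fr.scaffold, fr.start,
                                           strand, p.linkage_group, p.status))
    return out


def run_pipeline(assembly: Assembly, pairs: Sequence[PairAlignment],
                 individuals: Sequence[str], marker_rows: Sequence[MarkerMatrixRow],
                 probes: Sequence[tuple[str, str]],
                 config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    ledger_start = len(assembly.ledger)

    pairs = dedup_pairs(pairs)
    stats = config.library_stats or estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    disc_before = discordant_fraction(classes)
    window = default_window(stats)

    kept_rows, _ = markers.filter_markers(marker_rows)
    lod = markers.lod_matrix(kept_rows)
    groups = markers.group_markers(lod, config.lod_threshold)
    kept_ids = {r.marker_id for r in kept_rows}
    placements = markers.place_markers([p for p in probes if p[0] in kept_ids],
                                       assembly.sequences)
    assignment = markers.assign_scaffolds(placements, groups, config.majority,
                                          config.min_block)

    result = PipelineResult(assembly, stats)
    result.discordant_before = disc_before

    # -- stage 1: misassembly splitting ---------------------------------
    if config.do_split:
        candidates = misassembly.find_conflict_candidates(
            assignment.placements, assignment.misassembly_candidates,
            config.min_block)
        for cand in candidates:
            seq = assembly.sequences[cand.scaffold]
            scaf_pairs = [p for p in pairs
                          if cand.scaffold in (p.scaffold_1, p.scaffold_2)]
            scaf_classes = [c for p, c in zip(pairs, classes)
                            if cand.scaffold in (p.scaffold_1, p.scaffold_2)]
            span = spanning_coverage_track(scaf_pairs, scaf_classes,
                                           cand.scaffold, len(seq), window)
            disc = discordant_fraction_track(scaf_pairs, scaf_classes,
                                             cand.scaffold, len(seq), window)
            call = misassembly.locate_breakpoint(cand, seq, span, disc,
                                                 config.span_floor,
                                                 config.disc_ceiling)
            result.breakpoints.append(call)
        # apply right-to-left per scaffold so earlier positions stay valid
        for call in sorted((c for c in result.breakpoints
                            if c.chosen_split_pos is not None),
                           key=lambda c: (c.scaffold, -c.chosen_split_pos)):
            misassembly.split_scaffold(assembly, call.scaffold, call.chosen_split_pos)
            log.info("split %s at %d (LGs %s|%s)", call.scaffold,
                     call.chosen_split_pos, call.left_lg, call.right_lg)

    # -- stage 2: fusion / junction remodelling -------------------------
    if config.do_remodel:
        new_records = assembly.ledger.records[ledger_start:]
        cur_pairs = remodler.lift_pairs(new_records, pairs) if new_records else list(pairs)
        cur_classes = classify_all(cur_pairs, stats)
        clusters = remodler.cluster_discordant(cur_pairs, cur_classes, stats,
                                               config.min_cluster)
        proposals = remodler.propose_edits(clusters, assembly, stats,
                                           config.min_cluster)
        step0 = len(assembly.ledger)
        for prop in proposals:
            if prop.status == "rejected":
                log.warning("rejected %s %s->%s: %s", prop.kind, prop.donor,
                            prop.recipient, prop.reason)
                continue
            if prop.kind == "fusion" and prop.donor not in assembly:
                prop.status = "rejected"
                prop.reason = "donor already consumed by an earlier edit"
                continue
            if prop.kind == "junction" and (prop.left not in assembly
                                            or prop.right not in assembly):
                prop.status = "rejected"
                prop.reason = "scaffold already consumed by an earlier edit"
                continue
            remodler.apply_edit(assembly, prop)
            if prop.status == "applied":
                log.info("applied %s of %s into %s (%d supporting pairs)",
                         prop.kind, prop.donor, prop.recipient, prop.n_pairs)
        applied_records = assembly.ledger.records[step0:]
        lifted = remodler.lift_pairs(applied_records, cur_pairs)
        for prop in proposals:
            if prop.status == "applied":
                verdict = remodler.validate_edit(prop, lifted, stats,
                                                 config.min_validate)
                prop.status = "validated" if verdict.passed else prop.status
                result.verdicts.append((prop, verdict))
        result.proposals = proposals

    # -- stage 3: gap re-estimation -------------------------------------
    if config.do_gaps:
        new_records = assembly.ledger.records[ledger_start:]
        cur_pairs = remodler.lift_pairs(new_records, pairs) if new_records else list(pairs)
        result.gap_report = gaps.reestimate_all(
            assembly, [(stats, cur_pairs, config.gap_min_pairs)])

    # -- stage 4: rename by decreasing length ---------------------------
    if config.do_rename:
        assembly.rename_by_length()

    # -- stage 5: anchoring ---------------------------------------------
    if config.do_anchor:
        new_records = assembly.ledger.records[ledger_start:]
        lifted_pl = lift_placements(new_records, placements)
        assignment2 = markers.assign_scaffolds(lifted_pl, groups, config.majority,
                                               config.min_block)
        marker_counts: dict[str, int] = {}
        for p in assignment2.placements:
            if p.status == "kept" and p.scaffold in assignment2.assignments:
                marker_counts[p.scaffold] = marker_counts.get(p.scaffold, 0) + 1
        orders = []
        for lg in sorted(set(assignment2.assignments.values())):
            ctx = anchoring.make_lg_context(lg, assignment2.assignments,
                                            assignment2.placements, lod)
            init = anchoring.initial_order_upgma(ctx)
            best = anchoring.optimize_order(ctx, init, config.anchor_seed,
                                            config.anchor_restarts)
            orders.append(best)
        molecules, unanchored = anchoring.build_pseudomolecules(
            assembly, orders, marker_counts, config.min_orient_markers)
        result.orders = orders
        result.unanchored = unanchored
        result.agp_rows = [row for mol in molecules for row in mol.agp_rows]

    new_records = assembly.ledger.records[ledger_start:]
    final_pairs = remodler.lift_pairs(new_records, pairs) if new_records else list(pairs)
    result.discordant_after = discordant_fraction(classify_all(final_pairs, stats))
    return result


# ---------------------------------------------------------------------------
# annotation liftover


def lift_coordinates(ledger: EditLedger, scaffold: str, pos: int):
    """(new_scaffold, new_pos, strand_flip, flags) for a 0-based position."""
    fr = ledger.lift_point(scaffold, pos)
    return fr.scaffold, fr.start, fr.flipped, fr.flags


def lift_gff3(ledger: EditLedger, features: Sequence[Gff3Feature]) -> list[Gff3Feature]:
    """Lift features through the ledger; features broken across post-edit
    scaffolds come back as flagged fragments."""
    out: list[Gff3Feature] = []
    for feat in features:
        frags = ledger.lift_interval(feat.seqid, feat.start - 1, feat.end)
        frags = [fr for fr in frags if fr.end > fr.start]
        for i, fr in enumerate(frags):
            strand = feat.strand
            if fr.flipped and strand in ("+", "-"):
                strand = "-" if strand == "+" else "+"
            attrs = feat.attributes
            if len(frags) > 1:
                attrs = f"{attrs};split_lift={i + 1}/{len(frags)}"
            if fr.flags:
                attrs = f"{attrs};lift_flags={','.join(fr.flags)}"
            out.append(Gff3Feature(fr.scaffold, feat.source, feat.ftype,
                                   fr.start + 1, fr.end, feat.score, strand,
                                   feat.phase, attrs))
    return out


def consensus_annotation(primary: Sequence[Gff3Feature],
                         secondary: Sequence[Gff3Feature],
                         gene_type: str = "gene") -> list[Gff3Feature]:
    """All primary genes, plus secondary genes overlapping no primary gene
    on the same sequence and strand."""
    out = [Gff3Feature(f.seqid, f.source, f.ftype, f.start, f.end, f.score,
                       f.strand, f.phase, f"{f.attributes};consensus_source=primary")
           for f in primary]
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for f in primary:
        if f.ftype == gene_type:
            by_key.setdefault((f.seqid, f.strand), []).append((f.start, f.end))
    for f in secondary:
        if f.ftype != gene_type:
            continue
        spans = by_key.get((f.seqid, f.strand), [])
        if any(f.start <= e and s <= f.end for s, e in spans):
            continue
        out.append(Gff3Feature(f.seqid, f.source, f.ftype, f.start, f.end,
                               f.score, f.strand, f.phase,
                               f"{f.attributes};consensus_source=secondary"))
    return out


# ---------------------------------------------------------------------------
# in-silico digest and super-scaffolding periphery


@dataclass
class DigestMap:
    scaffold: str
    positions: list[int]  # 0-based motif start positions, both strands
    length: int

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def in_silico_digest(sequences: dict[str, str], motif: str = "GCTCTTC",
                     min_length: int = 20_000,
                     min_sites: int = 5) -> tuple[list[DigestMap], list[DigestMap]]:
    """Nicking-site maps per scaffold (motif and reverse complement).

    Returns (kept, excluded): kept scaffolds are strictly longer than
    ``min_length`` with strictly more than ``min_sites`` sites.
    """
    from .assembly import revcomp

    rc = revcomp(motif)
    kept, excluded = [], []
    for scaf, seq in sequences.items():
        positions = sorted(
            [m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq)]
            + ([m.start() for m in re.finditer(f"(?={re.escape(rc)})", seq)]
               if rc != motif else [])
        )
        dm = DigestMap(scaf, positions, len(seq))
        if dm.length > min_length and dm.n_sites > min_sites:
            kept.append(dm)
        else:
            excluded.append(dm)
    return kept, excluded


def superscaffold_from_placement(assembly: Assembly,
                                 placements: Sequence[tuple[str, str, int, int, str]],
                                 min_gap: int = 10) -> list[str]:
    """Group scaffolds into super-scaffolds from a genome-map placement
    table of (map_id, scaffold, start, end, orientation) rows; inter-
    placement distances become N-gaps (floored at ``min_gap``).

    Returns the names of the created super-scaffolds.
    """
    by_map: dict[str, list[tuple[int, int, str, str]]] = {}
    for map_id, scaf, start, end, orient in placements:
        by_map.setdefault(map_id, []).append((start, end, scaf, orient))
    created = []
    for map_id in sorted(by_map):
        rows = sorted(by_map[map_id])
        for (s1, e1, n1, _), (s2, e2, n2, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise ValueError(f"map {map_id}: placements of {n1} and {n2} overlap")
        if len(rows) < 2:
            continue
        comps = []
        off = 0
        prev_end = None
        for start, end, scaf, orient in rows:
            if prev_end is not None:
                off += max(min_gap, start - prev_end)
            L = assembly.length_of(scaf)
            comps.append({"id": scaf, "start": off, "strand": orient, "length": L})
            off += L
            prev_end = end
        name = f"super_{map_id}"
        assembly.superscaffold(name, comps)
        created.append(name)
    return created
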