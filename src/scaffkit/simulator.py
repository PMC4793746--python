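"""Truth-annotated synthetic dataset generator.

Produces a multi-chromosome genome, a flawed scaffold assembly with
planted errors (chimeric joins, excisions awaiting fusion, adjacent splits
awaiting junction, mis-sized gaps), mate pairs drawn on the TRUE genome
and mapped through provenance onto scaffold coordinates, and an F2-type
selfed marker population under the Haldane mapping function.

Everything is deterministic given ``SimConfig.seed``; each stage draws
from its own child stream so stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .assembly import Assembly, revcomp
from .io_formats.fasta import SequenceRecord
from .io_formats.marker_matrix import MarkerMatrixRow
from .readpairs import PairAlignment

_STAGES = {"genome": 1, "assembly": 2, "pairs": 3, "population": 4}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    # genome / assembly
    n_chromosomes: int = 3
    chromosome_length: int = 800_000
    n_scaffolds: int = 33
    inter_scaffold_gap: int = 10_000  # genome skipped between scaffold tiles
    gaps_per_scaffold: int = 2
    gap_length: int = 500
    orient_random: bool = True
    # planted errors
    n_chimera: int = 0
    n_excision: int = 0
    n_adjacent_split: int = 0
    n_gap_missize: int = 0
    excision_length: int = 8_000
    missize_delta: int = 400
    chimera_gap: int = 100
    # mate pairs
    insert_median: float = 5_000.0
    insert_sd: float = 500.0
    read_length: int = 100
    pair_coverage: float = 20.0  # physical (fragment) coverage of the genome
    duplicate_rate: float = 0.02
    # population
    n_markers: int = 198
    fraction_dominant: float = 0.3
    n_individuals: int = 180
    map_length_morgans: float = 1.0  # per chromosome
    missing_rate: float = 0.05
    genotyping_error_rate: float = 0.01
    probe_length: int = 69

    def __post_init__(self):
        for name in ("duplicate_rate", "missing_rate", "genotyping_error_rate",
                     "fraction_dominant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_scaffolds < self.n_chromosomes:
            raise SimulationError("need at least one scaffold per chromosome")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGES[stage]])


# ---------------------------------------------------------------------------
# provenance pieces


@dataclass
class SegPiece:
    """Scaffold piece copied from the genome (0-based half-open)."""
    chrom: str
    start: int
    end: int
    strand: str

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GapPiece:
    """N-run; ``span`` is the genome interval it stands in for (None for a
    chimeric joint that corresponds to no genome sequence)."""
    n_len: int
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def true_length(self) -> int | None:
        if self.chrom is None:
            return None
        return self.end - self.start

    def length(self) -> int:
        return self.n_len


Piece = SegPiece | GapPiece


def _piece_to_json(p: Piece) -> dict:
    d = asdict(p)
    d["kind"] = "seg" if isinstance(p, SegPiece) else "gap"
    return d


def _piece_from_json(d: dict) -> Piece:
    d = dict(d)
    kind = d.pop("kind")
    return SegPiece(**d) if kind == "seg" else GapPiece(**d)


@dataclass
class TruthSet:
    scaffold_provenance: dict[str, list[Piece]] = field(default_factory=dict)
    planted_errors: list[dict] = field(default_factory=list)
    true_marker_map: dict[str, dict] = field(default_factory=dict)
    true_order: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "scaffold_provenance": {
                k: [_piece_to_json(p) for p in v]
                for k, v in self.scaffold_provenance.items()
            },
            "planted_errors": self.planted_errors,
            "true_marker_map": self.true_marker_map,
            "true_order": {k: [list(t) for t in v] for k, v in self.true_order.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            scaffold_provenance={k: [_piece_from_json(p) for p in v]
                                 for k, v in d["scaffold_provenance"].items()},
            planted_errors=d["planted_errors"],
            true_marker_map=d["true_marker_map"],
            true_order={k: [tuple(t) for t in v] for k, v in d["true_order"].items()},
        )

    def errors_of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.planted_errors if e["kind"] == kind]


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> list[SequenceRecord]:
    rng = config.rng("genome")
    out = []
    for i in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chromosome_length)
        seq = np.take(_BASES, idx).tobytes().decode()
        out.append(SequenceRecord(f"chr{i + 1:02d}", seq))
    return out


# ---------------------------------------------------------------------------
# flawed assembly


def _piece_seq(piece: Piece, genome: dict[str, str]) -> str:
    if isinstance(piece, GapPiece):
        return "N" * piece.n_len
    seq = genome[piece.chrom][piece.start:piece.end]
    return seq if piece.strand == "+" else revcomp(seq)


def build_scaffold_sequence(pieces: Sequence[Piece], genome: dict[str, str]) -> str:
    return "".join(_piece_seq(p, genome) for p in pieces)


def _flip_pieces(pieces: list[Piece]) -> list[Piece]:
    out: list[Piece] = []
    for p in reversed(pieces):
        if isinstance(p, SegPiece):
            out.append(SegPiece(p.chrom, p.start, p.end, "-" if p.strand == "+" else "+"))
        else:
            out.append(GapPiece(p.n_len, p.chrom, p.start, p.end))
    return out


def _cut_pieces(pieces: list[Piece], pos: int) -> tuple[list[Piece], list[Piece]]:
    """Split a piece list at scaffold coordinate ``pos``."""
    left: list[Piece] = []
    right: list[Piece] = []
    off = 0
    for p in pieces:
        L = p.length()
        if off + L <= pos:
            left.append(p)
        elif off >= pos:
            right.append(p)
        else:
            k = pos - off
            if isinstance(p, SegPiece):
                if p.strand == "+":
                    left.append(SegPiece(p.chrom, p.start, p.start + k, "+"))
                    right.append(SegPiece(p.chrom, p.start + k, p.end, "+"))
                else:
                    left.append(SegPiece(p.chrom, p.end - k, p.end, "-"))
                    right.append(SegPiece(p.chrom, p.start, p.end - k, "-"))
            else:
                # cutting inside a gap: apportion Ns; genome span follows N split
                if p.chrom is None:
                    left.append(GapPiece(k))
                    right.append(GapPiece(p.n_len - k))
                else:
                    mid = p.start + min(p.end - p.start, k)
                    left.append(GapPiece(k, p.chrom, p.start, mid))
                    right.append(GapPiece(p.n_len - k, p.chrom, mid, p.end))
        off += L
    return left, right


def _seg_regions(pieces: list[Piece]) -> list[tuple[int, int]]:
    """Scaffold-coordinate intervals covered by seg pieces."""
    out = []
    off = 0
    for p in pieces:
        if isinstance(p, SegPiece):
            out.append((off, off + p.length()))
        off += p.length()
    return out


def make_flawed_assembly(genome: list[SequenceRecord],
                         config: SimConfig) -> tuple[Assembly, TruthSet]:
    rng = config.rng("assembly")
    gdict = {r.id: r.sequence for r in genome}

    # --- tile chromosomes into scaffolds -------------------------------
    per_chr = [config.n_scaffolds // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_scaffolds % config.n_chromosomes):
        per_chr[i] += 1
    tiles: list[tuple[str, list[Piece]]] = []  # (chrom, pieces)
    for rec, k in zip(genome, per_chr):
        L = len(rec.sequence)
        gap = config.inter_scaffold_gap
        usable = L - (k + 1) * gap
        if usable < k * (4 * config.gap_length + 2000):
            raise SimulationError("chromosomes too short for requested scaffold count")
        tile_len = usable // k
        for t in range(k):
            start = gap + t * (tile_len + gap)
            end = start + tile_len
            pieces: list[Piece] = []
            cur = start
            # interior gaps at even fractions, jittered
            for gi in range(config.gaps_per_scaffold):
                frac = (gi + 1) / (config.gaps_per_scaffold + 1)
                g0 = start + int(frac * tile_len) + int(rng.integers(-200, 201))
                g0 = max(cur + 1000, min(g0, end - config.gap_length - 1000))
                if g0 <= cur:
                    continue
                pieces.append(SegPiece(rec.id, cur, g0, "+"))
                pieces.append(GapPiece(config.gap_length, rec.id, g0, g0 + config.gap_length))
                cur = g0 + config.gap_length
            pieces.append(SegPiece(rec.id, cur, end, "+"))
            if config.orient_random and rng.random() < 0.5:
                pieces = _flip_pieces(pieces)
            tiles.append((rec.id, pieces))

    # --- plant errors ---------------------------------------------------
    truth = TruthSet()
    n_err = config.n_chimera * 2 + config.n_excision + config.n_adjacent_split + config.n_gap_missize
    if n_err > len(tiles):
        raise SimulationError(f"{n_err} scaffolds needed for planted errors, have {len(tiles)}")
    pool = list(rng.permutation(len(tiles)))
    scaffolds: list[dict] = []   # {pieces, chrom or None, error}
    consumed: set[int] = set()

    def take(predicate=None) -> int:
        for idx in list(pool):
            if idx in consumed:
                continue
            if predicate is None or predicate(idx):
                pool.remove(idx)
                consumed.add(idx)
                return idx
        raise SimulationError("not enough eligible scaffolds for planted errors")

    margin = int(config.insert_median + 3 * config.insert_sd)

    eid_counter = [0]

    def new_eid() -> int:
        eid_counter[0] += 1
        return eid_counter[0]

    chimera_parts: list[dict] = []
    for _ in range(config.n_chimera):
        i = take()
        j = take(lambda x, ci=tiles[i][0]: tiles[x][0] != ci)
        pa, pb = tiles[i][1], tiles[j][1]
        la = sum(p.length() for p in pa)
        pieces = pa + [GapPiece(config.chimera_gap)] + pb
        chimera_parts.append({
            "pieces": pieces,
            "error": {"kind": "chimera", "eid": new_eid(),
                      "true_split_pos": la + config.chimera_gap // 2,
                      "chromosomes": [tiles[i][0], tiles[j][0]]},
        })

    excisions: list[dict] = []
    for _ in range(config.n_excision):
        i = take()
        chrom, pieces = tiles[i]
        total = sum(p.length() for p in pieces)
        segs = _seg_regions(pieces)
        # region must sit inside one seg run, clear of ends (two insert
        # widths, so flank clusters are unambiguously interior) and gap edges
        exc_margin = 2 * margin
        spots = []
        for s, e in segs:
            lo = max(s + 1000, exc_margin)
            hi = min(e - 1000, total - exc_margin) - config.excision_length
            if hi > lo:
                spots.append((lo, hi))
        # allow the excised region to contain an interior gap: search over the
        # whole scaffold too, requiring only seg flanks
        x = None
        for lo, hi in spots:
            x = int(rng.integers(lo, hi))
            break
        if x is None:
            lo, hi = exc_margin, total - exc_margin - config.excision_length
            for _try in range(50):
                cand = int(rng.integers(lo, hi))
                in_seg = lambda pos: any(s + 200 <= pos <= e - 200 for s, e in segs)
                if in_seg(cand) and in_seg(cand + config.excision_length):
                    x = cand
                    break
        if x is None:
            raise SimulationError("no eligible excision site")
        left, rest = _cut_pieces(pieces, x)
        mid, right = _cut_pieces(rest, config.excision_length)
        true_span = sum(p.length() for p in mid)
        donor_pieces = left + [GapPiece(true_span, None, None, None)] + right
        # record genome span of the excised region on the gap for base truth
        free_flip = bool(rng.random() < 0.5)
        free_pieces = _flip_pieces(mid) if free_flip else mid
        excisions.append({
            "donor_pieces": donor_pieces, "free_pieces": free_pieces,
            "chrom": chrom,
            "error": {"kind": "excision_for_fusion", "eid": new_eid(), "gap_start": x,
                      "gap_end": x + true_span, "true_length": true_span,
                      "orientation": "-" if free_flip else "+"},
        })

    splits: list[dict] = []
    for _ in range(config.n_adjacent_split):
        i = take()
        chrom, pieces = tiles[i]
        total = sum(p.length() for p in pieces)
        segs = _seg_regions(pieces)
        cand = [(max(s + margin, total // 3), min(e - margin, 2 * total // 3))
                for s, e in segs]
        cand = [(lo, hi) for lo, hi in cand if hi > lo]
        if not cand:
            cand = [(s + 1000, e - 1000) for s, e in segs if e - s > 2000]
        lo, hi = cand[len(cand) // 2]
        x = int(rng.integers(lo, hi))
        left, right = _cut_pieces(pieces, x)
        right_flip = bool(rng.random() < 0.5)
        splits.append({
            "left_pieces": left,
            "right_pieces": _flip_pieces(right) if right_flip else right,
            "chrom": chrom,
            "error": {"kind": "adjacent_split_for_junction", "eid": new_eid(),
                      "orientation": "-" if right_flip else "+"},
        })

    missized: list[dict] = []
    for _ in range(config.n_gap_missize):
        i = take(lambda x: any(isinstance(p, GapPiece) and p.chrom is not None
                               for p in tiles[x][1]))
        chrom, pieces = tiles[i]
        gap_idxs = [k for k, p in enumerate(pieces)
                    if isinstance(p, GapPiece) and p.chrom is not None]
        gi = int(rng.choice(gap_idxs))
        gp = pieces[gi]
        sign = 1 if rng.random() < 0.5 else -1
        new_n = max(50, gp.n_len + sign * config.missize_delta)
        if new_n == gp.true_length():
            new_n += config.missize_delta
        off = sum(p.length() for p in pieces[:gi])
        pieces = pieces[:gi] + [GapPiece(new_n, gp.chrom, gp.start, gp.end)] + pieces[gi + 1:]
        missized.append({
            "pieces": pieces, "chrom": chrom,
            "error": {"kind": "gap_missize", "gap_start": off,
                      "gap_end": off + new_n, "observed_length": new_n,
                      "true_length": gp.true_length()},
        })

    # --- name scaffolds and assemble truth -----------------------------
    final: list[dict] = []
    for idx, (chrom, pieces) in enumerate(tiles):
        if idx in consumed:
            continue
        final.append({"pieces": pieces, "chrom": chrom, "error": None})
    for ch in chimera_parts:
        final.append({"pieces": ch["pieces"], "chrom": None, "error": ch["error"]})
    for ex in excisions:
        final.append({"pieces": ex["donor_pieces"], "chrom": ex["chrom"],
                      "error": dict(ex["error"], role="donor")})
        final.append({"pieces": ex["free_pieces"], "chrom": ex["chrom"],
                      "error": dict(ex["error"], role="free")})
    for sp in splits:
        final.append({"pieces": sp["left_pieces"], "chrom": sp["chrom"],
                      "error": dict(sp["error"], role="left")})
        final.append({"pieces": sp["right_pieces"], "chrom": sp["chrom"],
                      "error": dict(sp["error"], role="right")})
    for ms in missized:
        final.append({"pieces": ms["pieces"], "chrom": ms["chrom"], "error": ms["error"]})

    def genome_key(entry):
        firsts = [p for p in entry["pieces"] if isinstance(p, SegPiece)]
        c = firsts[0].chrom
        lo = min(p.start for p in firsts)
        return (c, lo)

    final.sort(key=genome_key)
    sequences: dict[str, str] = {}
    err_groups: dict[int, dict] = {}
    for idx, entry in enumerate(final):
        name = f"scaf{idx + 1:04d}"
        entry["name"] = name
        sequences[name] = build_scaffold_sequence(entry["pieces"], gdict)
        truth.scaffold_provenance[name] = entry["pieces"]

    # collate planted-error records, pairing donor/free and left/right by eid
    by_eid: dict[int, dict] = {}
    for entry in final:
        err = entry["error"]
        if err is None:
            continue
        kind = err["kind"]
        if kind == "chimera":
            truth.planted_errors.append({
                "kind": "chimera", "scaffold": entry["name"],
                "true_split_pos": err["true_split_pos"],
                "chromosomes": err["chromosomes"],
            })
        elif kind == "gap_missize":
            truth.planted_errors.append({
                "kind": "gap_missize", "scaffold": entry["name"],
                "gap_start": err["gap_start"], "gap_end": err["gap_end"],
                "observed_length": err["observed_length"],
                "true_length": err["true_length"],
            })
        elif kind == "excision_for_fusion":
            rec = by_eid.setdefault(err["eid"], {
                "kind": kind, "gap_start": err["gap_start"], "gap_end": err["gap_end"],
                "true_length": err["true_length"], "orientation": err["orientation"],
            })
            rec["recipient" if err["role"] == "donor" else "donor"] = entry["name"]
        else:  # adjacent_split_for_junction
            rec = by_eid.setdefault(err["eid"], {
                "kind": kind, "orientation": err["orientation"],
            })
            rec[err["role"]] = entry["name"]
    truth.planted_errors.extend(by_eid.values())

    # --- true per-chromosome order (single-chromosome scaffolds only) ---
    for rec in genome:
        entries = []
        for entry in final:
            segs = [p for p in entry["pieces"] if isinstance(p, SegPiece)]
            chroms = {p.chrom for p in segs}
            if chroms != {rec.id}:
                continue
            mid = (min(p.start for p in segs) + max(p.end for p in segs)) / 2
            strand = segs[0].strand
            entries.append((mid, entry["name"], strand))
        entries.sort()
        truth.true_order[rec.id] = [(n, s) for _, n, s in entries]

    return Assembly(sequences), truth


# ---------------------------------------------------------------------------
# mate pairs


def _mapping_index(truth: TruthSet):
    """Per chromosome: sorted arrays of seg-piece genome intervals with the
    scaffold, scaffold offset and strand of each."""
    per_chrom: dict[str, list[tuple[int, int, str, int, str]]] = {}
    for scaf, pieces in truth.scaffold_provenance.items():
        off = 0
        for p in pieces:
            if isinstance(p, SegPiece):
                per_chrom.setdefault(p.chrom, []).append((p.start, p.end, scaf, off, p.strand))
            off += p.length()
    index = {}
    for chrom, items in per_chrom.items():
        items.sort()
        index[chrom] = {
            "start": np.array([i[0] for i in items]),
            "end": np.array([i[1] for i in items]),
            "items": items,
        }
    return index


def _map_read(index, chrom: str, a: int, b: int) -> tuple[str, int, str] | None:
    """Map genome interval [a, b) to (scaffold, leftmost pos, strand) if it
    lies entirely inside one seg piece."""
    ix = index.get(chrom)
    if ix is None:
        return None
    k = int(np.searchsorted(ix["start"], a, side="right")) - 1
    if k < 0:
        return None
    s, e, scaf, off, strand = ix["items"][k]
    if a < s or b > e:
        return None
    if strand == "+":
        return scaf, off + (a - s), "+"
    return scaf, off + (e - b), "-"


def simulate_mate_pairs(genome: list[SequenceRecord], truth: TruthSet,
                        config: SimConfig) -> list[PairAlignment]:
    """FR mate pairs drawn on the true genome and projected onto scaffolds.

    Fragments with both ends unmappable (e.g. both inside N-covered genome)
    are resampled; fragments with exactly one mappable end are dropped.
    """
    rng = config.rng("pairs")
    index = _mapping_index(truth)
    total = sum(len(r.sequence) for r in genome)
    lengths = np.array([len(r.sequence) for r in genome], dtype=float)
    n_pairs = int(round(config.pair_coverage * total / config.insert_median))
    RL = config.read_length
    out: list[PairAlignment] = []
    serial = 0
    need = n_pairs
    while need > 0:
        chroms = rng.choice(len(genome), size=need, p=lengths / lengths.sum())
        flens = rng.normal(config.insert_median, config.insert_sd, size=need)
        flens = np.maximum(flens, 2 * RL + 1).astype(int)
        next_need = 0
        for ci, fl in zip(chroms, flens):
            rec = genome[ci]
            if fl >= len(rec.sequence):
                next_need += 1
                continue
            start = int(rng.integers(0, len(rec.sequence) - fl))
            m1 = _map_read(index, rec.id, start, start + RL)
            m2 = _map_read(index, rec.id, start + fl - RL, start + fl)
            if m1 is None and m2 is None:
                next_need += 1  # resample
                continue
            if m1 is None or m2 is None:
                continue  # drop single-end-mappable fragment
            s1, p1, st1 = m1
            s2, p2, st2 = m2
            # read 2 is sequenced on the opposite genome strand (FR)
            st2 = "-" if st2 == "+" else "+"
            serial += 1
            pair = PairAlignment(f"frag{serial:08d}", s1, p1, st1, s2, p2, st2,
                                 RL, "sim5k")
            out.append(pair)
            if rng.random() < config.duplicate_rate:
                out.append(PairAlignment(pair.pair_id + "d", s1, p1, st1,
                                         s2, p2, st2, RL, "sim5k"))
        need = next_need
    return out


# ---------------------------------------------------------------------------
# F2 population


def scaffold_position_of(truth: TruthSet, chrom: str, gpos: int) -> tuple[str, int] | None:
    for scaf, pieces in truth.scaffold_provenance.items():
        off = 0
        for p in pieces:
            if isinstance(p, SegPiece) and p.chrom == chrom and p.start <= gpos < p.end:
                if p.strand == "+":
                    return scaf, off + (gpos - p.start)
                return scaf, off + (p.end - 1 - gpos)
            off += p.length()
    return None


def simulate_population(genome: list[SequenceRecord], config: SimConfig,
                        truth: TruthSet | None = None,
                        ) -> tuple[list[str], list[MarkerMatrixRow], list[tuple[str, str]], dict[str, dict]]:
    """Returns (individuals, marker rows, probes, true marker map).

    When ``truth`` is given, markers are allocated evenly across scaffolds
    (inside their genome source segments) so every scaffold is markered;
    otherwise positions are uniform along the genome.
    """
    rng = config.rng("population")
    gdict = {r.id: r.sequence for r in genome}
    half = config.probe_length // 2

    positions: list[tuple[str, int]] = []  # (chrom, genome pos)
    if truth is not None:
        scafs = sorted(truth.scaffold_provenance)
        # proportional to non-gap length (largest remainder)
        weights = np.array([sum(p.length() for p in truth.scaffold_provenance[s]
                                if isinstance(p, SegPiece)) for s in scafs], dtype=float)
        quota = config.n_markers * weights / weights.sum()
        per = np.floor(quota).astype(int)
        rest = np.argsort(-(quota - per))
        for i in rest[:config.n_markers - int(per.sum())]:
            per[i] += 1
        per = list(per)
        for scaf, k in zip(scafs, per):
            segs = [p for p in truth.scaffold_provenance[scaf] if isinstance(p, SegPiece)]
            lens = np.array([max(p.length() - 2 * half - 2, 1) for p in segs], dtype=float)
            for _ in range(k):
                for _try in range(100):
                    p = segs[int(rng.choice(len(segs), p=lens / lens.sum()))]
                    gpos = int(rng.integers(p.start + half + 1, p.end - half - 1))
                    if all(c != p.chrom or abs(gpos - q) > 150 for c, q in positions):
                        positions.append((p.chrom, gpos))
                        break
                else:
                    raise SimulationError("marker density exceeds available sequence")
    else:
        for _ in range(config.n_markers):
            for _try in range(100):
                ci = int(rng.integers(0, len(genome)))
                rec = genome[ci]
                gpos = int(rng.integers(half + 1, len(rec.sequence) - half - 1))
                if all(c != rec.id or abs(gpos - q) > 150 for c, q in positions):
                    positions.append((rec.id, gpos))
                    break
            else:
                raise SimulationError("marker density exceeds available sequence")

    positions.sort()
    m = len(positions)
    types = np.where(rng.random(m) < config.fraction_dominant,
                     np.where(rng.random(m) < 0.5, "dominant_a", "dominant_b"),
                     "codominant")
    phases = rng.integers(0, 2, size=m)  # 1 = allele labels swapped

    # gametes per chromosome (Haldane: r = (1 - exp(-2d))/2, d in Morgans)
    n = config.n_individuals
    geno = np.zeros((m, n), dtype=int)
    for rec in genome:
        idxs = [i for i, (c, _) in enumerate(positions) if c == rec.id]
        if not idxs:
            continue
        pos = np.array([positions[i][1] for i in idxs], dtype=float)
        d = np.diff(pos) / len(rec.sequence) * config.map_length_morgans
        r_adj = 0.5 * (1 - np.exp(-2 * d))
        gam = np.zeros((2 * n, len(idxs)), dtype=int)
        gam[:, 0] = rng.integers(0, 2, size=2 * n)
        rec_ev = rng.random((2 * n, len(idxs) - 1)) < r_adj
        for j in range(1, len(idxs)):
            gam[:, j] = gam[:, j - 1] ^ rec_ev[:, j - 1]
        g = gam[:n] + gam[n:]
        for col, i in enumerate(idxs):
            geno[i] = g[:, col]

    individuals = [f"ind{i + 1:03d}" for i in range(n)]
    rows: list[MarkerMatrixRow] = []
    probes: list[tuple[str, str]] = []
    true_map: dict[str, dict] = {}
    for i, (chrom, gpos) in enumerate(positions):
        mid = f"mk{i + 1:05d}"
        g = geno[i].copy()
        if phases[i] == 1:
            g = 2 - g
        codes = np.array(list("ahb"))[g]
        if types[i] == "dominant_b":
            codes = np.where(np.isin(codes, ["h", "b"]), "c", codes)
            valid = ["a", "c"]
        elif types[i] == "dominant_a":
            codes = np.where(np.isin(codes, ["a", "h"]), "d", codes)
            valid = ["b", "d"]
        else:
            valid = ["a", "h", "b"]
        err = rng.random(n) < config.genotyping_error_rate
        for j in np.nonzero(err)[0]:
            alts = [c for c in valid if c != codes[j]]
            codes[j] = alts[int(rng.integers(0, len(alts)))]
        codes = np.where(rng.random(n) < config.missing_rate, "u", codes)
        rows.append(MarkerMatrixRow(mid, str(types[i]), "".join(codes)))
        probes.append((mid, gdict[chrom][gpos - half:gpos - half + config.probe_length]))
        entry = {"chrom": chrom, "position": gpos, "type": str(types[i]),
                 "phase": int(phases[i])}
        if truth is not None:
            sp = scaffold_position_of(truth, chrom, gpos)
            if sp is not None:
                entry["scaffold"], entry["scaffold_pos"] = sp
        true_map[mid] = entry
    if truth is not None:
        truth.true_marker_map = true_map
    return individuals, rows, probes, true_map


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SimDataset:
    config: SimConfig
    genome: list[SequenceRecord]
    assembly: Assembly
    truth: TruthSet
    pairs: list[PairAlignment]
    individuals: list[str]
    marker_rows: list[MarkerMatrixRow]
    probes: list[tuple[str, str]]


def simulate_dataset(config: SimConfig) -> SimDataset:
    genome = simulate_genome(config)
    assembly, truth = make_flawed_assembly(genome, config)
    pairs = simulate_mate_pairs(genome, truth, config)
    individuals, rows, probes, _ = simulate_population(genome, config, truth)
    return SimDataset(config, genome, assembly, truth, pairs, individuals, rows, probes)


def write_dataset(ds: SimDataset, outdir: str | Path) -> None:
    from .io_formats import write_fasta, write_marker_matrix
    from .io_formats.sam import write_sam_pairs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fasta", [(r.id, r.sequence) for r in ds.genome])
    write_fasta(outdir / "scaffolds.fasta", ds.assembly.sequences.items())
    write_sam_pairs(outdir / "pairs.sam", ds.pairs, ds.assembly.sequences)
    write_marker_matrix(outdir / "markers.tsv", ds.individuals, ds.marker_rows)
    write_fasta(outdir / "probes.fasta", ds.probes)
    (outdir / "truth.json").write_text(ds.truth.to_json())
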