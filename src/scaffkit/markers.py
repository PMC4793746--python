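"""Genotype filtering, two-point linkage LOD, grouping and marker placement.

The two-point model is an F2 from a selfed heterozygote: both parental
meioses recombine independently with fraction r.  Each meiosis produces a
two-locus gamete with probabilities (1-r)/2 for the parental and r/2 for
the recombinant classes (coupling phase); the repulsion phase swaps allele
labels at the second locus.  Observations are genotype classes, with
dominant codes marginalised over their compatible genotypes:

    a={AA}  h={Aa}  b={aa}  c="not a"={Aa,aa}  d="not b"={AA,Aa}

r is estimated by EM on the expected number of recombinant meioses; both
phases are evaluated and the better likelihood kept.  LOD is
log10 L(r_hat) - log10 L(0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .assembly import revcomp
from .io_formats.marker_matrix import MarkerMatrixRow

# observation codes (u excluded; pairwise-complete individuals only)
CODES = "ahbcd"
CODE_INDEX = {c: i for i, c in enumerate(CODES)}
# genotype sets compatible with each code (genotype = # of 'a'-locus minor alleles)
CODE_SETS = {"a": (0,), "h": (1,), "b": (2,), "c": (1, 2), "d": (0, 1)}

EM_TOL = 1e-6
EM_MAX_ITER = 100


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterDecision:
    marker_id: str
    kept: bool
    reason: str  # "" when kept


def filter_markers(rows: Sequence[MarkerMatrixRow], max_missing: float = 0.20,
                   min_het_or_dom: float = 0.10,
                   min_hom: float = 0.015) -> tuple[list[MarkerMatrixRow], list[FilterDecision]]:
    """Keep markers with <= 20% missing, >= 10% heterozygous-or-dominant and
    >= 1.5% homozygous for at least one homozygous state (bounds inclusive).

    For dominant markers the dominant class (c or d) plays the
    heterozygous-or-dominant role and the recessive class the homozygous one.
    Proportions other than missingness are over non-missing calls.
    """
    kept: list[MarkerMatrixRow] = []
    decisions: list[FilterDecision] = []
    for row in rows:
        g = row.genotypes
        n = len(g)
        n_u = g.count("u")
        ok = True
        reason = ""
        if n == 0 or n_u / n > max_missing:
            ok, reason = False, "missing"
        else:
            nm = n - n_u
            if row.marker_type == "codominant":
                het_dom = g.count("h")
                homs = (g.count("a"), g.count("b"))
            elif row.marker_type == "dominant_b":
                het_dom = g.count("c")
                homs = (g.count("a"),)
            else:  # dominant_a
                het_dom = g.count("d")
                homs = (g.count("b"),)
            if nm == 0 or het_dom / nm < min_het_or_dom:
                ok, reason = False, "het_or_dom"
            elif max(homs) / nm < min_hom:
                ok, reason = False, "hom"
        decisions.append(FilterDecision(row.marker_id, ok, reason))
        if ok:
            kept.append(row)
    return kept, decisions


# ---------------------------------------------------------------------------
# two-point EM machinery

def _combo_tables():
    """16 meiosis-pair combinations: genotype at each locus, recombinant
    meiosis count, and the parental/recombinant split per combo."""
    # per-meiosis two-locus gametes (allele at locus 1, allele at locus 2, recombinant?)
    gametes = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]
    g1 = np.empty(16, dtype=int)
    g2 = np.empty(16, dtype=int)
    k = np.empty(16, dtype=int)  # number of recombinant meioses (0..2)
    for idx, ((a1, b1, r1), (a2, b2, r2)) in enumerate(product(gametes, repeat=2)):
        g1[idx] = a1 + a2
        g2[idx] = b1 + b2
        k[idx] = r1 + r2
    return g1, g2, k


_G1, _G2, _K = _combo_tables()


def _cell_masks(phase: str) -> np.ndarray:
    """(25, 16) 0/1 matrix: which combos are compatible with each observed
    code pair.  Repulsion swaps genotype labels at locus 2."""
    mask = np.zeros((25, 16))
    for i, c1 in enumerate(CODES):
        for j, c2 in enumerate(CODES):
            s1 = CODE_SETS[c1]
            s2 = CODE_SETS[c2]
            for combo in range(16):
                gg2 = _G2[combo] if phase == "coupling" else 2 - _G2[combo]
                if _G1[combo] in s1 and gg2 in s2:
                    mask[i * 5 + j, combo] = 1
    return mask


_MASK = {p: _cell_masks(p) for p in ("coupling", "repulsion")}


def _combo_probs(r: np.ndarray) -> np.ndarray:
    """(B, 16) meiosis-pair probabilities for per-pair r values (B,)."""
    par = (1 - r) / 2
    rec = r / 2
    per = np.stack([par, par, rec, rec], axis=1)  # (B, 4) gamete probs
    return np.einsum("bi,bj->bij", per, per).reshape(len(r), 16)


def _loglik(counts: np.ndarray, r: np.ndarray, mask: np.ndarray) -> np.ndarray:
    p = _combo_probs(r)
    cell = p @ mask.T  # (B, 25)
    with np.errstate(divide="ignore"):
        lc = np.where(counts > 0, np.log(np.maximum(cell, 1e-300)), 0.0)
    return (counts * lc).sum(axis=1)


def _em(counts: np.ndarray, mask: np.ndarray, r0: float = 0.25) -> np.ndarray:
    """Batched EM over (B, 25) count tables; returns r_hat (B,).

    Only pairs that have not yet converged are updated each iteration.
    """
    B = counts.shape[0]
    n_ind = counts.sum(axis=1)
    r = np.full(B, r0)
    idx = np.nonzero(n_ind > 0)[0]
    for _ in range(EM_MAX_ITER):
        if idx.size == 0:
            break
        sub_r = r[idx]
        p = _combo_probs(sub_r)
        cell = p @ mask.T
        cell_k = (p * _K) @ mask.T
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_k = np.where(cell > 0, cell_k / np.maximum(cell, 1e-300), 0.0)
        rec = (counts[idx] * exp_k).sum(axis=1)
        r_new = np.clip(rec / (2 * n_ind[idx]), 0.0, 0.5)
        moved = np.abs(r_new - sub_r) > EM_TOL
        r[idx] = r_new
        idx = idx[moved]
    return r


def pair_count_tables(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """25-cell count table(s) over pairwise-complete individuals.

    ``codes_a``/``codes_b`` are int arrays (code index, -1 for missing) of
    shape (n_ind,) or (B, n_ind).
    """
    a = np.atleast_2d(np.asarray(codes_a, dtype=np.int64))
    b = np.atleast_2d(np.asarray(codes_b, dtype=np.int64))
    B, n = a.shape
    valid = (a >= 0) & (b >= 0)
    idx = np.where(valid, a * 5 + b, 25)  # 25 = discard bin
    flat = idx + 26 * np.arange(B)[:, None]
    counts = np.bincount(flat.ravel(), minlength=26 * B).reshape(B, 26)
    return counts[:, :25].astype(float)


def estimate_r_lod_batch(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r_hat, LOD) for a batch of 25-cell count tables."""
    counts = np.atleast_2d(counts)
    ll05 = _loglik(counts, np.full(len(counts), 0.5), _MASK["coupling"])
    best_r = np.full(len(counts), 0.5)
    best_ll = ll05.copy()
    for phase in ("coupling", "repulsion"):
        mask = _MASK[phase]
        r = _em(counts, mask)
        ll = _loglik(counts, r, mask)
        better = ll > best_ll
        best_r = np.where(better, r, best_r)
        best_ll = np.where(better, ll, best_ll)
    lod = np.maximum((best_ll - ll05) / np.log(10), 0.0)
    return best_r, lod


def encode_genotypes(rows: Sequence[MarkerMatrixRow]) -> np.ndarray:
    """(m, n_ind) int8 code-index matrix, -1 for missing."""
    m = len(rows)
    if m == 0:
        return np.zeros((0, 0), dtype=np.int8)
    n = len(rows[0].genotypes)
    out = np.full((m, n), -1, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, c in enumerate(row.genotypes):
            if c != "u":
                out[i, j] = CODE_INDEX[c]
    return out


def estimate_r_em(codes_i: str | Sequence[str], codes_j: str | Sequence[str]) -> tuple[float, float]:
    """Two-point (r_hat, LOD) for a single marker pair given genotype code
    strings/sequences over the same individuals ('u' = missing)."""
    ai = np.array([CODE_INDEX.get(c, -1) for c in codes_i])
    aj = np.array([CODE_INDEX.get(c, -1) for c in codes_j])
    counts = pair_count_tables(ai, aj)
    if counts.sum() == 0:
        return 0.5, 0.0
    r, lod = estimate_r_lod_batch(counts)
    return float(r[0]), float(lod[0])


def grid_search_r(codes_i: str | Sequence[str], codes_j: str | Sequence[str],
                  step: float = 0.005) -> tuple[float, float]:
    """Independent oracle: maximize the same likelihood on an r grid."""
    ai = np.array([CODE_INDEX.get(c, -1) for c in codes_i])
    aj = np.array([CODE_INDEX.get(c, -1) for c in codes_j])
    counts = pair_count_tables(ai, aj)
    grid = np.arange(0.0, 0.5 + step / 2, step)
    best = (-np.inf, 0.5)
    for phase in ("coupling", "repulsion"):
        ll = _loglik(np.repeat(counts, len(grid), axis=0), grid, _MASK[phase])
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (float(ll[i]), float(grid[i]))
    ll05 = float(_loglik(counts, np.array([0.5]), _MASK["coupling"])[0])
    return best[1], max((best[0] - ll05) / np.log(10), 0.0)


@dataclass
class LodMatrix:
    marker_ids: list[str]
    r: np.ndarray    # (m, m), 0.5 on failure/diagonal
    lod: np.ndarray  # (m, m), symmetric, >= 0

    def index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)


def lod_matrix(rows: Sequence[MarkerMatrixRow]) -> LodMatrix:
    """All-pairs two-point r/LOD (EM, phase-resolved).

    Count tables for every pair are built with 25 one-hot matrix products
    (one per observable code pair) rather than per-pair tallies.
    """
    ids = [r.marker_id for r in rows]
    G = encode_genotypes(rows)
    m = len(rows)
    r_mat = np.full((m, m), 0.5)
    lod_mat = np.zeros((m, m))
    if m >= 2:
        onehot = [np.ascontiguousarray((G == c), dtype=np.float32) for c in range(5)]
        iu = np.triu_indices(m, 1)
        counts = np.empty((len(iu[0]), 25))
        for c1 in range(5):
            for c2 in range(5):
                plane = onehot[c1] @ onehot[c2].T
                counts[:, c1 * 5 + c2] = plane[iu]
        r, lod = estimate_r_lod_batch(counts)
        empty = counts.sum(axis=1) == 0
        lod[empty] = 0.0
        r[empty] = 0.5
        r_mat[iu] = r
        r_mat.T[iu] = r
        lod_mat[iu] = lod
        lod_mat.T[iu] = lod
    np.fill_diagonal(r_mat, 0.0)
    return LodMatrix(ids, r_mat, lod_mat)


# ---------------------------------------------------------------------------
# grouping


def group_markers(lod: LodMatrix, threshold: float = 10.0) -> dict[str, str]:
    """Single-linkage connected components of the LOD >= threshold graph.

    Returns marker_id -> linkage-group label; labels ``LG1``... by
    decreasing group size (ties by smallest member id).
    """
    adj = csr_matrix(lod.lod >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for mid, lab in zip(lod.marker_ids, labels):
        groups.setdefault(int(lab), []).append(mid)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    out: dict[str, str] = {}
    for gi, members in enumerate(ordered, start=1):
        for mid in members:
            out[mid] = f"LG{gi}"
    return out


# ---------------------------------------------------------------------------
# placement


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    scaffold: str | None
    position: int | None  # 0-based midpoint of the probe hit
    strand: str | None
    linkage_group: str | None = None
    status: str = "kept"  # kept / discarded_multi_hit / discarded_no_hit /
    #                       discarded_discrepant / discarded_no_majority


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _find_mismatch(haystack: str, needle: str, max_mm: int) -> list[int]:
    hits = []
    L = len(needle)
    for i in range(len(haystack) - L + 1):
        mm = 0
        for a, b in zip(haystack[i:i + L], needle):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append(i)
    return hits


def place_markers(probes: Sequence[tuple[str, str]], scaffolds: dict[str, str],
                  max_mismatches: int = 0) -> list[MarkerPlacement]:
    """Exhaustive probe placement (forward and reverse complement).

    Exactly one hit across the assembly keeps the marker, positioned at the
    hit midpoint; zero or multiple hits discard it.
    """
    out: list[MarkerPlacement] = []
    for marker_id, probe in probes:
        probe = probe.upper()
        rc = revcomp(probe)
        hits: list[tuple[str, int, str]] = []
        for scaf, seq in scaffolds.items():
            if max_mismatches == 0:
                fwd = _find_all(seq, probe)
                rev = _find_all(seq, rc) if rc != probe else []
            else:
                fwd = _find_mismatch(seq, probe, max_mismatches)
                rev = _find_mismatch(seq, rc, max_mismatches) if rc != probe else []
            hits.extend((scaf, i, "+") for i in fwd)
            hits.extend((scaf, i, "-") for i in rev)
            if len(hits) > 1:
                break
        if len(hits) == 1:
            scaf, start, strand = hits[0]
            out.append(MarkerPlacement(marker_id, scaf, start + len(probe) // 2, strand))
        elif not hits:
            out.append(MarkerPlacement(marker_id, None, None, None, status="discarded_no_hit"))
        else:
            out.append(MarkerPlacement(marker_id, None, None, None, status="discarded_multi_hit"))
    return out


# ---------------------------------------------------------------------------
# scaffold -> linkage group assignment


@dataclass
class ScaffoldAssignment:
    assignments: dict[str, str] = field(default_factory=dict)  # scaffold -> LG
    misassembly_candidates: list[str] = field(default_factory=list)
    placements: list[MarkerPlacement] = field(default_factory=list)  # updated statuses


def _lg_blocks(ordered_lgs: list[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of identical LG labels: (lg, first_idx, last_idx)."""
    blocks = []
    for i, lg in enumerate(ordered_lgs):
        if blocks and blocks[-1][0] == lg:
            blocks[-1] = (lg, blocks[-1][1], i)
        else:
            blocks.append((lg, i, i))
    return blocks


def assign_scaffolds(placements: Sequence[MarkerPlacement], groups: dict[str, str],
                     majority: float = 2 / 3, min_block: int = 3) -> ScaffoldAssignment:
    """Assign each scaffold to the modal linkage group of its markers.

    Minority markers on assigned scaffolds are discarded as local
    discrepancies; scaffolds without a qualifying majority are left
    unassigned.  Scaffolds whose markers form >= 2 positionally contiguous
    blocks of >= ``min_block`` markers from different LGs are flagged as
    misassembly candidates instead.
    """
    labelled = [
        MarkerPlacement(p.marker_id, p.scaffold, p.position, p.strand,
                        groups.get(p.marker_id), p.status)
        for p in placements
    ]
    by_scaffold: dict[str, list[MarkerPlacement]] = {}
    for p in labelled:
        if p.status == "kept" and p.linkage_group is not None:
            by_scaffold.setdefault(p.scaffold, []).append(p)

    result = ScaffoldAssignment()
    updated: dict[str, MarkerPlacement] = {p.marker_id: p for p in labelled}
    for scaf, ps in by_scaffold.items():
        ps.sort(key=lambda p: (p.position, p.marker_id))
        lgs = [p.linkage_group for p in ps]
        blocks = _lg_blocks(lgs)
        big = [b for b in blocks if b[2] - b[1] + 1 >= min_block]
        if len({b[0] for b in big}) >= 2:
            result.misassembly_candidates.append(scaf)
            continue
        tally: dict[str, int] = {}
        for lg in lgs:
            tally[lg] = tally.get(lg, 0) + 1
        modal_lg, modal_n = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        if modal_n / len(ps) >= majority:
            result.assignments[scaf] = modal_lg
            for p in ps:
                if p.linkage_group != modal_lg:
                    updated[p.marker_id] = MarkerPlacement(
                        p.marker_id, p.scaffold, p.position, p.strand,
                        p.linkage_group, "discarded_discrepant")
        else:
            for p in ps:
                updated[p.marker_id] = MarkerPlacement(
                    p.marker_id, p.scaffold, p.position, p.strand,
                    p.linkage_group, "discarded_no_majority")
    result.placements = [updated[p.marker_id] for p in labelled]
    return result
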