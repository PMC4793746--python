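"""Scaffold ordering/orientation within linkage groups and pseudo-molecule
construction.

Within one linkage group, scaffolds are first seriated by average-linkage
agglomerative clustering on mean cross-scaffold marker LOD, then refined
by steepest-ascent permutation search maximising

    score = sum over cross-scaffold marker pairs, x_i < x_j, of
            (1 - (x_j - x_i) / n) * LOD_ij

where x are 1-based marker ranks in the tested order (markers keep their
bp order within a scaffold, reversed when the scaffold is flipped) and n
is the marker count of the group.  Marker order within scaffolds is never
tested: only cross-scaffold pairs contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import Assembly
from .io_formats.agp import AgpRow
from .markers import LodMatrix, MarkerPlacement

SPACER = 100


@dataclass
class LgContext:
    """Per-linkage-group marker/LOD bundle used by scoring and search.

    ``pair_sum``/``pair_rank`` hold the per-scaffold-pair block sums that
    let the score be evaluated in O(k^2) per candidate order: for markers i
    (scaffold A, earlier) and j (scaffold B, later), x_j - x_i decomposes
    into the block-offset difference plus j's within-block rank minus i's,
    so only Sum(LOD) and Sum(LOD * within-rank) per pair are needed.
    """

    lg: str
    scaffolds: list[str]
    markers_by_scaffold: dict[str, list[str]]  # bp-ordered marker ids
    lod: np.ndarray          # (n, n) marker LOD in context marker order
    marker_index: dict[str, int]
    cross_mask: np.ndarray   # (n, n) True for cross-scaffold pairs
    sizes: np.ndarray = None         # (k,) markers per scaffold
    pair_sum: np.ndarray = None      # (k, k) Sum LOD over cross pairs
    pair_rank: np.ndarray = None     # (k, k): [s, t] = Sum LOD * rank_in_t
    total_cross_lod: float = 0.0

    @property
    def n_markers(self) -> int:
        return len(self.marker_index)


def make_lg_context(lg: str, assignments: dict[str, str],
                    placements: Sequence[MarkerPlacement],
                    lod: LodMatrix) -> LgContext:
    scaffolds = sorted(s for s, g in assignments.items() if g == lg)
    by_scaffold: dict[str, list[str]] = {}
    ordered_ids: list[str] = []
    scaffold_of: list[int] = []
    for si, scaf in enumerate(scaffolds):
        ms = sorted((p for p in placements
                     if p.scaffold == scaf and p.status == "kept"
                     and p.linkage_group == lg),
                    key=lambda p: (p.position, p.marker_id))
        by_scaffold[scaf] = [p.marker_id for p in ms]
        ordered_ids.extend(p.marker_id for p in ms)
        scaffold_of.extend([si] * len(ms))
    idx = [lod.index(m) for m in ordered_ids]
    sub = lod.lod[np.ix_(idx, idx)]
    sof = np.array(scaffold_of)
    cross = sof[:, None] != sof[None, :]
    ctx = LgContext(lg, scaffolds, by_scaffold, sub,
                    {m: i for i, m in enumerate(ordered_ids)}, cross)
    k = len(scaffolds)
    sizes = np.array([len(by_scaffold[s]) for s in scaffolds])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    pair_sum = np.zeros((k, k))
    pair_rank = np.zeros((k, k))
    for s in range(k):
        rs = slice(starts[s], starts[s] + sizes[s])
        for t in range(k):
            if s == t:
                continue
            block = sub[rs, starts[t]:starts[t] + sizes[t]]
            pair_sum[s, t] = block.sum()
            pair_rank[s, t] = (block.sum(axis=0) * np.arange(sizes[t])).sum()
    ctx.sizes = sizes
    ctx.pair_sum = pair_sum
    ctx.pair_rank = pair_rank
    ctx.total_cross_lod = float(pair_sum.sum() / 2)
    return ctx


@dataclass
class ScaffoldOrder:
    lg: str
    entries: list[tuple[str, str]]  # (scaffold, orientation "+"/"-")
    score: float = 0.0


# ---------------------------------------------------------------------------
# similarity and initial order


def scaffold_similarity(ctx: LgContext) -> np.ndarray:
    """S(A, B) = mean LOD over all cross-scaffold marker pairs (0 when a
    pair of scaffolds shares no markers)."""
    k = len(ctx.scaffolds)
    sim = np.zeros((k, k))
    for i in range(k):
        mi = [ctx.marker_index[m] for m in ctx.markers_by_scaffold[ctx.scaffolds[i]]]
        for j in range(i + 1, k):
            mj = [ctx.marker_index[m] for m in ctx.markers_by_scaffold[ctx.scaffolds[j]]]
            if mi and mj:
                sim[i, j] = sim[j, i] = float(ctx.lod[np.ix_(mi, mj)].mean())
    return sim


def initial_order_upgma(ctx: LgContext, sim: np.ndarray | None = None) -> ScaffoldOrder:
    """Average-linkage agglomeration; each merge concatenates the two
    ordered blocks in the end-combination maximising the similarity of the
    boundary scaffolds.  Ties break lexicographically."""
    if sim is None:
        sim = scaffold_similarity(ctx)
    names = ctx.scaffolds
    if len(names) == 1:
        return ScaffoldOrder(ctx.lg, [(names[0], "+")])
    name_idx = {n: i for i, n in enumerate(names)}
    clusters: list[list[str]] = [[n] for n in names]
    csim: dict[tuple[int, int], float] = {}
    sizes = {i: 1 for i in range(len(clusters))}
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            csim[(i, j)] = sim[i, j]
    alive = set(range(len(clusters)))
    next_id = len(clusters)
    members: dict[int, list[str]] = {i: clusters[i] for i in alive}

    def pair_key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    while len(alive) > 1:
        best = None
        for i in sorted(alive):
            for j in sorted(alive):
                if j <= i:
                    continue
                s = csim[pair_key(i, j)]
                tie = tuple(sorted((min(members[i]), min(members[j]))))
                if best is None or s > best[0] + 1e-12 or (
                        abs(s - best[0]) <= 1e-12 and tie < best[1]):
                    best = (s, tie, i, j)
        _, _, a, b = best
        if min(members[b]) < min(members[a]):
            a, b = b, a
        xa, xb = members[a], members[b]
        combos = [xa + xb, xa + xb[::-1], xa[::-1] + xb, xa[::-1] + xb[::-1]]
        def boundary(combo_left_last: str, combo_right_first: str) -> float:
            return sim[name_idx[combo_left_last], name_idx[combo_right_first]]
        bounds = [boundary(xa[-1], xb[0]), boundary(xa[-1], xb[-1]),
                  boundary(xa[0], xb[0]), boundary(xa[0], xb[-1])]
        merged = combos[int(np.argmax(bounds))]
        nid = next_id
        next_id += 1
        members[nid] = merged
        sizes[nid] = sizes[a] + sizes[b]
        alive.discard(a)
        alive.discard(b)
        for k in alive:
            csim[pair_key(nid, k)] = (
                sizes[a] * csim[pair_key(a, k)] + sizes[b] * csim[pair_key(b, k)]
            ) / (sizes[a] + sizes[b])
        alive.add(nid)
    order = members[next(iter(alive))]
    return ScaffoldOrder(ctx.lg, [(n, "+") for n in order])


# ---------------------------------------------------------------------------
# scoring


def _marker_permutation(ctx: LgContext, entries: Sequence[tuple[str, str]]) -> np.ndarray:
    perm: list[int] = []
    for scaf, orient in entries:
        ids = ctx.markers_by_scaffold[scaf]
        if orient == "-":
            ids = ids[::-1]
        perm.extend(ctx.marker_index[m] for m in ids)
    return np.array(perm, dtype=int)


def order_score(ctx: LgContext, entries: Sequence[tuple[str, str]]) -> float:
    """Evaluate the anchoring score for one signed scaffold order."""
    perm = _marker_permutation(ctx, entries)
    n = len(perm)
    if n < 2:
        return 0.0
    lod = ctx.lod[np.ix_(perm, perm)]
    cross = ctx.cross_mask[np.ix_(perm, perm)]
    x = np.arange(1, n + 1)
    dist = x[None, :] - x[:, None]  # x_j - x_i for j > i
    weight = 1.0 - dist / n
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    return float((weight * lod)[upper & cross].sum())


def order_score_of(order: ScaffoldOrder, ctx: LgContext) -> float:
    return order_score(ctx, order.entries)


def order_score_fast(ctx: LgContext, entries: Sequence[tuple[str, str]]) -> float:
    """Block-decomposed score, equal to :func:`order_score` in O(k^2)."""
    n = ctx.n_markers
    if n < 2:
        return 0.0
    name_idx = {s: i for i, s in enumerate(ctx.scaffolds)}
    k = len(entries)
    blocks = np.array([name_idx[s] for s, _ in entries])
    flips = np.array([o == "-" for _, o in entries])
    sizes = ctx.sizes[blocks]
    offs = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    Sg = ctx.pair_sum[np.ix_(blocks, blocks)]
    Rg = ctx.pair_rank[np.ix_(blocks, blocks)]
    # Sum LOD * within-rank of the later (column) / earlier (row) block,
    # honouring orientations
    rb = np.where(flips[None, :], (sizes[None, :] - 1) * Sg - Rg, Rg)
    ra = np.where(flips[:, None], (sizes[:, None] - 1) * Sg - Rg.T, Rg.T)
    upper = np.triu(np.ones((k, k), dtype=bool), k=1)
    off_diff = offs[None, :] - offs[:, None]
    penalty = (off_diff * Sg + rb - ra)[upper].sum()
    return float(ctx.total_cross_lod - penalty / n)


# ---------------------------------------------------------------------------
# optimisation


def _neighbourhood(entries: list[tuple[str, str]]):
    k = len(entries)
    for i in range(k):  # flip one scaffold
        cand = list(entries)
        name, o = cand[i]
        cand[i] = (name, "-" if o == "+" else "+")
        yield cand
    for i in range(k):  # swap two scaffolds
        for j in range(i + 1, k):
            cand = list(entries)
            cand[i], cand[j] = cand[j], cand[i]
            yield cand
    for i in range(k):  # relocate one scaffold
        for j in range(k):
            if i == j:
                continue
            cand = list(entries)
            item = cand.pop(i)
            cand.insert(j, item)
            yield cand
    for i in range(k):  # reverse a contiguous block (flipping members)
        for j in range(i + 1, k):
            block = [(n, "-" if o == "+" else "+") for n, o in entries[i:j + 1]][::-1]
            yield list(entries[:i]) + block + list(entries[j + 1:])


def _hill_climb(ctx: LgContext, entries: list[tuple[str, str]]) -> tuple[list[tuple[str, str]], float]:
    score = order_score_fast(ctx, entries)
    while True:
        best_gain = 0.0
        best_cand = None
        for cand in _neighbourhood(entries):
            s = order_score_fast(ctx, cand)
            if s > score + 1e-9 and s - score > best_gain:
                best_gain = s - score
                best_cand = (cand, s)
        if best_cand is None:
            return entries, score
        entries, score = best_cand


def optimize_order(ctx: LgContext, initial: ScaffoldOrder, seed: int = 42,
                   restarts: int = 10) -> ScaffoldOrder:
    """Steepest-ascent search over swaps, relocations, block reversals and
    flips, with seeded random restarts; never returns a score below the
    initial order's."""
    entries, score = _hill_climb(ctx, list(initial.entries))
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        k = len(ctx.scaffolds)
        perm = rng.permutation(k)
        flips = rng.integers(0, 2, size=k)
        start = [(ctx.scaffolds[p], "-" if flips[i] else "+")
                 for i, p in enumerate(perm)]
        cand, s = _hill_climb(ctx, start)
        if s > score + 1e-9:
            entries, score = cand, s
    return ScaffoldOrder(ctx.lg, entries, score)


# ---------------------------------------------------------------------------
# pseudo-molecules


@dataclass
class Pseudomolecule:
    name: str
    agp_rows: list[AgpRow]
    sequence: str


def build_pseudomolecules(assembly: Assembly, orders: Sequence[ScaffoldOrder],
                          marker_counts: dict[str, int],
                          min_orient_markers: int = 2,
                          name_template: str = "chr{:02d}",
                          spacer: int = SPACER) -> tuple[list[Pseudomolecule], list[str]]:
    """Emit one pseudo-molecule per linkage group: components in order and
    orientation, 100-N spacers, '?' orientation for scaffolds with too few
    markers to orient (their sequence is used forward).

    Returns (pseudomolecules, unanchored scaffold names).  The assembly is
    edited in place (anchored scaffolds replaced by the new objects) with
    an anchor ledger record.
    """
    seen: set[str] = set()
    objects = []
    molecules: list[Pseudomolecule] = []
    for mi, order in enumerate(sorted(orders, key=lambda o: o.lg), start=1):
        name = name_template.format(mi)
        comps = []
        pos = 0
        rows: list[AgpRow] = []
        part = 1
        for scaf, orient in order.entries:
            if scaf in seen:
                raise ValueError(f"scaffold {scaf} appears in two orders")
            seen.add(scaf)
            if pos > 0:
                rows.append(AgpRow(name, pos + 1, pos + spacer, part, "U",
                                   gap_length=spacer))
                pos += spacer
                part += 1
            L = assembly.length_of(scaf)
            agp_orient = orient
            strand = orient
            if marker_counts.get(scaf, 0) < min_orient_markers:
                agp_orient = "?"
                strand = "+"
            comps.append({"id": scaf, "start": pos, "strand": strand, "length": L})
            rows.append(AgpRow(name, pos + 1, pos + L, part, "W",
                               component_id=scaf, component_beg=1,
                               component_end=L, orientation=agp_orient))
            pos += L
            part += 1
        objects.append({"name": name, "components": comps})
        molecules.append(Pseudomolecule(name, rows, ""))
    unanchored = [s for s in assembly.sequences if s not in seen]
    assembly.anchor(objects)
    for mol in molecules:
        mol.sequence = assembly.sequences[mol.name]
    return molecules, unanchored
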