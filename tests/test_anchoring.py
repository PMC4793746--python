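import itertools

import numpy as np
import pytest

from scaffkit import anchoring, markers
from scaffkit.anchoring import (LgContext, ScaffoldOrder, build_pseudomolecules,
                                initial_order_upgma, make_lg_context,
                                optimize_order, order_score, order_score_fast,
                                scaffold_similarity)
from scaffkit.assembly import Assembly, revcomp
from scaffkit.markers import LodMatrix, MarkerPlacement


def ctx_from(markers_by_scaffold, lod_values):
    """Build an LgContext from explicit per-scaffold marker lists and a
    dict of pairwise LODs."""
    ids = [m for ms in markers_by_scaffold.values() for m in ms]
    m = len(ids)
    lod = np.zeros((m, m))
    pos = {mid: i for i, mid in enumerate(ids)}
    for (a, b), v in lod_values.items():
        lod[pos[a], pos[b]] = lod[pos[b], pos[a]] = v
    mat = LodMatrix(ids, np.zeros((m, m)), lod)
    placements = []
    for scaf, ms in markers_by_scaffold.items():
        for k, mid in enumerate(ms):
            placements.append(MarkerPlacement(mid, scaf, k * 100, "+", "LG1"))
    assignments = {s: "LG1" for s in markers_by_scaffold}
    return make_lg_context("LG1", assignments, placements, mat)


# ---------------------------------------------------------------------------
# similarity


def test_similarity_single_markers():
    ctx = ctx_from({"A": ["m1"], "B": ["m2"]}, {("m1", "m2"): 7.0})
    sim = scaffold_similarity(ctx)
    assert sim[0, 1] == 7.0


def test_similarity_mean_and_symmetry():
    ctx = ctx_from({"A": ["m1", "m2"], "B": ["m3"]},
                   {("m1", "m3"): 6.0, ("m2", "m3"): 8.0})
    sim = scaffold_similarity(ctx)
    assert sim[0, 1] == pytest.approx(7.0)
    assert np.allclose(sim, sim.T)


# ---------------------------------------------------------------------------
# UPGMA-like initial order


def test_upgma_hand_trace():
    # S(A,B)=10, S(A,C)=2, S(B,C)=8 -> order A,B,C
    ctx = ctx_from({"A": ["m1"], "B": ["m2"], "C": ["m3"]},
                   {("m1", "m2"): 10.0, ("m1", "m3"): 2.0, ("m2", "m3"): 8.0})
    order = initial_order_upgma(ctx)
    assert [s for s, _ in order.entries] == ["A", "B", "C"]


def test_upgma_all_equal_lexicographic():
    ctx = ctx_from({"d": ["m1"], "b": ["m2"], "c": ["m3"], "a": ["m4"]},
                   {(x, y): 5.0 for x, y in itertools.combinations(
                       ["m1", "m2", "m3", "m4"], 2)})
    order = initial_order_upgma(ctx)
    assert [s for s, _ in order.entries] == ["a", "b", "c", "d"]


def test_upgma_single_scaffold():
    ctx = ctx_from({"A": ["m1"]}, {})
    assert initial_order_upgma(ctx).entries == [("A", "+")]


# ---------------------------------------------------------------------------
# score


def worked_ctx():
    # m1, m2 on A (ranks 1,2); m3 on B (rank 3); n=3
    return ctx_from({"A": ["m1", "m2"], "B": ["m3"]},
                    {("m1", "m3"): 2.0, ("m2", "m3"): 4.0})


def test_score_worked_example():
    ctx = worked_ctx()
    score = order_score(ctx, [("A", "+"), ("B", "+")])
    assert score == pytest.approx(10 / 3)


def test_score_single_scaffold_zero():
    ctx = ctx_from({"A": ["m1", "m2"]}, {})
    assert order_score(ctx, [("A", "+")]) == 0.0


def test_score_invariant_under_global_reversal():
    ctx = ctx_from({"A": ["m1", "m2"], "B": ["m3", "m4"], "C": ["m5"]},
                   {(a, b): v for (a, b), v in zip(
                       itertools.combinations([f"m{i}" for i in range(1, 6)], 2),
                       [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])})
    fwd = [("A", "+"), ("B", "-"), ("C", "+")]
    rev = [("C", "-"), ("B", "+"), ("A", "-")]
    assert order_score(ctx, fwd) == pytest.approx(order_score(ctx, rev))


def test_fast_score_equals_direct_formula():
    rng = np.random.default_rng(0)
    ids = [f"m{i}" for i in range(12)]
    lods = {pair: float(rng.uniform(0, 10))
            for pair in itertools.combinations(ids, 2)}
    ctx = ctx_from({"A": ids[:3], "B": ids[3:7], "C": ids[7:9], "D": ids[9:]},
                   lods)
    scafs = ctx.scaffolds
    for _ in range(30):
        perm = rng.permutation(len(scafs))
        entries = [(scafs[p], rng.choice(["+", "-"])) for p in perm]
        assert order_score_fast(ctx, entries) == pytest.approx(
            order_score(ctx, entries), abs=1e-8)


# ---------------------------------------------------------------------------
# optimisation


def exhaustive_best_score(ctx):
    """Independent brute-force oracle over all signed permutations."""
    best = -np.inf
    for perm in itertools.permutations(ctx.scaffolds):
        for bits in range(2 ** len(perm)):
            entries = [(s, "-" if bits >> i & 1 else "+")
                       for i, s in enumerate(perm)]
            best = max(best, order_score(ctx, entries))
    return best


def test_optimizer_matches_exhaustive_on_small_lg():
    rng = np.random.default_rng(3)
    ids = [f"m{i}" for i in range(10)]
    lods = {pair: float(rng.uniform(0, 8)) for pair in itertools.combinations(ids, 2)}
    ctx = ctx_from({"A": ids[:2], "B": ids[2:4], "C": ids[4:6],
                    "D": ids[6:8], "E": ids[8:]}, lods)
    best = optimize_order(ctx, initial_order_upgma(ctx), seed=1, restarts=5)
    assert best.score == pytest.approx(exhaustive_best_score(ctx), abs=1e-6)


def test_optimizer_never_below_initial():
    rng = np.random.default_rng(4)
    ids = [f"m{i}" for i in range(8)]
    lods = {pair: float(rng.uniform(0, 5)) for pair in itertools.combinations(ids, 2)}
    ctx = ctx_from({"A": ids[:2], "B": ids[2:4], "C": ids[4:6], "D": ids[6:]}, lods)
    init = initial_order_upgma(ctx)
    init_score = order_score(ctx, init.entries)
    best = optimize_order(ctx, init, seed=2, restarts=2)
    assert best.score >= init_score - 1e-9


def test_optimizer_deterministic():
    rng = np.random.default_rng(5)
    ids = [f"m{i}" for i in range(8)]
    lods = {pair: float(rng.uniform(0, 5)) for pair in itertools.combinations(ids, 2)}
    ctx = ctx_from({"A": ids[:2], "B": ids[2:4], "C": ids[4:6], "D": ids[6:]}, lods)
    init = initial_order_upgma(ctx)
    o1 = optimize_order(ctx, init, seed=7, restarts=4)
    o2 = optimize_order(ctx, init, seed=7, restarts=4)
    assert o1.entries == o2.entries and o1.score == o2.score


def test_optimizer_fixed_point():
    ctx = worked_ctx()
    best = optimize_order(ctx, initial_order_upgma(ctx), seed=1, restarts=2)
    again = optimize_order(ctx, ScaffoldOrder("LG1", best.entries), seed=1, restarts=0)
    assert again.score == pytest.approx(best.score)


# ---------------------------------------------------------------------------
# pseudo-molecule construction


def test_build_pseudomolecules_arithmetic_and_agp():
    asm = Assembly({"s1": "ACGT" * 250, "s2": "GGCC" * 500, "un": "T" * 50})
    orders = [ScaffoldOrder("LG1", [("s1", "+"), ("s2", "-")], 1.0)]
    mols, unanchored = build_pseudomolecules(asm, orders,
                                            {"s1": 5, "s2": 5})
    assert unanchored == ["un"]
    mol = mols[0]
    assert mol.name == "chr01"
    assert len(mol.sequence) == 1000 + 100 + 2000
    assert mol.sequence == "ACGT" * 250 + "N" * 100 + revcomp("GGCC" * 500)
    w_rows = [r for r in mol.agp_rows if r.component_type == "W"]
    assert [r.orientation for r in w_rows] == ["+", "-"]
    gap_rows = [r for r in mol.agp_rows if r.component_type == "U"]
    assert gap_rows[0].gap_length == 100
    assert gap_rows[0].linkage == "yes" and gap_rows[0].gap_type == "scaffold"


def test_build_pseudomolecules_unoriented_few_markers():
    asm = Assembly({"s1": "ACGT" * 250, "s2": "GGCC" * 500})
    orders = [ScaffoldOrder("LG1", [("s1", "+"), ("s2", "-")], 1.0)]
    mols, _ = build_pseudomolecules(asm, orders, {"s1": 5, "s2": 1})
    w_rows = [r for r in mols[0].agp_rows if r.component_type == "W"]
    assert w_rows[1].orientation == "?"
    # '?' components are used forward in the sequence
    assert mols[0].sequence.endswith("GGCC" * 500)


def test_build_pseudomolecules_duplicate_scaffold_error():
    asm = Assembly({"s1": "ACGT" * 250})
    orders = [ScaffoldOrder("LG1", [("s1", "+")], 1.0),
              ScaffoldOrder("LG2", [("s1", "+")], 1.0)]
    with pytest.raises(ValueError, match="two orders"):
        build_pseudomolecules(asm, orders, {"s1": 5})


def test_agp_fasta_consistency():
    from scaffkit.io_formats.agp import agp_to_sequences
    asm = Assembly({"s1": "ACGTACGTGG" * 100, "s2": "CCATTGGATC" * 80})
    components = {k: v for k, v in asm.sequences.items()}
    orders = [ScaffoldOrder("LG1", [("s2", "-"), ("s1", "+")], 1.0)]
    mols, _ = build_pseudomolecules(asm, orders, {"s1": 5, "s2": 5})
    rebuilt = agp_to_sequences(mols[0].agp_rows, components)
    assert rebuilt["chr01"] == mols[0].sequence
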