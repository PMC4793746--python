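

import numpy as np
import pytest

from scaffkit import markers
from scaffkit.io_formats.marker_matrix import MarkerMatrixRow
from scaffkit.markers import (assign_scaffolds, estimate_r_em, filter_markers,
                              grid_search_r, group_markers, lod_matrix,
                              place_markers, MarkerPlacement)


# ---------------------------------------------------------------------------
# independent likelihood oracle (direct 3x3 genotype-table enumeration)


def oracle_loglik(codes_i, codes_j, r, swap=False):
    """F2 two-point log-likelihood by direct enumeration, written separately
    from the package implementation."""
    par, rec = (1 - r) / 2, r / 2
    gam = {(0, 0): par, (1, 1): par, (0, 1): rec, (1, 0): rec}
    joint = np.zeros((3, 3))
    for (a1, b1), p1 in gam.items():
        for (a2, b2), p2 in gam.items():
            joint[a1 + a2][b1 + b2] += p1 * p2
    if swap:
        joint = joint[:, ::-1]
    sets = {"a": [0], "h": [1], "b": [2], "c": [1, 2], "d": [0, 1]}
    ll = 0.0
    for ci, cj in zip(codes_i, codes_j):
        if ci == "u" or cj == "u":
            continue
        p = sum(joint[g1][g2] for g1 in sets[ci] for g2 in sets[cj])
        ll += np.log(max(p, 1e-300))
    return ll


def oracle_r_lod(codes_i, codes_j, step=0.005):
    grid = np.arange(0.0, 0.5 + step / 2, step)
    best_ll, best_r = -np.inf, 0.5
    for swap in (False, True):
        for r in grid:
            ll = oracle_loglik(codes_i, codes_j, r, swap)
            if ll > best_ll:
                best_ll, best_r = ll, float(r)
    ll05 = oracle_loglik(codes_i, codes_j, 0.5)
    return best_r, max((best_ll - ll05) / np.log(10), 0.0)


# ---------------------------------------------------------------------------
# filtering


def row(codes, mtype="codominant", mid="m"):
    return MarkerMatrixRow(mid, mtype, codes)


def test_filter_missing_over_20pct_rejected():
    g = "u" * 37 + "a" * 36 + "h" * 71 + "b" * 36  # 37/180 = 20.6%
    kept, dec = filter_markers([row(g)])
    assert not kept and dec[0].reason == "missing"


def test_filter_missing_exactly_20pct_inclusive():
    g = "u" * 36 + "a" * 36 + "h" * 72 + "b" * 36  # 36/180 = 20.0%
    kept, _ = filter_markers([row(g)])
    assert len(kept) == 1


def test_filter_hom_below_1_5pct_rejected():
    g = "a" * 2 + "h" * 178  # 2/180 = 1.1% < 1.5%
    kept, dec = filter_markers([row(g)])
    assert not kept and dec[0].reason == "hom"


def test_filter_het_or_dom_threshold():
    g = "h" * 17 + "a" * 82 + "b" * 81  # 17/180 = 9.4% < 10%
    kept, dec = filter_markers([row(g)])
    assert not kept and dec[0].reason == "het_or_dom"


def test_filter_dominant_roles():
    # dominant_b: c plays het-or-dom, a plays hom
    g = "c" * 135 + "a" * 45
    kept, _ = filter_markers([row(g, "dominant_b")])
    assert len(kept) == 1
    g = "c" * 178 + "a" * 2  # hom 1.1%
    kept, dec = filter_markers([row(g, "dominant_b")])
    assert not kept and dec[0].reason == "hom"


def test_filter_idempotent_and_order_independent(small_ds):
    rows = list(small_ds.marker_rows)
    kept1, _ = filter_markers(rows)
    kept2, _ = filter_markers(kept1)
    assert kept1 == kept2
    kept3, _ = filter_markers(rows[::-1])
    assert sorted(r.marker_id for r in kept1) == sorted(r.marker_id for r in kept3)


# ---------------------------------------------------------------------------
# two-point EM


def test_lod_closed_form_duplicate_columns():
    codes = "a" * 45 + "h" * 90 + "b" * 45
    r, lod = estimate_r_em(codes, codes)
    assert r < 1e-3
    assert lod == pytest.approx(90 * np.log10(4) + 90 * np.log10(2), abs=1e-6)


def test_lod_independent_columns_near_zero():
    rng = np.random.default_rng(1)
    g1 = "".join(np.array(list("ahb"))[rng.choice(3, 180, p=[.25, .5, .25])])
    g2 = "".join(np.array(list("ahb"))[rng.choice(3, 180, p=[.25, .5, .25])])
    _, lod = estimate_r_em(g1, g2)
    assert lod < 0.5


def test_lod_no_shared_individuals_zero():
    r, lod = estimate_r_em("aau", "uua")
    assert lod == 0.0


def test_em_matches_independent_oracle_small():
    rng = np.random.default_rng(42)
    for _ in range(10):
        g1 = "".join(rng.choice(list("ahbu"), 60, p=[.24, .48, .24, .04]))
        g2 = "".join(rng.choice(list("ahbu"), 60, p=[.24, .48, .24, .04]))
        r_em, lod_em = estimate_r_em(g1, g2)
        r_or, lod_or = oracle_r_lod(g1, g2)
        assert lod_em == pytest.approx(lod_or, abs=0.02)


def _simulate_pair(rng, r_true, n=180, dom=False, swap=False):
    g1 = rng.integers(0, 2, n) + rng.integers(0, 2, n)
    rec1 = rng.random(n) < r_true
    rec2 = rng.random(n) < r_true
    a1 = (g1 - rng.integers(0, 2, n)).clip(0, 1)  # crude split into gametes
    # correct gamete bookkeeping: draw gametes explicitly
    gam1a = rng.integers(0, 2, n)
    gam1b = rng.integers(0, 2, n)
    gam2a = gam1a ^ rec1
    gam2b = gam1b ^ rec2
    c1 = gam1a + gam1b
    c2 = gam2a + gam2b
    codes1 = np.array(list("ahb"))[c1]
    codes2 = np.array(list("ahb"))[2 - c2 if swap else c2]
    if dom:
        codes2 = np.where(np.isin(codes2, ["h", "b"]), "c", codes2)
    return "".join(codes1), "".join(codes2)


def test_em_equals_grid_on_simulated_pairs():
    rng = np.random.default_rng(7)
    for i in range(50):
        r_true = rng.uniform(0.02, 0.45)
        dom = i % 3 == 0
        swap = i % 2 == 0
        g1, g2 = _simulate_pair(rng, r_true, dom=dom, swap=swap)
        r_em, _ = estimate_r_em(g1, g2)
        r_grid, _ = grid_search_r(g1, g2)
        assert abs(r_em - r_grid) <= 0.005


def test_em_recovers_true_r():
    rng = np.random.default_rng(3)
    errs = []
    for _ in range(200):
        g1, g2 = _simulate_pair(rng, 0.2)
        r_em, _ = estimate_r_em(g1, g2)
        errs.append(r_em - 0.2)
    assert abs(np.mean(errs)) < 0.03


def test_em_handles_repulsion_phase():
    rng = np.random.default_rng(9)
    g1, g2 = _simulate_pair(rng, 0.1, swap=True)
    r_em, lod = estimate_r_em(g1, g2)
    assert abs(r_em - 0.1) < 0.06
    assert lod > 10


# ---------------------------------------------------------------------------
# LOD matrix and grouping


def _rows_from_cols(cols):
    return [MarkerMatrixRow(f"m{i}", "codominant", c) for i, c in enumerate(cols)]


def test_lod_matrix_symmetric_three_markers():
    rng = np.random.default_rng(0)
    cols = ["".join(rng.choice(list("ahb"), 100, p=[.25, .5, .25])) for _ in range(3)]
    mat = lod_matrix(_rows_from_cols(cols))
    assert np.allclose(mat.lod, mat.lod.T)
    assert (mat.lod >= 0).all()
    assert np.count_nonzero(np.triu(np.ones((3, 3)), k=1)) == 3


def test_lod_matrix_duplicate_column_row_maximal():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list("ahb"), 120, p=[.25, .5, .25]))
    other = "".join(rng.choice(list("ahb"), 120, p=[.25, .5, .25]))
    mat = lod_matrix(_rows_from_cols([base, base, other]))
    assert mat.lod[0, 1] == mat.lod[0].max()
    assert mat.r[0, 1] < 1e-3


def test_group_markers_thresholds():
    rng = np.random.default_rng(4)
    base = "".join(rng.choice(list("ahb"), 120, p=[.25, .5, .25]))
    other = "".join(rng.choice(list("ahb"), 120, p=[.25, .5, .25]))
    mat = lod_matrix(_rows_from_cols([base, base, other]))
    assert len(set(group_markers(mat, threshold=1e9).values())) == 3
    assert len(set(group_markers(mat, threshold=0.0).values())) == 1


def test_group_markers_recovers_chromosomes(small_ds):
    kept, _ = markers.filter_markers(small_ds.marker_rows)
    mat = lod_matrix(kept)
    groups = group_markers(mat, threshold=10.0)
    lgs = {}
    for rw in kept:
        chrom = small_ds.truth.true_marker_map[rw.marker_id]["chrom"]
        lgs.setdefault(groups[rw.marker_id], set()).add(chrom)
    assert len(lgs) == small_ds.config.n_chromosomes
    for chroms in lgs.values():
        assert len(chroms) == 1


# ---------------------------------------------------------------------------
# placement


def test_place_marker_unique_hit():
    scaffolds = {"s1": "AAAACGTACGTTTTT", "s2": "CCCCCCCCCC"}
    [p] = place_markers([("m1", "ACGTACGT")], scaffolds)
    assert (p.scaffold, p.position, p.strand, p.status) == ("s1", 7, "+", "kept")


def test_place_marker_revcomp_hit():
    from scaffkit.assembly import revcomp
    scaffolds = {"s1": "AAAAAGGGCCCATTTTT"}
    [p] = place_markers([("m1", revcomp("GGGCCCAT"))], scaffolds)
    assert p.status == "kept" and p.strand == "-"
    assert p.position == 5 + 4  # midpoint of the genomic hit


def test_place_marker_multi_hit_discarded():
    scaffolds = {"s1": "ACGTACGTAAA", "s2": "TTTACGTACGT"}
    [p] = place_markers([("m1", "ACGTACGT")], scaffolds)
    assert p.status == "discarded_multi_hit"


def test_place_marker_no_hit_distinct_status():
    [p] = place_markers([("m1", "GGGGGGGG")], {"s1": "ACGTACGT"})
    assert p.status == "discarded_no_hit"


def test_place_markers_against_truth(small_ds):
    placements = place_markers(small_ds.probes[:30], small_ds.assembly.sequences)
    tm = small_ds.truth.true_marker_map
    checked = 0
    for p in placements:
        info = tm[p.marker_id]
        if "scaffold" not in info or p.status != "kept":
            continue
        assert p.scaffold == info["scaffold"]
        assert abs(p.position - info["scaffold_pos"]) <= 1
        checked += 1
    assert checked >= 20


def test_place_marker_mismatch_tolerant():
    scaffolds = {"s1": "TTTTTAAGGAAGGTTTTT"}
    [p] = place_markers([("m1", "AAGGAAGC")], scaffolds, max_mismatches=1)
    assert p.status == "kept"
    [p] = place_markers([("m1", "AAGGAAGC")], scaffolds, max_mismatches=0)
    assert p.status == "discarded_no_hit"


# ---------------------------------------------------------------------------
# scaffold assignment


def _pl(mid, scaf, pos):
    return MarkerPlacement(mid, scaf, pos, "+")


def test_assign_majority_with_discrepancy():
    placements = [_pl(f"m{i}", "s", i * 100) for i in range(10)]
    groups = {f"m{i}": "LG1" for i in range(10)}
    groups["m4"] = "LG2"  # interleaved singleton
    res = assign_scaffolds(placements, groups)
    assert res.assignments["s"] == "LG1"
    st = {p.marker_id: p.status for p in res.placements}
    assert st["m4"] == "discarded_discrepant"
    assert st["m3"] == "kept"


def test_assign_block_conflict_flags_misassembly():
    placements = [_pl(f"m{i}", "s", i * 100) for i in range(10)]
    groups = {f"m{i}": ("LG1" if i < 5 else "LG2") for i in range(10)}
    res = assign_scaffolds(placements, groups)
    assert res.misassembly_candidates == ["s"]
    assert "s" not in res.assignments


def test_assign_no_majority_unassigned():
    placements = [_pl("m1", "s", 0), _pl("m2", "s", 100)]
    groups = {"m1": "LG1", "m2": "LG2"}
    res = assign_scaffolds(placements, groups)
    assert "s" not in res.assignments
    assert all(p.status == "discarded_no_majority" for p in res.placements)


def test_assign_true_lg_on_clean_sim(small_ds):
    kept, _ = markers.filter_markers(small_ds.marker_rows)
    mat = lod_matrix(kept)
    groups = group_markers(mat, threshold=10.0)
    kept_ids = {r.marker_id for r in kept}
    placements = place_markers([p for p in small_ds.probes if p[0] in kept_ids],
                               small_ds.assembly.sequences)
    res = assign_scaffolds(placements, groups)
    # every scaffold with >= 5 placed markers is assigned, consistently with truth
    tm = small_ds.truth.true_marker_map
    lg_to_chrom = {}
    for scaf, lg in res.assignments.items():
        chroms = {tm[p.marker_id]["chrom"] for p in res.placements
                  if p.scaffold == scaf and p.status == "kept"}
        assert len(chroms) == 1
        chrom = chroms.pop()
        assert lg_to_chrom.setdefault(lg, chrom) == chrom
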