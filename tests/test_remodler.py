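import pytest

from scaffkit.assembly import Assembly
from scaffkit.readpairs import (LibraryStats, PairAlignment, classify_all,
                                dedup_pairs, discordant_fraction,
                                estimate_library_stats)
from scaffkit.remodler import (apply_edit, cluster_discordant, lift_pairs,
                               propose_edits, region_report, validate_edit)

STATS = LibraryStats("lib", 5000, 2500, 7500)


def mkpair(pid, s1, p1, st1, s2, p2, st2):
    return PairAlignment(pid, s1, p1, st1, s2, p2, st2, 100)


def _link_pairs(n, s1, base1, st1, s2, base2, st2, step=50):
    return [mkpair(f"l{i}", s1, base1 + i * step, st1, s2, base2 + i * step, st2)
            for i in range(n)]


def test_cluster_formed_from_ten_links():
    pairs = _link_pairs(10, "s2", 59000, "+", "s5", 200, "-")
    classes = classify_all(pairs, STATS)
    clusters = cluster_discordant(pairs, classes, STATS)
    assert len(clusters) == 1
    assert clusters[0].n_pairs == 10


def test_cluster_below_min_dropped():
    pairs = _link_pairs(3, "s2", 59000, "+", "s5", 200, "-")
    clusters = cluster_discordant(pairs, classify_all(pairs, STATS), STATS,
                                  min_cluster=5)
    assert clusters == []


def test_cluster_split_by_distance():
    pairs = (_link_pairs(6, "s2", 1000, "+", "s5", 200, "-")
             + _link_pairs(6, "s2", 50000, "+", "s5", 40000, "-"))
    clusters = cluster_discordant(pairs, classify_all(pairs, STATS), STATS)
    assert len(clusters) == 2


def test_excision_truth_clusters_and_fusion(error_ds):
    ds = error_ds
    pairs = dedup_pairs(ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    clusters = cluster_discordant(pairs, classes, stats)
    proposals = propose_edits(clusters, ds.assembly, stats)
    fusions = {p.donor: p for p in proposals if p.kind == "fusion"
               and p.status != "rejected"}
    for err in ds.truth.errors_of_kind("excision_for_fusion"):
        # >= 2 clusters link the free scaffold to the donor gap flanks
        link = [c for c in clusters
                if {c.locus_1.scaffold, c.locus_2.scaffold}
                == {err["donor"], err["recipient"]}]
        assert len(link) >= 2
        prop = fusions[err["donor"]]
        assert prop.recipient == err["recipient"]
        assert prop.orientation == err["orientation"]
        assert abs(prop.gap_start - err["gap_start"]) < 50
        assert abs(prop.gap_end - err["gap_end"]) < 50


def test_adjacent_split_truth_junction(error_ds):
    ds = error_ds
    pairs = dedup_pairs(ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    clusters = cluster_discordant(pairs, classes, stats)
    proposals = propose_edits(clusters, ds.assembly, stats)
    junctions = [p for p in proposals if p.kind == "junction"
                 and p.status != "rejected"]
    for err in ds.truth.errors_of_kind("adjacent_split_for_junction"):
        match = [p for p in junctions
                 if {p.left, p.right} == {err["left"], err["right"]}]
        assert len(match) == 1
        prop = match[0]
        relative = "-" if (prop.left_flip != prop.right_flip) else "+"
        # orientation is relative: global flips of the pair are equivalent
        if prop.left == err["left"]:
            assert relative == err["orientation"] or (
                prop.left_flip and prop.right_flip and err["orientation"] == "+")
        assert prop.n_made_concordant >= prop.n_pairs * 0.8


def test_contradictory_orientations_rejected():
    # both donor ends link to the SAME recipient locus with clashing strands
    asm = Assembly({"d": "A" * 8000,
                    "r": "C" * 30000 + "N" * 8000 + "G" * 30000})
    pairs = (_link_pairs(6, "d", 100, "-", "r", 29000, "+")
             + _link_pairs(6, "d", 7500, "-", "r", 38200, "+"))
    classes = classify_all(pairs, STATS)
    clusters = cluster_discordant(pairs, classes, STATS)
    proposals = propose_edits(clusters, asm, STATS)
    assert proposals, "expected a proposal to be generated"
    assert all(p.status == "rejected" for p in proposals)


def test_apply_fusion_arithmetic():
    asm = Assembly({"d": "G" * 5000,
                    "r": "A" * 1000 + "N" * 5200 + "C" * 1000})
    from scaffkit.remodler import EditProposal
    prop = EditProposal("fusion", "d", "r", "+", 1000, 6200)
    apply_edit(asm, prop)
    assert prop.status == "applied"
    assert asm.sequences["r"] == "A" * 1000 + "N" * 100 + "G" * 5000 + "N" * 100 + "C" * 1000
    assert prop.joints == [1100, 6100]


def test_apply_junction_arithmetic():
    asm = Assembly({"a": "A" * 1000, "b": "C" * 2000})
    from scaffkit.remodler import EditProposal
    prop = EditProposal("junction", "b", "a", "+", left="a", right="b")
    apply_edit(asm, prop)
    assert len(asm.sequences["a"]) == 3100


def test_apply_fusion_overfill_rejected():
    asm = Assembly({"d": "G" * 9000, "r": "A" * 1000 + "N" * 500 + "C" * 1000})
    from scaffkit.remodler import EditProposal
    prop = EditProposal("fusion", "d", "r", "+", 1000, 1500)
    apply_edit(asm, prop, max_overfill=2000)
    assert prop.status == "rejected"
    assert "overfills" in prop.reason


def test_apply_validate_full_cycle_reduces_discordance(error_ds):
    ds = error_ds
    asm = ds.assembly.copy()
    pairs = dedup_pairs(ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    baseline = discordant_fraction(classes)
    clusters = cluster_discordant(pairs, classes, stats)
    proposals = [p for p in propose_edits(clusters, asm, stats)
                 if p.status != "rejected"]
    assert proposals
    current = baseline
    for prop in proposals:
        apply_edit(asm, prop)
        assert prop.status == "applied"
        lifted = lift_pairs(asm.ledger.records, pairs)
        frac = discordant_fraction(classify_all(lifted, stats))
        assert frac < current  # every applied edit strictly reduces discordance
        current = frac
        verdict = validate_edit(prop, lifted, stats)
        assert verdict.passed, verdict.reason


def test_validate_wrong_orientation_fails(error_ds):
    ds = error_ds
    asm = ds.assembly.copy()
    pairs = dedup_pairs(ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    clusters = cluster_discordant(pairs, classes, stats)
    prop = next(p for p in propose_edits(clusters, asm, stats)
                if p.kind == "fusion" and p.status != "rejected")
    prop.orientation = "-" if prop.orientation == "+" else "+"  # sabotage
    apply_edit(asm, prop)
    lifted = lift_pairs(asm.ledger.records, pairs)
    verdict = validate_edit(prop, lifted, stats)
    assert not verdict.passed


def test_validate_no_evidence_fails():
    from scaffkit.remodler import EditProposal
    prop = EditProposal("junction", "b", "a", left="a", right="b",
                        status="applied", joints=[1000], result="a")
    verdict = validate_edit(prop, [], STATS)
    assert not verdict.passed
    assert "no evidence" in verdict.reason


def test_scaffold_count_decreases_per_edit(error_ds):
    asm = error_ds.assembly.copy()
    pairs = dedup_pairs(error_ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    clusters = cluster_discordant(pairs, classes, stats)
    proposals = [p for p in propose_edits(clusters, asm, stats)
                 if p.status != "rejected"]
    before = len(asm)
    multiset = asm.base_multiset()
    for prop in proposals:
        apply_edit(asm, prop)
    assert len(asm) == before - len(proposals)
    assert asm.base_multiset() == multiset


def test_region_report_clean_and_deterministic(small_ds):
    pairs = dedup_pairs(small_ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    name = next(iter(small_ds.assembly.sequences))
    rep1 = region_report(name, small_ds.assembly.length_of(name), pairs, classes, 1600)
    rep2 = region_report(name, small_ds.assembly.length_of(name), pairs, classes, 1600)
    assert rep1["windows"].equals(rep2["windows"])
    assert rep1["links"].equals(rep2["links"])
    # clean scaffold: essentially no discordant link rows touch it
    assert len(rep1["links"]) <= 2


def test_region_report_links_at_planted_fusion(error_ds):
    pairs = dedup_pairs(error_ds.pairs)
    stats = estimate_library_stats(pairs)
    classes = classify_all(pairs, stats)
    err = error_ds.truth.errors_of_kind("excision_for_fusion")[0]
    rep = region_report(err["recipient"], error_ds.assembly.length_of(err["recipient"]),
                        pairs, classes, 1600)
    links = rep["links"]
    assert not links.empty
    partners = set(links["scaffold_1"]) | set(links["scaffold_2"])
    assert err["donor"] in partners
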