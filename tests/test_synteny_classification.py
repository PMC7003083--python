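"""Stage-2 classification: mapping filters, tag propagation, fragmentation."""

import numpy as np
import pytest

from oracles import random_stage2_instance, stage2_oracle
from xenocds.io_formats import MappingRecord
from xenocds.model import Stage1, Stage2, Thresholds, XenocdsError
from xenocds.synteny_classification import (break_at_gaps, build_scaffold_table,
                                            classify_foreign, fragment_assembly,
                                            table_from_annotations)
from xenocds.taxonomic_assignment import CdsAnnotation


def ann(cds_id, stage1, group=None):
    return CdsAnnotation(cds_id=cds_id, stage1=stage1, foreign_group=group)


def foreign(cds_id, group="eubacteria"):
    return ann(cds_id, Stage1.FOREIGN, group)


def confident(cds_id):
    return ann(cds_id, Stage1.CONFIDENT_ARTHROPOD)


def mapping(cds, scaffold, part=1, aln=500, ident=99.0, start=1):
    return MappingRecord(cds, scaffold, start, start + aln - 1, "+", aln, ident, part)


def run(annotations, mappings, thresholds=Thresholds()):
    table = build_scaffold_table(annotations, mappings, thresholds)
    return {a.cds_id: a.stage2 for a in classify_foreign(annotations, table)}, table


def test_mapping_filters_are_inclusive_minima(thresholds):
    anns = [foreign("f1"), foreign("f2")]
    # 99 bp dropped, 100 bp kept; 94.9% dropped, 95.0% kept
    labels, _ = run(anns, [mapping("f1", "sA", aln=99), mapping("f2", "sA", aln=100)])
    assert labels["f1"] is Stage2.UNCERTAIN      # its only mapping was dropped
    labels, _ = run(anns, [mapping("f1", "sA", ident=94.9), mapping("f2", "sA", ident=95.0)])
    assert labels["f1"] is Stage2.UNCERTAIN
    labels, _ = run(anns, [mapping("f1", "sA", aln=100, ident=95.0),
                           mapping("f2", "sA")])
    assert labels["f1"] is Stage2.CONTAMINANT_CANDIDATE


def test_hgt_when_linked_to_confident_resident():
    anns = [foreign("f1"), confident("a1")]
    labels, _ = run(anns, [mapping("f1", "sA"), mapping("a1", "sA", start=1000)])
    assert labels["f1"] is Stage2.HGT_CANDIDATE
    assert labels["a1"] is Stage2.NOT_APPLICABLE


def test_two_foreign_alone_are_contaminants():
    anns = [foreign("f1"), foreign("f2", "fungi")]
    labels, _ = run(anns, [mapping("f1", "sA"), mapping("f2", "sA", start=1000)])
    assert labels["f1"] is labels["f2"] is Stage2.CONTAMINANT_CANDIDATE


def test_sole_or_unmapped_foreign_is_uncertain():
    anns = [foreign("f1"), foreign("f2")]
    labels, _ = run(anns, [mapping("f1", "sA")])   # f2 has no mapping at all
    assert labels["f1"] is Stage2.UNCERTAIN
    assert labels["f2"] is Stage2.UNCERTAIN


def test_chimeric_cds_cannot_corroborate_itself():
    """A foreign CDS whose two chimeric parts are its scaffold's only
    occupants stays uncertain: a CDS is not 'another' CDS for itself."""
    anns = [foreign("f1")]
    labels, _ = run(anns, [mapping("f1", "sA", part=1), mapping("f1", "sB", part=2)])
    assert labels["f1"] is Stage2.UNCERTAIN


def test_resident_tag_propagates_across_chimera_chain():
    """sA--sB--sC linked by two chimeric resident CDS; arthropod CDS only
    on sA; a foreign CDS on sC is still an HGT candidate."""
    anns = [confident("a1"), confident("x1"), confident("x2"), foreign("f1")]
    mappings = [
        mapping("a1", "sA"),
        mapping("x1", "sA", part=1), mapping("x1", "sB", part=2),
        mapping("x2", "sB", part=1), mapping("x2", "sC", part=2),
        mapping("f1", "sC", start=2000),
    ]
    labels, table = run(anns, mappings)
    assert table.arthropod_tagged == {"sA", "sB", "sC"}
    assert labels["f1"] is Stage2.HGT_CANDIDATE


def test_chimeric_confident_tags_otherwise_empty_scaffold():
    anns = [confident("x1"), foreign("f1")]
    mappings = [mapping("x1", "sA", part=1), mapping("x1", "sB", part=2),
                mapping("f1", "sB", start=2000)]
    labels, table = run(anns, mappings)
    assert {"sA", "sB"} <= table.arthropod_tagged
    assert labels["f1"] is Stage2.HGT_CANDIDATE


def test_only_mapped_categories_enter_table():
    anns = [ann("o1", Stage1.ORPHAN), ann("u1", Stage1.UNASSIGNED),
            ann("m1", Stage1.OTHER_METAZOA), foreign("f1"), foreign("f2")]
    _, table = run(anns, [mapping("o1", "sA"), mapping("u1", "sA"),
                          mapping("m1", "sA"), mapping("f1", "sA"),
                          mapping("f2", "sA", start=600)])
    members = {cid for cid, _ in table.members["sA"]}
    assert members == {"f1", "f2"}


def test_stage2_partition_is_total():
    anns = [foreign(f"f{i}") for i in range(5)] + [confident("a1")]
    labels, _ = run(anns, [mapping("f0", "sA"), mapping("a1", "sA", start=600),
                           mapping("f1", "sB"), mapping("f2", "sB", start=600)])
    foreign_labels = [labels[f"f{i}"] for i in range(5)]
    assert all(l is not Stage2.NOT_APPLICABLE for l in foreign_labels)
    assert labels["a1"] is Stage2.NOT_APPLICABLE


def test_oracle_equivalence_sample(thresholds):
    """2,000 random small instances match the brute-force membership
    scanner (full 10^4 sweep in the acceptance checks)."""
    rng = np.random.default_rng(7)
    for _ in range(2000):
        cds_stage1, placements = random_stage2_instance(rng)
        anns = [foreign(c) if s == "foreign" else confident(c)
                for c, s in cds_stage1.items()]
        mappings = []
        for cds, places in placements.items():
            for part, (scaffold, aln, ident) in enumerate(places, start=1):
                mappings.append(mapping(cds, scaffold, part=part, aln=aln, ident=ident))
        labels, _ = run(anns, mappings, thresholds)
        expected = stage2_oracle(cds_stage1, placements)
        got = {c: labels[c].value for c in expected}
        assert got == expected


def test_table_from_annotations_matches_fresh_build(thresholds):
    anns = [confident("a1"), confident("x1"), foreign("f1"), foreign("f2")]
    mappings = [mapping("a1", "sA"), mapping("x1", "sA", part=1),
                mapping("x1", "sB", part=2), mapping("f1", "sB", start=700),
                mapping("f2", "sC"), mapping("f1", "sC", start=900)]
    table = build_scaffold_table(anns, mappings, thresholds)
    classified = classify_foreign(anns, table)
    rebuilt = table_from_annotations(classified)
    assert rebuilt.arthropod_tagged == table.arthropod_tagged
    assert {s: sorted(m) for s, m in rebuilt.members.items()} == \
           {s: sorted(m) for s, m in table.members.items()}


# ------------------------------------------------------- fragmentation ----

def test_fragment_identity_and_determinism():
    mappings = [mapping("f1", "sA"), mapping("f2", "sA", start=700)]
    lengths = {"sA": 2000}
    same_m, same_l = fragment_assembly(mappings, lengths, 1)
    assert same_m == mappings and same_l == lengths
    a = fragment_assembly(mappings, lengths, 2, seed=5)
    b = fragment_assembly(mappings, lengths, 2, seed=5)
    assert a == b
    with pytest.raises(XenocdsError):
        fragment_assembly(mappings, lengths, 0)


def test_fragment_to_singletons_makes_everything_uncertain(thresholds):
    anns = [foreign(f"f{i}") for i in range(4)] + [confident("a1")]
    mappings = [mapping(f"f{i}", "sA", start=1 + 600 * i) for i in range(4)]
    mappings.append(mapping("a1", "sA", start=3000))
    frag_m, frag_l = fragment_assembly(mappings, {"sA": 4000}, 5)
    labels, _ = run(anns, frag_m, thresholds)
    assert all(labels[f"f{i}"] is Stage2.UNCERTAIN for i in range(4))


def test_fragment_partitions_are_nested():
    mappings = [mapping(f"c{i}", "sA", start=1 + 500 * i) for i in range(8)]
    lengths = {"sA": 8000}
    coarse, _ = fragment_assembly(mappings, lengths, 2)
    fine, _ = fragment_assembly(mappings, lengths, 4)
    coarse_of = {m.cds_id: m.scaffold_id for m in coarse}
    fine_of = {m.cds_id: m.scaffold_id for m in fine}
    # CDS sharing a fine fragment always share the coarse fragment
    for a in fine_of:
        for b in fine_of:
            if fine_of[a] == fine_of[b]:
                assert coarse_of[a] == coarse_of[b]


def test_break_at_gaps_splits_and_shifts():
    scaffolds = {"sA": "A" * 500 + "N" * 20 + "C" * 500}
    mappings = [mapping("c1", "sA", start=1, aln=400),
                mapping("c2", "sA", start=600, aln=300)]
    new_m, lengths = break_at_gaps(scaffolds, mappings, gap_run=10)
    by = {m.cds_id: m for m in new_m}
    assert by["c1"].scaffold_id == "sA|ctg0" and by["c1"].start == 1
    assert by["c2"].scaffold_id == "sA|ctg1" and by["c2"].start == 80
    assert lengths == {"sA|ctg0": 500, "sA|ctg1": 500}
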