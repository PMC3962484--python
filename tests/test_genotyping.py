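"""Genotype calling, duplicated-marker classes, segregation checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salhap.genome import ChromosomeDef, GenomeConfig, LocusSpec, build_genome
from salhap.genotyping import (align_to_db, call_genotype, call_genotypes,
                               classify_duplicate_marker, composite_truth,
                               expand_duplicate_calls, infer_duplicate_class,
                               segregation_check)
from salhap.meiosis import CrossSpec, simulate_cross
from salhap.reads import simulate_reads
from salhap.refdb import ScreeningParams
from salhap.sequtils import mutate, random_sequence

PARAMS = ScreeningParams()


@pytest.mark.parametrize("depths,expected_call", [
    ({"A" * 74: 6, "C" * 74: 5}, "het"),     # both verified, total >= 10
    ({"A" * 74: 9, "C" * 74: 2}, "hom"),     # minor allele unverified
    ({"A" * 74: 5, "C" * 74: 4}, "missing"),  # total below 10
    ({"A" * 74: 40}, "hom"),
    ({"A" * 74: 8, "C" * 74: 8, "G" * 74: 8}, "missing"),  # aberrant
])
def test_heterozygote_depth_rules(depths, expected_call):
    """A heterozygote needs two verified alleles with depth > 2 and total
    depth >= 10; three verified alleles flag paralog collapse (missing)."""
    call, _ = call_genotype(depths, PARAMS)
    assert call == expected_call


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.dictionaries(st.sampled_from(["A" * 74, "C" * 74, "G" * 74]),
                       st.integers(min_value=0, max_value=40),
                       min_size=1, max_size=3))
def test_het_rule_never_fires_below_depth_ten(depths):
    """Property: the heterozygote rule never fires when the total depth is
    below 10, and calls are deterministic."""
    call, alleles = call_genotype(depths, PARAMS)
    if sum(depths.values()) < 10:
        assert call == "missing"
    if call == "het":
        assert len(set(alleles)) == 2
        assert all(depths[a] > 2 for a in alleles)
    assert call_genotype(depths, PARAMS) == (call, alleles)


def test_align_to_db_unique_multi_unassigned():
    rng = np.random.default_rng(0)
    a = random_sequence(74, rng)
    b = random_sequence(74, rng)
    b_near = mutate(b, [0, 1, 2], ["A" if b[i] != "A" else "C"
                                   for i in (0, 1, 2)])
    db = pd.DataFrame({"locus_id": ["L1", "L2", "L3"],
                       "sequence": [a, b, b_near],
                       "status": ["unique"] * 3, "reason": ""})
    stray = random_sequence(74, rng)
    piles = pd.DataFrame({
        "individual_id": ["I1"] * 3, "locus_id": ["x"] * 3,
        "allele": [a, b, stray], "depth": [10, 10, 10]})
    out = align_to_db(piles, db, PARAMS)
    # exact match to a unique locus is assigned; b matches both L2 and L3
    # within 3 mismatches and is dropped; stray matches nothing
    assert list(out["allele"]) == [a]
    assert list(out["db_locus"]) == ["L1"]
    assert out.attrs["n_multimap"] == 1
    assert out.attrs["n_unassigned"] == 1


def test_calls_match_truth_without_noise(duplicated_genome, haploid_family):
    """With no sequencing error and ample depth, calls at unique loci equal
    the simulated truth exactly, and haploids are never heterozygous at
    unique loci."""
    g = duplicated_genome
    piles = simulate_reads(g, haploid_family, mean_depth=30,
                           depth_dispersion=None, error_rate=0.0,
                           rng=np.random.default_rng(1))
    db = pd.DataFrame({"locus_id": [l.locus_id for l in g.loci
                                    if not l.is_duplicated],
                       "sequence": [l.sequence for l in g.loci
                                    if not l.is_duplicated],
                       "status": "unique", "reason": ""})
    out = align_to_db(piles, db, PARAMS)
    calls = call_genotypes(out, PARAMS)
    for locus in g.loci:
        if locus.is_duplicated:
            continue
        lid = locus.locus_id
        assert not calls[lid].str.contains("/").any()
        # allele letters relabel sorted sequences; compare partitions
        truth_groups = haploid_family.groupby(haploid_family[lid]).groups
        call_groups = calls.groupby(calls[lid]).groups
        assert sorted(map(sorted, truth_groups.values())) == \
            sorted(map(sorted, call_groups.values()))


# ---------------------------------------------------------------------------
# Duplicated-marker segregation model


def test_one_paralog_polymorphic_shared_allele():
    """Dam aa x ab: offspring 0.5 aa : 0.5 ab, paralog 2 mappable."""
    cls = classify_duplicate_marker(("a", "a"), ("a", "b"))
    assert cls.class_name == "aa_ab"
    assert cls.mappable_paralogs == (2,)
    assert cls.expected == {"a": 0.5, "a/b": 0.5}


def test_one_paralog_polymorphic_distinct_alleles():
    cls = classify_duplicate_marker(("a", "a"), ("b", "c"))
    assert cls.class_name == "aa_bc"
    assert cls.expected == {"a/b": 0.5, "a/c": 0.5}
    assert cls.mappable_paralogs == (2,)


def test_both_paralogs_polymorphic_shared_allele():
    """Dam ab x ac: 0.25 each of aa, ac, ab, bc; both paralogs mappable."""
    cls = classify_duplicate_marker(("a", "b"), ("a", "c"))
    assert cls.class_name == "ab_ac"
    assert cls.mappable_paralogs == (1, 2)
    assert cls.expected == {"a": 0.25, "a/c": 0.25, "a/b": 0.25, "b/c": 0.25}


def test_both_paralogs_polymorphic_distinct_alleles():
    cls = classify_duplicate_marker(("a", "b"), ("c", "d"))
    assert cls.class_name == "ab_cd"
    assert cls.expected == {"a/c": 0.25, "a/d": 0.25, "b/c": 0.25,
                            "b/d": 0.25}


def test_unmappable_classes():
    assert classify_duplicate_marker(("a", "a"), ("b", "b")).expected \
        == {"a/b": 1.0}
    assert not classify_duplicate_marker(("a", "a"), ("b", "b")).is_mappable
    ab_ab = classify_duplicate_marker(("a", "b"), ("a", "b"))
    assert ab_ab.class_name == "ab_ab"
    assert not ab_ab.is_mappable
    assert ab_ab.expected == {"a": 0.25, "a/b": 0.5, "b": 0.25}


def test_classification_normalises_paralog_order():
    """A heterozygous first paralog with a fixed second paralog is the same
    class with the mappable paralog relabelled."""
    cls = classify_duplicate_marker(("a", "b"), ("a", "a"))
    assert cls.class_name == "aa_ab"
    assert cls.mappable_paralogs == (1,)


def test_expand_duplicate_calls_recovers_paralog_gametes():
    cls = classify_duplicate_marker(("a", "b"), ("a", "c"))
    calls = pd.Series(["a", "a/c", "a/b", "b/c", "-"])
    out = expand_duplicate_calls(calls, cls)
    assert list(out["P1"]) == ["a", "a", "b", "b", "-"]
    assert list(out["P2"]) == ["a", "c", "a", "c", "-"]


@pytest.mark.parametrize("parents", [
    (("a", "a"), ("a", "b")),
    (("a", "a"), ("b", "c")),
    (("a", "b"), ("a", "c")),
    (("a", "b"), ("c", "d")),
    (("a", "b"), ("a", "b")),
    (("a", "a"), ("b", "b")),
])
def test_infer_duplicate_class_round_trip(parents):
    """Simulated composite calls recover the generating class: inferred
    parental genotypes reproduce the expected segregation frequencies."""
    cls = classify_duplicate_marker(*parents)
    rng = np.random.default_rng(17)
    genos = list(cls.expected)
    probs = [cls.expected[g] for g in genos]
    calls = pd.Series(rng.choice(genos, size=200, p=probs))
    inferred = infer_duplicate_class(calls)
    assert inferred is not None
    assert classify_duplicate_marker(*inferred).expected == cls.expected


def test_segregation_check_exact_and_extreme():
    expected = {"a": 0.5, "a/b": 0.5}
    stat, p, ok = segregation_check({"a": 23, "a/b": 23}, expected)
    assert stat == 0.0 and ok
    _, p_bad, bad = segregation_check({"a": 46}, expected)
    assert not bad
    with pytest.raises(ValueError):
        segregation_check({}, expected)


def test_segregation_check_type_one_error_rate():
    """Under the true 1:1 model the goodness test rejects ~5% of 1000
    replicates at alpha = 0.05."""
    rng = np.random.default_rng(18)
    fails = 0
    for _ in range(1000):
        n_a = rng.binomial(46, 0.5)
        _, _, ok = segregation_check({"a": n_a, "a/b": 46 - n_a},
                                     {"a": 0.5, "a/b": 0.5}, alpha=0.05)
        fails += not ok
    assert 20 <= fails <= 90  # 5% nominal, discreteness tolerated


def test_composite_truth_collapses_paralog_pairs(duplicated_genome,
                                                 haploid_family):
    comp = composite_truth(duplicated_genome, haploid_family)
    pair_ids = {l.paralog_id for l in duplicated_genome.loci
                if l.is_duplicated}
    assert pair_ids <= set(comp.columns)
    for pid in pair_ids:
        p1, p2 = (l for l in duplicated_genome.loci if l.paralog_id == pid)
        for ind in haploid_family.index:
            g1 = haploid_family.at[ind, p1.locus_id]
            g2 = haploid_family.at[ind, p2.locus_id]
            expect = g1 if g1 == g2 else "/".join(sorted((g1, g2)))
            assert comp.at[ind, pid] == expect
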