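"""Reference database: clustering, screens, duplicate identification."""

import numpy as np
import pandas as pd
import pytest

from salhap.genome import (ChromosomeDef, GenomeConfig, HomeologPair,
                           LocusLayout, build_genome)
from salhap.genotyping import align_to_db, call_genotypes
from salhap.meiosis import CrossSpec, simulate_cross
from salhap.reads import simulate_reads
from salhap.refdb import (ScreeningParams, cluster_reads, coverage_filter,
                          dust_score, identify_duplicates,
                          low_complexity_screen, self_align_screen)
from salhap.sequtils import mutate, random_sequence

PARAMS = ScreeningParams()


def _pileup(rows):
    return pd.DataFrame(rows, columns=["individual_id", "locus_id",
                                       "allele", "depth"])


def test_cluster_merges_within_mismatch_radius():
    rng = np.random.default_rng(0)
    base = random_sequence(74, rng)
    near = mutate(base, [3, 9], ["A" if base[3] != "A" else "C",
                                 "A" if base[9] != "A" else "C"])
    res = cluster_reads(_pileup([("I1", "x", base, 30),
                                 ("I1", "x", near, 10)]), PARAMS)
    assert len(res.clusters) == 1


def test_cluster_splits_beyond_mismatch_radius():
    rng = np.random.default_rng(1)
    base = random_sequence(74, rng)
    alt = list(base)
    for pos in (2, 11, 23, 40):
        alt[pos] = "A" if base[pos] != "A" else "C"
    res = cluster_reads(_pileup([("I1", "x", base, 30),
                                 ("I1", "x", "".join(alt), 25)]), PARAMS)
    assert len(res.clusters) == 2


def test_cluster_flags_ambiguous_sequences():
    """A sequence within the radius of two cluster consensi is flagged and
    left unassigned."""
    rng = np.random.default_rng(2)
    base = random_sequence(74, rng)
    far = list(base)
    for pos in (1, 5, 12, 30, 44, 60):  # 6 mismatches from base
        far[pos] = "A" if base[pos] != "A" else "C"
    far = "".join(far)
    mid = list(base)
    for pos in (1, 5, 12):  # 3 from base, 3 from far
        mid[pos] = far[pos]
    mid = "".join(mid)
    res = cluster_reads(_pileup([("I1", "x", base, 40),
                                 ("I1", "x", far, 35),
                                 ("I1", "x", mid, 5)]), PARAMS)
    flagged = res.assignments[res.assignments["ambiguous"]]
    assert list(flagged["allele"]) == [mid]
    assert len(res.clusters) == 2


def test_cluster_recovers_simulated_loci_exactly():
    """Zero-noise simulation: one cluster per simulated locus."""
    cfg = GenomeConfig([ChromosomeDef("C1", 0.0, 50.0)],
                       layout=LocusLayout(markers_per_chromosome=100,
                                          dam_het_prob=0.0), rng_seed=11)
    g = build_genome(cfg)
    hap = simulate_cross(g, CrossSpec("haploid", 10),
                         np.random.default_rng(12))
    piles = simulate_reads(g, hap, mean_depth=30, depth_dispersion=None,
                           error_rate=0.0, rng=np.random.default_rng(13))
    res = cluster_reads(piles, PARAMS)
    assert len(res.clusters) == 100
    assert set(res.clusters["consensus"]) == {l.sequence for l in g.loci}


@pytest.mark.parametrize("n_covered,kept", [(90, True), (84, False)])
def test_coverage_rule_strict_inequalities(n_covered, kept):
    """Retention needs depth above 5 in more than 85% of individuals."""
    clusters = pd.DataFrame({"cluster_id": ["L1"], "consensus": ["A" * 74],
                             "n_alleles": [1], "total_depth": [600]})
    depth = pd.DataFrame(
        [[6] * n_covered + [0] * (100 - n_covered)],
        index=["L1"], columns=[f"I{i}" for i in range(100)])
    db = coverage_filter(clusters, depth, 100, PARAMS)
    assert (db["status"].iloc[0] == "unique") is kept


def test_coverage_requires_individuals():
    clusters = pd.DataFrame({"cluster_id": [], "consensus": [],
                             "n_alleles": [], "total_depth": []})
    with pytest.raises(ValueError):
        coverage_filter(clusters, pd.DataFrame(), 0, PARAMS)


def _db(seqs, status="unique"):
    return pd.DataFrame({"locus_id": [f"L{i}" for i in range(len(seqs))],
                         "sequence": seqs, "status": status, "reason": ""})


def test_self_align_excludes_both_members():
    rng = np.random.default_rng(3)
    a = random_sequence(74, rng)
    b = mutate(a, [0, 1, 2], ["A" if a[i] != "A" else "C" for i in (0, 1, 2)])
    c = random_sequence(74, rng)
    db = self_align_screen(_db([a, b, c]), PARAMS)
    assert list(db["status"]) == ["excluded_multimap", "excluded_multimap",
                                  "unique"]


def test_self_align_single_locus_retained():
    db = self_align_screen(_db([random_sequence(74,
                                                np.random.default_rng(4))]),
                           PARAMS)
    assert db["status"].iloc[0] == "unique"


def test_low_complexity_screen_repeats_and_runs():
    seqs = ["AC" * 37, "A" * 74,
            random_sequence(74, np.random.default_rng(5))]
    db = low_complexity_screen(_db(seqs), PARAMS)
    assert list(db["status"]) == ["excluded_lowcomplexity",
                                  "excluded_lowcomplexity", "unique"]


def test_dust_threshold_masks_under_one_percent_of_random():
    rng = np.random.default_rng(6)
    scores = [dust_score(random_sequence(74, rng)) for _ in range(3000)]
    assert np.mean(np.array(scores) > PARAMS.low_complexity_threshold) < 0.01


def test_duplicate_rule_requires_two_heterozygous_haploids():
    db = _db([random_sequence(74, np.random.default_rng(7))])
    calls_two = {"F1": pd.DataFrame({"L0": ["a/b", "a/b", "a"]},
                                    index=["I1", "I2", "I3"])}
    calls_one = {"F1": pd.DataFrame({"L0": ["a/b", "a", "a"]},
                                    index=["I1", "I2", "I3"])}
    assert identify_duplicates(db, calls_two, PARAMS)["status"].iloc[0] \
        == "duplicated"
    assert identify_duplicates(db, calls_one, PARAMS)["status"].iloc[0] \
        == "unique"


def test_duplicate_rule_rejects_non_haploid_calls():
    db = _db([random_sequence(74, np.random.default_rng(8))])
    calls = {"F1": pd.DataFrame({"L0": ["a/b"]}, index=["I1"])}
    with pytest.raises(ValueError, match="haploid"):
        identify_duplicates(db, calls, PARAMS,
                            cross_types={"F1": "gynogenetic_diploid"})


def test_pipeline_recovers_duplicates_with_perfect_specificity():
    """Zero-error simulation with 50 true duplicated pairs: the full
    screening chain flags exactly the collapsed duplicated loci and no
    unique locus (specificity 1, sensitivity 1), and every input locus ends
    in exactly one status."""
    chroms = [ChromosomeDef("C1", 40.0, 40.0), ChromosomeDef("C2", 0.0, 60.0)]
    cfg = GenomeConfig(
        chroms,
        homeolog_pairs=[HomeologPair("C1q", "C2q", divergence=2, n_pairs=50,
                                     classes=("aa_ab", "ab_ac", "aa_bc",
                                              "ab_cd", "aa_bb", "ab_ab"))],
        layout=LocusLayout(markers_per_chromosome=20), rng_seed=14)
    g = build_genome(cfg)
    rng = np.random.default_rng(15)
    hap = simulate_cross(g, CrossSpec("haploid", 20, family_id="F1"), rng)
    piles = simulate_reads(g, hap, mean_depth=30, depth_dispersion=None,
                           error_rate=0.0, rng=rng)

    clustered = cluster_reads(piles, PARAMS)
    db = coverage_filter(clustered.clusters, clustered.depth, 20, PARAMS)
    db = self_align_screen(db, PARAMS)
    db = low_complexity_screen(db, PARAMS)
    assigned = align_to_db(piles, db, PARAMS)
    calls = call_genotypes(assigned, PARAMS)
    db = identify_duplicates(db, {"F1": calls}, PARAMS)

    # every locus in exactly one status
    assert db["status"].isin(("unique", "duplicated", "excluded_coverage",
                              "excluded_multimap",
                              "excluded_lowcomplexity")).all()
    # duplicated status is exact among loci surviving the screens: every
    # retained collapsed paralog cluster is flagged, no unique locus is
    from salhap.sequtils import hamming_matrix
    dup_truth = [l.sequence for l in g.loci if l.is_duplicated]
    uniq_truth = [l.sequence for l in g.loci if not l.is_duplicated]
    dup_called = db.loc[db["status"] == "duplicated", "sequence"].tolist()
    uniq_called = db.loc[db["status"] == "unique", "sequence"].tolist()
    excluded = db.loc[db["status"].str.startswith("excluded"),
                      "sequence"].tolist()
    n_dup_excluded = (int((hamming_matrix(excluded, dup_truth)
                           .min(axis=1) <= 3).sum()) if excluded else 0)
    assert len(dup_called) == 50 - n_dup_excluded
    assert (hamming_matrix(dup_called, dup_truth).min(axis=1) <= 3).all()
    # specificity 1.0: every unique call is a true unique locus (consensus
    # may sit one base off the reference haplotype at the segregating SNP)
    assert (hamming_matrix(uniq_called, uniq_truth).min(axis=1) <= 1).all()
    assert (hamming_matrix(uniq_called, dup_truth).min(axis=1) > 3).all()
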