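"""Two-point analysis, grouping, ordering, merging, anchoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from salhap.genome import (ChromosomeDef, GenomeConfig, LocusLayout,
                           LocusSpec, build_genome)
from salhap.linkage import (LinkageMap, LinkageParams, anchor_groups,
                            build_map, encode_haploid_calls, form_groups,
                            map_distance, merge_maps, order_markers,
                            two_point, two_point_matrix)
from salhap.meiosis import CrossSpec, simulate_cross


def _calls(bits):
    return pd.Series(["a" if b == 0 else "b" for b in bits])


def test_two_point_complete_linkage():
    """46 offspring, no recombinants: rf 0 and LOD = 46 log10(2)."""
    a = _calls([0, 1] * 23)
    res = two_point(a, a)
    assert res.rf == 0.0
    assert res.r == 0
    assert abs(res.lod - 46 * np.log10(2)) < 1e-9


def test_two_point_independence_and_phase():
    a = _calls([0] * 23 + [1] * 23)
    b = _calls([0] * 12 + [1] * 11 + [0] * 12 + [1] * 11)  # 23 discordant
    res = two_point(a, b)
    assert res.rf == 0.5
    assert abs(res.lod) < 1e-9
    # phase swap: raw rf flips to 1 - rf, folded rf unchanged
    swapped = a.map({"a": "b", "b": "a"})
    r1, r2 = two_point(a, b), two_point(swapped, b)
    assert abs(r1.rf_raw - (1 - r2.rf_raw)) < 1e-12
    assert r1.rf == r2.rf


def test_two_point_requires_joint_observations():
    with pytest.raises(ValueError):
        two_point(pd.Series(["-", "-"]), pd.Series(["a", "b"]))


def test_groups_on_independent_chromosomes():
    """Two unlinked chromosomes with ample offspring form exactly two
    groups at the starting LOD."""
    cfg = GenomeConfig([ChromosomeDef("C1", 0.0, 50.0, kind="acrocentric"),
                        ChromosomeDef("C2", 0.0, 50.0, kind="acrocentric")],
                       layout=LocusLayout(markers_per_chromosome=10),
                       rng_seed=31)
    g = build_genome(cfg)
    hap = simulate_cross(g, CrossSpec("haploid", 100),
                         np.random.default_rng(32))
    codes, kept = encode_haploid_calls(hap)
    tp = two_point_matrix(codes)
    groups, final_lod = form_groups(kept, tp["rf"], tp["lod"],
                                    LinkageParams(target_groups=2))
    assert len(groups) == 2
    assert final_lod == 3.0
    truth = {m: m[:2] for m in kept}
    for members in groups.values():
        assert len({truth[m] for m in members}) == 1


def test_groups_partition_invariant_to_marker_order():
    cfg = GenomeConfig([ChromosomeDef("C1", 0.0, 50.0, kind="acrocentric"),
                        ChromosomeDef("C2", 0.0, 50.0, kind="acrocentric")],
                       layout=LocusLayout(markers_per_chromosome=8),
                       rng_seed=33)
    g = build_genome(cfg)
    hap = simulate_cross(g, CrossSpec("haploid", 80),
                         np.random.default_rng(34))
    perm = hap[list(np.random.default_rng(35).permutation(hap.columns))]

    def partition(table):
        codes, kept = encode_haploid_calls(table)
        tp = two_point_matrix(codes)
        groups, _ = form_groups(kept, tp["rf"], tp["lod"],
                                LinkageParams(target_groups=2))
        return {frozenset(ms) for ms in groups.values()}

    assert partition(hap) == partition(perm)


def test_escalation_to_singletons():
    rng = np.random.default_rng(36)
    table = pd.DataFrame({f"M{i}": _calls(rng.integers(0, 2, 40))
                          for i in range(6)})
    codes, kept = encode_haploid_calls(table)
    tp = two_point_matrix(codes)
    groups, _ = form_groups(kept, tp["rf"], tp["lod"],
                            LinkageParams(lod_start=1e6, target_groups=6))
    assert len(groups) == 6  # unreachable LOD: every marker its own group


def test_form_groups_needs_enough_markers():
    with pytest.raises(ValueError, match="markers"):
        form_groups(["M1"], np.zeros((1, 1)), np.zeros((1, 1)),
                    LinkageParams(target_groups=34))


def test_order_three_markers_brute_force():
    """Recombinant counts r(AB)=2, r(BC)=3, r(AC)=5 order as A-B-C."""
    a = [0] * 23 + [1] * 23
    b = list(a)
    for i in (0, 1):  # r(AB) = 2
        b[i] ^= 1
    c = list(b)
    for i in (2, 3, 4):  # r(BC) = 3, r(AC) = 5
        c[i] ^= 1
    table = pd.DataFrame({"A": _calls(a), "B": _calls(b), "C": _calls(c)})
    out = order_markers(table, ["A", "B", "C"], LinkageParams())
    assert list(out["marker"]) == ["A", "B", "C"]
    assert out["position"].is_monotonic_increasing


def test_cosegregating_markers_bin_together():
    a = _calls([0, 1] * 20)
    table = pd.DataFrame({"M1": a, "M2": a, "M3": a.map({"a": "b",
                                                         "b": "a"})})
    out = order_markers(table, ["M1", "M2", "M3"], LinkageParams())
    assert set(out["bin"]) == {"M1"}
    assert (out["position"] == 0.0).all()


def test_order_recovery_with_dense_offspring():
    """8 markers, 1000 haploid offspring, complete interference: the
    recovered order equals the simulated order (up to reversal)."""
    loci = [LocusSpec(f"M{k}", "C1", float(p))
            for k, p in enumerate(np.linspace(5, 60, 8))]
    cfg = GenomeConfig([ChromosomeDef("C1", 0.0, 60.0, kind="acrocentric")],
                       loci=loci, rng_seed=37)
    g = build_genome(cfg)
    hap = simulate_cross(g, CrossSpec("haploid", 1000),
                         np.random.default_rng(38))
    out = order_markers(hap, [l.locus_id for l in g.loci], LinkageParams())
    got = list(out["marker"])
    truth = [f"M{k}" for k in range(8)]
    assert got == truth or got == truth[::-1]


def test_order_objective_matches_exhaustive_oracle():
    """For <= 8 markers the returned order attains the exhaustive-search
    minimum of the adjacent recombinant count."""
    rng = np.random.default_rng(39)
    loci = [LocusSpec(f"M{k}", "C1", float(p))
            for k, p in enumerate(sorted(rng.uniform(0, 60, 7)))]
    cfg = GenomeConfig([ChromosomeDef("C1", 0.0, 60.0, kind="acrocentric")],
                       loci=loci, rng_seed=40)
    g = build_genome(cfg)
    hap = simulate_cross(g, CrossSpec("haploid", 60),
                         np.random.default_rng(41))
    out = order_markers(hap, [l.locus_id for l in g.loci], LinkageParams())
    reps = list(dict.fromkeys(out["bin"]))
    codes, kept = encode_haploid_calls(hap[reps])
    r = two_point_matrix(codes)["r"]
    idx = {m: i for i, m in enumerate(kept)}

    def cost(order):
        return sum(r[idx[u], idx[v]] for u, v in zip(order, order[1:]))

    best = min(cost(list(p)) for p in itertools.permutations(reps))
    assert cost(reps) == best


def test_map_length_recovered_with_dense_markers():
    """Complete interference, 40 markers, 1000 offspring: each arm maps to
    ~50 cM and the total metacentric map length lands within 10%."""
    cfg = GenomeConfig([ChromosomeDef("C1", 60.0, 60.0)],
                       layout=LocusLayout(markers_per_chromosome=40),
                       rng_seed=42)
    g = build_genome(cfg)
    hap = simulate_cross(g, CrossSpec("haploid", 1000,
                                      interference="complete"),
                         np.random.default_rng(43))
    lmap = build_map(hap, LinkageParams(target_groups=1), family_id="F")
    assert lmap.n_groups == 1
    # one obligate crossover per arm: 50 cM of gamete map per arm
    assert abs(lmap.total_length - 100.0) < 10.0


def test_map_function_values():
    assert map_distance(0.0, "kosambi") == 0.0
    assert abs(map_distance(0.2, "haldane") - (-50 * np.log(0.6))) < 1e-9
    assert abs(map_distance(0.2, "morgan") - 20.0) < 1e-12
    assert map_distance(0.2, "kosambi") < map_distance(0.2, "haldane")


def _simple_map(order, family, positions=None):
    positions = positions or list(np.arange(len(order), dtype=float) * 10)
    return LinkageMap(table=pd.DataFrame({
        "group": "G1", "marker": order, "position": positions}),
        family_id=family)


def test_merge_identical_maps_idempotent():
    maps = [_simple_map(["A", "B", "C", "D"], f"F{i}") for i in range(3)]
    merged = merge_maps(maps)
    sub = merged.group_table(merged.groups[0])
    assert list(sub["marker"]) == ["A", "B", "C", "D"]
    assert list(sub["position"]) == [0.0, 10.0, 20.0, 30.0]
    assert merged.conflicts.empty


def test_merge_interpolates_family_unique_markers():
    """Family A maps {1,2,3}, family B {2,3,4}: the consensus covers
    {1,2,3,4} in the precedence order."""
    merged = merge_maps([_simple_map(["M1", "M2", "M3"], "FA"),
                         _simple_map(["M2", "M3", "M4"], "FB")])
    sub = merged.group_table(merged.groups[0])
    assert list(sub["marker"]) == ["M1", "M2", "M3", "M4"]
    assert sub["position"].is_monotonic_increasing


def test_merge_drops_conflicting_marker():
    """Tied opposite orders for a marker pair drop one marker into the
    conflict report."""
    merged = merge_maps([_simple_map(["M1", "M2", "M3", "M4"], "FA"),
                         _simple_map(["M1", "M3", "M2", "M4"], "FB")])
    sub = merged.group_table(merged.groups[0])
    assert len(merged.conflicts) == 1
    dropped = merged.conflicts["marker"].iloc[0]
    assert dropped in {"M2", "M3"}
    assert dropped not in set(sub["marker"])


def test_merge_handles_reversed_family_orientation():
    merged = merge_maps([_simple_map(["M1", "M2", "M3", "M4"], "FA"),
                         _simple_map(["M4", "M3", "M2", "M1"], "FB",
                                     positions=[0.0, 12.0, 24.0, 36.0])])
    sub = merged.group_table(merged.groups[0])
    assert list(sub["marker"]) in (["M1", "M2", "M3", "M4"],
                                   ["M4", "M3", "M2", "M1"])
    assert merged.conflicts.empty


def test_anchor_majority_vote_and_conflict():
    lmap = _simple_map(["M1", "M2", "M3"], "F")
    anchors = pd.DataFrame({"marker": ["M1", "M2", "M3"],
                            "chromosome": ["chr7", "chr7", "chr9"],
                            "arm": ["p", "q", "q"]})
    out = anchor_groups(lmap, anchors)
    assert (out.table["chromosome"] == "chr7").all()
    assert (out.conflicts["reason"].str.contains("anchor conflict")).any()


def test_anchor_orientation_flip():
    """A group mapped q-arm-first is flipped so p-arm anchors come first."""
    lmap = _simple_map(["M1", "M2", "M3"], "F")
    anchors = pd.DataFrame({"marker": ["M1", "M3"],
                            "chromosome": ["chr1", "chr1"],
                            "arm": ["q", "p"]})
    out = anchor_groups(lmap, anchors)
    sub = out.group_table(out.groups[0])
    assert list(sub["marker"]) == ["M3", "M2", "M1"]
    assert list(sub["position"]) == [0.0, 10.0, 20.0]


def test_anchor_position_concordance_orientation():
    lmap = _simple_map(["M1", "M2", "M3", "M4"], "F")
    anchors = pd.DataFrame({"marker": ["M1", "M2", "M4"],
                            "chromosome": "chr2",
                            "arm": ["q", "q", "q"],
                            "position": [55.0, 40.0, 10.0]})
    out = anchor_groups(lmap, anchors)
    sub = out.group_table(out.groups[0])
    assert list(sub["marker"]) == ["M4", "M3", "M2", "M1"]


def test_anchorless_group_unlabelled():
    lmap = _simple_map(["M1", "M2"], "F")
    out = anchor_groups(lmap, pd.DataFrame({"marker": ["X"],
                                            "chromosome": ["chr1"]}))
    assert (out.table["chromosome"] == "").all()
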