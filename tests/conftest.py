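"""Shared fixtures: small genomes and simulated crosses built at test time."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from salhap.genome import (ChromosomeDef, GenomeConfig, HomeologPair,
                           LocusLayout, LocusSpec, build_genome,
                           standard_karyotype)
from salhap.meiosis import CrossSpec, simulate_cross
from salhap.pipeline import make_fixtures, run_pipeline


def brute_force_half_tetrad(k: int):
    """Exact heterozygote probability of a gynogenetic diploid at a locus
    with k crossovers between locus and centromere, by enumerating every
    equally likely non-sister chromatid pair choice and both meiosis-I
    poles.  Returns a Fraction."""
    from fractions import Fraction

    pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
    het = total = 0
    for combo in itertools.product(pairs, repeat=k):
        cur = [0, 0, 1, 1]
        for i, j in combo:
            cur[i], cur[j] = cur[j], cur[i]
        for pole in (0, 1):
            total += 1
            het += cur[2 * pole] != cur[2 * pole + 1]
    return Fraction(het, total)


@pytest.fixture(scope="session")
def single_arm_genome():
    """One acrocentric chromosome, markers every 10 cM along a 60 cM arm."""
    loci = [LocusSpec(f"M{k:02d}", "C1", float(p))
            for k, p in enumerate(range(0, 61, 10))]
    cfg = GenomeConfig([ChromosomeDef("C1", 0.0, 60.0, kind="acrocentric")],
                       loci=loci, rng_seed=5)
    return build_genome(cfg)


@pytest.fixture(scope="session")
def metacentric_genome():
    """One metacentric chromosome (40 + 40 cM), 17 evenly spaced markers
    (one exactly at the centromere)."""
    cfg = GenomeConfig([ChromosomeDef("C1", 40.0, 40.0, kind="metacentric")],
                       loci=None,
                       layout=LocusLayout(markers_per_chromosome=17,
                                          spacing="even"),
                       rng_seed=9)
    return build_genome(cfg)


@pytest.fixture(scope="session")
def duplicated_genome():
    """Two chromosomes with one homeolog arm pair carrying the four
    mappable duplicate classes plus unique loci."""
    chroms = [ChromosomeDef("C1", 30.0, 30.0, kind="metacentric"),
              ChromosomeDef("C2", 0.0, 40.0, kind="acrocentric")]
    pair = HomeologPair("C1q", "C2q", divergence=2, n_pairs=4,
                        classes=("aa_ab", "ab_ac", "aa_bc", "ab_cd"))
    loci = [LocusSpec(f"U{k:02d}", "C1", float(p))
            for k, p in enumerate(np.linspace(0, 60, 8))]
    loci += [LocusSpec(f"V{k:02d}", "C2", float(p))
             for k, p in enumerate(np.linspace(0, 40, 6))]
    cfg = GenomeConfig(chroms, homeolog_pairs=[pair], loci=loci, rng_seed=3)
    return build_genome(cfg)


@pytest.fixture(scope="session")
def haploid_family(duplicated_genome):
    rng = np.random.default_rng(21)
    spec = CrossSpec("haploid", 40, family_id="HapT",
                     interference="complete")
    return simulate_cross(duplicated_genome, spec, rng)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One full tiny-scale pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("tiny_run")
    cfg = make_fixtures("tiny", seed=2)
    manifest = run_pipeline(cfg, out, seed=2)
    return {"cfg": cfg, "out": out, "manifest": manifest}


@pytest.fixture(scope="session")
def chinook_karyotype():
    return standard_karyotype()
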