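"""Female meiosis simulator: tetrads, crossovers and three cross types.

A tetrad is the four-chromatid bundle of one meiosis.  Chromatids 0,1 are
sisters carrying maternal haplotype 0 centromeres, chromatids 2,3 carry
haplotype 1.  Each crossover picks one of the four non-sister chromatid pairs
uniformly (no chromatid interference) and exchanges the segments distal to
the crossover point on that arm.

Cross types
-----------
haploid
    Gynogenetic haploid: one random chromatid per tetrad (UV-inactivated
    sperm); hemizygous everywhere, so unique loci score homozygous and only
    collapsed duplicated loci can look heterozygous.
gynogenetic_diploid
    Second polar body retained: the offspring receives both meiosis-II
    products of one randomly chosen meiosis-I pole (a half-tetrad).  A locus
    is heterozygous iff an odd pattern of exchange separated it from its
    centromere — the basis of gene-centromere mapping.
diploid
    One chromatid from each parent's tetrad.

Interference models: ``complete`` places exactly one crossover per arm at a
uniform position (the salmonid-like regime of one obligate crossover per
arm); ``none`` draws a Poisson count with mean equal to the arm length in
Morgans; ``gamma`` uses a renewal process with Gamma(nu)-distributed
inter-crossover distances (mean 1 Morgan), reducing to ``none`` at nu = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from salhap.genome import ChromosomeDef, Genome

#: the four non-sister chromatid pairs a crossover can involve
NON_SISTER_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))

INTERFERENCE_MODELS = ("complete", "none", "gamma")


@dataclass(frozen=True)
class CrossSpec:
    cross_type: str  # haploid | gynogenetic_diploid | diploid
    n_offspring: int
    family_id: str = "F1"
    interference: str = "complete"
    nu: Optional[float] = None  # gamma shape, required for "gamma"
    with_sire: Optional[bool] = None

    def __post_init__(self):
        if self.cross_type not in ("haploid", "gynogenetic_diploid",
                                   "diploid"):
            raise ValueError(f"unknown cross type {self.cross_type!r}")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.interference not in INTERFERENCE_MODELS:
            raise ValueError(f"unknown interference model "
                             f"{self.interference!r}")
        if self.interference == "gamma" and (self.nu is None or self.nu <= 0):
            raise ValueError("gamma interference requires nu > 0")
        if self.with_sire and self.cross_type != "diploid":
            raise ValueError("gynogenetic crosses have no sire: offspring "
                             "carry only maternal chromatids")


class Tetrad:
    """Crossover record of one meiosis for one chromosome."""

    def __init__(self, chromosome: str, crossovers: dict):
        # crossovers: arm -> list of (dist_from_centromere, chromatid_i, j),
        # sorted by distance
        self.chromosome = chromosome
        self.crossovers = crossovers

    def n_crossovers(self, arm: Optional[str] = None) -> int:
        if arm is not None:
            return len(self.crossovers.get(arm, ()))
        return sum(len(v) for v in self.crossovers.values())

    def haps_at(self, arm: str, dists) -> np.ndarray:
        """Maternal haplotype (0/1) of each chromatid at the given
        centromere distances on one arm; shape (len(dists), 4).

        A crossover exactly at a locus does not separate it from the
        centromere (strict inequality), so a locus at distance 0 always
        segregates with its centromere.
        """
        dists = np.atleast_1d(np.asarray(dists, dtype=float))
        xs = self.crossovers.get(arm, [])
        out = np.empty((len(dists), 4), dtype=np.int8)
        cur = np.array([0, 0, 1, 1], dtype=np.int8)
        k = 0
        for idx in np.argsort(dists, kind="stable"):
            d = dists[idx]
            while k < len(xs) and xs[k][0] < d:
                _, i, j = xs[k]
                cur[i], cur[j] = cur[j], cur[i]
                k += 1
            out[idx] = cur
        return out


def _crossover_positions(length_cm: float, interference: str,
                         rng: np.random.Generator,
                         nu: Optional[float]) -> np.ndarray:
    if length_cm <= 0:
        return np.empty(0)
    if interference == "complete":
        return rng.uniform(0.0, length_cm, size=1)
    if interference == "none":
        n = rng.poisson(length_cm / 100.0)
        return np.sort(rng.uniform(0.0, length_cm, size=n))
    if interference == "gamma":
        # renewal from the centromere: Gamma(nu) gaps with mean 100 cM
        positions = []
        pos = 0.0
        while True:
            pos += rng.gamma(nu, 100.0 / nu)
            if pos >= length_cm:
                break
            positions.append(pos)
        return np.asarray(positions)
    raise ValueError(f"unknown interference model {interference!r}")


def simulate_tetrad(genome_or_chrom, chromosome: Optional[str] = None,
                    interference: str = "complete",
                    rng: Optional[np.random.Generator] = None,
                    nu: Optional[float] = None) -> Tetrad:
    """Simulate one tetrad for one chromosome.

    Accepts a :class:`Genome` plus chromosome name, or a
    :class:`ChromosomeDef` directly.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(genome_or_chrom, ChromosomeDef):
        chrom = genome_or_chrom
    else:
        if chromosome not in genome_or_chrom.chromosomes:
            raise ValueError(f"unknown chromosome {chromosome!r}")
        chrom = genome_or_chrom.chromosomes[chromosome]
    if interference not in INTERFERENCE_MODELS:
        raise ValueError(f"unknown interference model {interference!r}")
    crossovers = {}
    for arm in ("p", "q"):
        length = chrom.arm_length(arm)
        if length <= 0:
            continue
        dists = _crossover_positions(length, interference, rng, nu)
        pair_idx = rng.integers(0, 4, size=len(dists))
        crossovers[arm] = [(float(d), *NON_SISTER_PAIRS[k])
                           for d, k in zip(dists, pair_idx)]
    return Tetrad(chrom.name, crossovers)


def half_tetrad_het_prob(k: int) -> float:
    """Heterozygote probability of a gynogenetic diploid at a locus with
    ``k`` crossovers between locus and centromere: (2/3)(1 - (-1/2)^k).

    Holds under uniform non-sister chromatid choice (no chromatid
    interference): 0 at the centromere, 1 after an obligate single
    crossover, 2/3 in the many-crossover limit.
    """
    if k < 0:
        raise ValueError("crossover count must be >= 0")
    return (2.0 / 3.0) * (1.0 - (-0.5) ** k)


def _loci_by_chromosome(genome: Genome):
    grouped = {}
    for locus in genome.loci:
        grouped.setdefault(locus.chromosome, []).append(locus)
    out = {}
    for chrom_name, loci in grouped.items():
        chrom = genome.chromosomes[chrom_name]
        arms = {"p": [], "q": []}
        for locus in loci:
            arm, dist = chrom.arm_of(locus.position)
            arms[arm].append((locus, dist))
        out[chrom_name] = arms
    return out


def _gamete_labels(tetrad: Tetrad, arms, chromatid: int, genotypes) -> dict:
    """Allele labels carried by one chromatid at every locus of a
    chromosome; ``genotypes`` maps locus_id -> (label_hap0, label_hap1)."""
    labels = {}
    for arm, loci in arms.items():
        if not loci:
            continue
        dists = [d for _, d in loci]
        haps = tetrad.haps_at(arm, dists)
        for (locus, _), hap_row in zip(loci, haps):
            labels[locus.locus_id] = genotypes[locus.locus_id][hap_row[chromatid]]
    return labels


def simulate_cross(genome: Genome, spec: CrossSpec,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate true genotypes: offspring x loci (paralogs kept separate).

    Entries are allele labels: a single label for haploid offspring
    (hemizygous) and a sorted "x/y" pair for gynogenetic diploids and
    diploids.  Collapsing paralog pairs to the observed composite genotype
    is the genotyping stage's job (see
    :func:`salhap.genotyping.composite_truth`).
    """
    if rng is None:
        rng = np.random.default_rng()
    by_chrom = _loci_by_chromosome(genome)
    dam_geno = {l.locus_id: l.dam_genotype for l in genome.loci}
    if spec.cross_type == "diploid":
        for l in genome.loci:
            if l.sire_genotype is None:
                raise ValueError(f"{l.locus_id}: diploid cross requires a "
                                 f"sire genotype at every locus")
        sire_geno = {l.locus_id: l.sire_genotype for l in genome.loci}

    locus_ids = [l.locus_id for l in genome.loci]
    rows = []
    index = [f"{spec.family_id}_{i + 1:04d}" for i in range(spec.n_offspring)]
    for _ in range(spec.n_offspring):
        row = {}
        for chrom_name, arms in by_chrom.items():
            tetrad = simulate_tetrad(genome, chrom_name, spec.interference,
                                     rng, spec.nu)
            if spec.cross_type == "haploid":
                chromatid = int(rng.integers(0, 4))
                row.update(_gamete_labels(tetrad, arms, chromatid, dam_geno))
            elif spec.cross_type == "gynogenetic_diploid":
                # meiosis-I pole: sister chromatids (0,1) or (2,3)
                pole = int(rng.integers(0, 2))
                g1 = _gamete_labels(tetrad, arms, 2 * pole, dam_geno)
                g2 = _gamete_labels(tetrad, arms, 2 * pole + 1, dam_geno)
                for lid in g1:
                    row[lid] = "/".join(sorted((g1[lid], g2[lid])))
            else:  # diploid
                dam_gam = _gamete_labels(tetrad, arms,
                                         int(rng.integers(0, 4)), dam_geno)
                sire_tetrad = simulate_tetrad(genome, chrom_name,
                                              spec.interference, rng, spec.nu)
                sire_gam = _gamete_labels(sire_tetrad, arms,
                                          int(rng.integers(0, 4)), sire_geno)
                for lid in dam_gam:
                    row[lid] = "/".join(sorted((dam_gam[lid], sire_gam[lid])))
        rows.append(row)
    return pd.DataFrame(rows, index=index, columns=locus_ids)


def simulate_panel(genome: Genome, n_individuals: int,
                   rng: Optional[np.random.Generator] = None,
                   prefix: str = "P") -> pd.DataFrame:
    """Unrelated diploid individuals for reference-database construction.

    Each individual draws two alleles per locus uniformly from the alleles
    segregating at that locus (its parental genotype labels), emulating a
    population sample with intermediate allele frequencies.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    index = [f"{prefix}{i + 1:04d}" for i in range(n_individuals)]
    data = {}
    for locus in genome.loci:
        pool = sorted(set(locus.dam_genotype))
        draws = rng.integers(0, len(pool), size=(n_individuals, 2))
        data[locus.locus_id] = [
            "/".join(sorted((pool[i], pool[j]))) for i, j in draws]
    return pd.DataFrame(data, index=index,
                        columns=[l.locus_id for l in genome.loci])
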