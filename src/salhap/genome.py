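"""Genome model: karyotype, locus placement and parental allele assignment.

Coordinates are centimorgans on a per-chromosome axis with origin at the
p-terminus; the centromere sits at the p-arm length.  Metacentric chromosomes
have two mappable arms, acrocentric chromosomes effectively one (their p arm
is absent or tiny).  Homeologous arm pairs — descendants of one ancestral
chromosome retained after whole genome duplication — carry duplicated locus
pairs whose haplotypes differ at no more than three of the 74 positions, so
short-read clustering collapses the two paralogs into a single observed locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from salhap.sequtils import (
    LOCUS_LENGTH,
    alternate_base,
    mutate,
    random_sequence,
)

#: duplicated-marker classes, named by the dam's genotype at (paralog1, paralog2)
DUPLICATE_CLASSES = ("aa_bb", "ab_ab", "aa_ab", "aa_bc", "ab_ac", "ab_cd")

# dam genotype labels per paralog for each class; allele 'a' is the base
# sequence, 'b'/'c'/'d' carry substitutions at the pair's variant positions
_CLASS_GENOTYPES = {
    "aa_bb": (("a", "a"), ("b", "b")),
    "ab_ab": (("a", "b"), ("a", "b")),
    "aa_ab": (("a", "a"), ("a", "b")),
    "aa_bc": (("a", "a"), ("b", "c")),
    "ab_ac": (("a", "b"), ("a", "c")),
    "ab_cd": (("a", "b"), ("c", "d")),
}


@dataclass(frozen=True)
class ChromosomeDef:
    """One chromosome: arm lengths in cM, centromere at the p-arm length."""

    name: str
    p_len: float
    q_len: float
    kind: Optional[str] = None  # "metacentric" / "acrocentric"; inferred if None

    def __post_init__(self):
        if self.p_len < 0 or self.q_len <= 0:
            raise ValueError(f"{self.name}: arm lengths must be positive "
                             f"(p may be 0 for an acrocentric)")
        if self.p_len > self.q_len:
            raise ValueError(f"{self.name}: p arm must not exceed q arm")

    @property
    def centromere(self) -> float:
        return self.p_len

    @property
    def length(self) -> float:
        return self.p_len + self.q_len

    @property
    def is_metacentric(self) -> bool:
        if self.kind is not None:
            return self.kind == "metacentric"
        return self.p_len > 0

    def arm_of(self, position: float) -> tuple[str, float]:
        """Arm letter and distance from the centromere for a cM position."""
        if not 0 <= position <= self.length:
            raise ValueError(f"position {position} outside {self.name}")
        if position < self.centromere:
            return "p", self.centromere - position
        return "q", position - self.centromere

    def arm_length(self, arm: str) -> float:
        return self.p_len if arm == "p" else self.q_len


@dataclass(frozen=True)
class HomeologPair:
    """A homeologous arm pair with its paralog sequence divergence (1-3 nt)."""

    arm_a: str
    arm_b: str
    divergence: int = 2
    n_pairs: int = 8
    distal_fraction: float = 0.5
    classes: Sequence[str] = ("aa_ab", "ab_ac", "aa_bc", "ab_cd")

    def __post_init__(self):
        if self.arm_a == self.arm_b:
            raise ValueError("homeolog arms must be distinct")
        if not 1 <= self.divergence <= 3:
            raise ValueError("paralog divergence must be 1-3 mismatches")
        for c in self.classes:
            if c not in DUPLICATE_CLASSES:
                raise ValueError(f"unknown duplicate class {c!r}")


@dataclass
class LocusDef:
    """A RAD locus: 74-nt haplotypes and the parental genotype assignment."""

    locus_id: str
    chromosome: str
    position: float
    sequence: str  # base (reference) haplotype
    alleles: dict  # label -> 74-nt sequence, shared within a paralog pair
    dam_genotype: tuple[str, str]
    sire_genotype: Optional[tuple[str, str]] = None
    is_duplicated: bool = False
    paralog_id: Optional[str] = None
    dup_class: Optional[str] = None
    error_allele: Optional[str] = None

    def __post_init__(self):
        if len(self.sequence) != LOCUS_LENGTH:
            raise ValueError(
                f"{self.locus_id}: locus sequences must be exactly "
                f"{LOCUS_LENGTH} nt, got {len(self.sequence)}")
        for label, seq in self.alleles.items():
            if len(seq) != LOCUS_LENGTH:
                raise ValueError(f"{self.locus_id}: allele {label} is not "
                                 f"{LOCUS_LENGTH} nt")

    @property
    def dam_heterozygous(self) -> bool:
        return self.dam_genotype[0] != self.dam_genotype[1]


@dataclass(frozen=True)
class LocusSpec:
    """Compact locus request used in configs; sequences are generated."""

    locus_id: str
    chromosome: str
    position: float
    dam_het: bool = True
    duplicate_arm: Optional[str] = None  # partner arm for a paralog pair
    divergence: int = 2
    dup_class: str = "aa_ab"


@dataclass(frozen=True)
class LocusLayout:
    """Automatic unique-locus placement along every chromosome."""

    markers_per_chromosome: int = 12
    spacing: str = "even"  # "even" or "uniform"
    dam_het_prob: float = 1.0

    def __post_init__(self):
        if self.markers_per_chromosome < 0:
            raise ValueError("markers_per_chromosome must be >= 0")
        if self.spacing not in ("even", "uniform"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if not 0 <= self.dam_het_prob <= 1:
            raise ValueError("dam_het_prob must be in [0, 1]")


@dataclass
class GenomeConfig:
    chromosomes: list
    homeolog_pairs: list = field(default_factory=list)
    loci: Optional[list] = None  # explicit LocusSpec list; None -> use layout
    layout: Optional[LocusLayout] = None
    rng_seed: int = 0


class Genome:
    """A built genome: chromosomes, loci with alleles, homeolog pairing."""

    def __init__(self, config: GenomeConfig, loci: list[LocusDef]):
        self.config = config
        self.chromosomes = {c.name: c for c in config.chromosomes}
        self.homeolog_pairs = list(config.homeolog_pairs)
        self.loci = loci
        self.by_id = {l.locus_id: l for l in loci}
        if len(self.by_id) != len(loci):
            raise ValueError("duplicate locus_id in genome")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_mappable_arms(self) -> int:
        """Two arms per metacentric, one per acrocentric."""
        return sum(2 if c.is_metacentric else 1
                   for c in self.chromosomes.values())

    def arm_of(self, locus: LocusDef) -> str:
        chrom = self.chromosomes[locus.chromosome]
        arm, _ = chrom.arm_of(locus.position)
        return f"{locus.chromosome}{arm}"

    def centromere_distance(self, locus: LocusDef) -> float:
        chrom = self.chromosomes[locus.chromosome]
        _, dist = chrom.arm_of(locus.position)
        return dist

    def loci_df(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            rows.append({
                "locus_id": l.locus_id,
                "chromosome": l.chromosome,
                "position": l.position,
                "arm": self.arm_of(l),
                "centromere_dist": self.centromere_distance(l),
                "is_duplicated": l.is_duplicated,
                "paralog_id": l.paralog_id or "",
                "dup_class": l.dup_class or "",
                "dam_genotype": "/".join(l.dam_genotype),
            })
        cols = ["locus_id", "chromosome", "position", "arm",
                "centromere_dist", "is_duplicated", "paralog_id",
                "dup_class", "dam_genotype"]
        return pd.DataFrame(rows, columns=cols)

    def centromere_table(self) -> pd.DataFrame:
        rows = [{"chromosome": c.name, "centromere_cM": c.centromere,
                 "length_cM": c.length,
                 "kind": "metacentric" if c.is_metacentric else "acrocentric"}
                for c in self.chromosomes.values()]
        return pd.DataFrame(rows)

    def homeolog_table(self) -> pd.DataFrame:
        rows = [{"arm_a": h.arm_a, "arm_b": h.arm_b,
                 "divergence": h.divergence} for h in self.homeolog_pairs]
        return pd.DataFrame(rows, columns=["arm_a", "arm_b", "divergence"])

    def fasta_records(self):
        """(locus_id, base sequence) pairs for the truth FASTA."""
        return [(l.locus_id, l.sequence) for l in self.loci]


def standard_karyotype(n_metacentric: int = 16, n_acrocentric: int = 18,
                       metacentric_arm: float = 50.0,
                       acrocentric_arm: float = 60.0,
                       prefix: str = "Ots") -> list[ChromosomeDef]:
    """The salmonid-style karyotype used throughout: metacentrics first.

    Defaults give the 34-chromosome, 50-mappable-arm configuration (16
    metacentric + 18 acrocentric) of the Chinook salmon karyotype.
    """
    chroms = []
    for i in range(n_metacentric):
        chroms.append(ChromosomeDef(f"{prefix}{i + 1:02d}",
                                    metacentric_arm, metacentric_arm,
                                    kind="metacentric"))
    for i in range(n_acrocentric):
        chroms.append(ChromosomeDef(f"{prefix}{n_metacentric + i + 1:02d}",
                                    0.0, acrocentric_arm,
                                    kind="acrocentric"))
    return chroms


def _arm_lookup(chromosomes: dict, arm_name: str) -> tuple[ChromosomeDef, str]:
    chrom_name, arm = arm_name[:-1], arm_name[-1]
    if arm not in ("p", "q") or chrom_name not in chromosomes:
        raise ValueError(f"unknown arm {arm_name!r}")
    chrom = chromosomes[chrom_name]
    if chrom.arm_length(arm) <= 0:
        raise ValueError(f"arm {arm_name!r} has zero length")
    return chrom, arm


def _arm_position(chrom: ChromosomeDef, arm: str, dist: float) -> float:
    if arm == "p":
        return chrom.centromere - dist
    return chrom.centromere + dist


def _make_unique_locus(locus_id: str, chrom_name: str, position: float,
                       dam_het: bool, rng: np.random.Generator,
                       sire_het: bool = False) -> LocusDef:
    seq = random_sequence(LOCUS_LENGTH, rng)
    pos_snp, pos_err = rng.choice(LOCUS_LENGTH, size=2, replace=False)
    alleles = {"a": seq}
    alleles["b"] = mutate(seq, [pos_snp], [alternate_base(seq[pos_snp], 0)])
    dam = ("a", "b") if dam_het else ("a", "a")
    sire = ("a", "b") if sire_het else ("a", "a")
    err = mutate(seq, [pos_err], [alternate_base(seq[pos_err], 0)])
    return LocusDef(locus_id, chrom_name, float(position), seq, alleles,
                    dam_genotype=dam, sire_genotype=sire, error_allele=err)


def _make_duplicate_pair(pair_id: str, loc_a: tuple, loc_b: tuple,
                         divergence: int, dup_class: str,
                         rng: np.random.Generator) -> list[LocusDef]:
    """Build the two paralog LocusDefs of one duplicated locus.

    Alleles 'b', 'c', 'd' substitute different bases at the same ``divergence``
    variant positions of the shared base haplotype 'a', so every pairwise
    allele distance is at most ``divergence`` and the collapsed cluster stays
    within the 3-mismatch alignment radius.
    """
    if dup_class not in _CLASS_GENOTYPES:
        raise ValueError(f"unknown duplicate class {dup_class!r}")
    seq = random_sequence(LOCUS_LENGTH, rng)
    positions = rng.choice(LOCUS_LENGTH, size=divergence + 1, replace=False)
    var_pos, pos_err = positions[:-1], positions[-1]
    alleles = {"a": seq}
    for k, label in enumerate("bcd"):
        alleles[label] = mutate(seq, var_pos,
                                [alternate_base(seq[p], k) for p in var_pos])
    geno_a, geno_b = _CLASS_GENOTYPES[dup_class]
    used = sorted(set(geno_a) | set(geno_b))
    alleles = {k: v for k, v in alleles.items() if k in used}
    err = mutate(seq, [pos_err], [alternate_base(seq[pos_err], 0)])
    out = []
    for suffix, (chrom_name, position), geno in (
            ("P1", loc_a, geno_a), ("P2", loc_b, geno_b)):
        out.append(LocusDef(
            f"{pair_id}_{suffix}", chrom_name, float(position), seq,
            alleles, dam_genotype=geno, sire_genotype=(geno[0], geno[0]),
            is_duplicated=True, paralog_id=pair_id, dup_class=dup_class,
            error_allele=err))
    return out


def build_genome(config: GenomeConfig) -> Genome:
    """Instantiate a genome: deterministic sequences given ``rng_seed``.

    Unique loci come from ``config.loci`` (explicit) or ``config.layout``
    (even or uniform placement per chromosome); duplicated paralog pairs are
    placed on the arms of each declared homeolog pair, biased toward the
    distal ``distal_fraction`` of the arm.
    """
    rng = np.random.default_rng(config.rng_seed)
    chromosomes = {c.name: c for c in config.chromosomes}
    if not chromosomes:
        raise ValueError("genome needs at least one chromosome")
    homeolog_arms = set()
    for h in config.homeolog_pairs:
        for arm_name in (h.arm_a, h.arm_b):
            _arm_lookup(chromosomes, arm_name)  # validates
            homeolog_arms.add(arm_name)

    loci: list[LocusDef] = []

    if config.loci is not None:
        for spec in config.loci:
            if isinstance(spec, LocusDef):
                chrom = chromosomes.get(spec.chromosome)
                if chrom is None:
                    raise ValueError(f"unknown chromosome {spec.chromosome}")
                chrom.arm_of(spec.position)  # bounds check
                if spec.is_duplicated:
                    arm, _ = chrom.arm_of(spec.position)
                    if f"{spec.chromosome}{arm}" not in homeolog_arms:
                        raise ValueError(
                            f"{spec.locus_id}: duplicated locus on arm "
                            f"{spec.chromosome}{arm} not in homeolog_pairs")
                loci.append(spec)
                continue
            chrom = chromosomes.get(spec.chromosome)
            if chrom is None:
                raise ValueError(f"unknown chromosome {spec.chromosome}")
            chrom.arm_of(spec.position)  # bounds check
            if spec.duplicate_arm is not None:
                arm, dist = chrom.arm_of(spec.position)
                arm_a = f"{spec.chromosome}{arm}"
                declared = {tuple(sorted((h.arm_a, h.arm_b)))
                            for h in config.homeolog_pairs}
                if tuple(sorted((arm_a, spec.duplicate_arm))) not in declared:
                    raise ValueError(
                        f"{spec.locus_id}: paralog arm pair ({arm_a}, "
                        f"{spec.duplicate_arm}) not declared in homeolog_pairs")
                chrom_b, arm_b = _arm_lookup(chromosomes, spec.duplicate_arm)
                rel = dist / chrom.arm_length(arm)
                pos_b = _arm_position(chrom_b, arm_b,
                                      rel * chrom_b.arm_length(arm_b))
                loci.extend(_make_duplicate_pair(
                    spec.locus_id, (spec.chromosome, spec.position),
                    (chrom_b.name, pos_b), spec.divergence, spec.dup_class,
                    rng))
            else:
                loci.append(_make_unique_locus(
                    spec.locus_id, spec.chromosome, spec.position,
                    spec.dam_het, rng))
    elif config.layout is not None:
        layout = config.layout
        for chrom in config.chromosomes:
            n = layout.markers_per_chromosome
            if n == 0:
                continue
            if layout.spacing == "even":
                positions = np.linspace(0.0, chrom.length, n)
            else:
                positions = np.sort(rng.uniform(0.0, chrom.length, size=n))
            for k, pos in enumerate(positions):
                dam_het = bool(rng.random() < layout.dam_het_prob)
                loci.append(_make_unique_locus(
                    f"{chrom.name}_L{k + 1:03d}", chrom.name, pos,
                    dam_het, rng))

    for h in config.homeolog_pairs:
        chrom_a, arm_a = _arm_lookup(chromosomes, h.arm_a)
        chrom_b, arm_b = _arm_lookup(chromosomes, h.arm_b)
        for k in range(h.n_pairs):
            dup_class = h.classes[k % len(h.classes)]
            pos = []
            for chrom, arm in ((chrom_a, arm_a), (chrom_b, arm_b)):
                arm_len = chrom.arm_length(arm)
                dist = arm_len * (1.0 - h.distal_fraction * rng.random())
                pos.append((chrom.name, _arm_position(chrom, arm, dist)))
            pair_id = f"{h.arm_a}x{h.arm_b}_D{k + 1:02d}"
            loci.extend(_make_duplicate_pair(
                pair_id, pos[0], pos[1], h.divergence, dup_class, rng))

    return Genome(config, loci)
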