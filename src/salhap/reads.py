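"""Read-depth simulation on top of true genotypes.

The interface downstream stages consume is a pileup table: one row per
(individual, locus, allele sequence) with a read count.  Total depth per
locus per individual follows a negative binomial (configurable mean and
dispersion); reads split evenly between the carried alleles; sequencing
error re-assigns reads at ``error_rate`` to an error haplotype.  By default
the error haplotype is a third allele one substitution away from the locus
consensus, so error-driven false heterozygotes in haploids remain
distinguishable from real duplicated-locus heterozygotes; ``error_mode=
"parental"`` instead sends error reads to the alternate parental allele to
stress-test the duplicate-detection rule.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from salhap.genome import Genome

PILEUP_COLUMNS = ["individual_id", "locus_id", "allele", "depth"]


def _draw_depths(n: int, mean_depth: float, dispersion: Optional[float],
                 rng: np.random.Generator) -> np.ndarray:
    if dispersion is None:
        return np.full(n, int(round(mean_depth)), dtype=np.int64)
    p = dispersion / (dispersion + mean_depth)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_reads(genome: Genome, genotypes: pd.DataFrame,
                   mean_depth: float = 40.0,
                   depth_dispersion: Optional[float] = 5.0,
                   error_rate: float = 0.005,
                   rng: Optional[np.random.Generator] = None,
                   error_mode: str = "third_allele") -> pd.DataFrame:
    """Generate a pileup table from a true genotype matrix.

    ``genotypes`` is individuals x loci with allele-label entries as produced
    by :func:`salhap.meiosis.simulate_cross` (single label, or "x/y").
    ``depth_dispersion=None`` gives constant depth ``mean_depth`` (useful in
    tests); otherwise depth ~ NegativeBinomial with that mean and dispersion
    (variance = mean + mean^2 / dispersion).
    """
    if rng is None:
        rng = np.random.default_rng()
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if error_mode not in ("third_allele", "parental"):
        raise ValueError(f"unknown error_mode {error_mode!r}")

    individuals = list(genotypes.index)
    n_ind = len(individuals)
    out_ind, out_loc, out_allele, out_depth = [], [], [], []

    for locus_id in genotypes.columns:
        locus = genome.by_id[locus_id]
        col = genotypes[locus_id].to_numpy()
        depths = _draw_depths(n_ind, mean_depth, depth_dispersion, rng)
        errors = (rng.binomial(depths, error_rate)
                  if error_rate > 0 else np.zeros(n_ind, dtype=np.int64))
        for i in range(n_ind):
            total, n_err = int(depths[i]), int(errors[i])
            if total == 0:
                continue
            labels = col[i].split("/")
            counts: dict[str, int] = {}
            n_real = total - n_err
            if len(labels) == 1 or labels[0] == labels[1]:
                seq = locus.alleles[labels[0]]
                counts[seq] = n_real
            else:
                k = int(rng.binomial(n_real, 0.5))
                counts[locus.alleles[labels[0]]] = k
                counts[locus.alleles[labels[1]]] = n_real - k
            if n_err:
                if error_mode == "third_allele":
                    target = locus.error_allele
                else:
                    others = [s for lab, s in sorted(locus.alleles.items())
                              if lab not in labels]
                    target = others[0] if others else locus.error_allele
                counts[target] = counts.get(target, 0) + n_err
            for seq, depth in counts.items():
                if depth > 0:
                    out_ind.append(individuals[i])
                    out_loc.append(locus_id)
                    out_allele.append(seq)
                    out_depth.append(depth)

    return pd.DataFrame({
        "individual_id": out_ind, "locus_id": out_loc,
        "allele": out_allele, "depth": out_depth,
    }, columns=PILEUP_COLUMNS)
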