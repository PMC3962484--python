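"""Reference database of RAD loci.

The database is built in a fixed order: de-novo clustering of reads pooled
across individuals, a coverage filter (depth > 5 in more than 85% of
individuals by default), a self-alignment screen that removes loci matching
several database entries within the mismatch radius (repeats), a
low-complexity screen (DUST-style triplet statistic replacing an alignment
low-complexity filter), and finally identification of duplicated loci from
heterozygous genotype calls in gynogenetic haploid offspring — a single
heterozygous haploid is treated as possible sequencing error, two or more
mark the locus as duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from salhap.sequtils import encode, encode_many, hamming_matrix

STATUSES = ("unique", "duplicated", "excluded_coverage",
            "excluded_multimap", "excluded_lowcomplexity")

DB_COLUMNS = ["locus_id", "sequence", "status", "reason"]


@dataclass(frozen=True)
class ScreeningParams:
    min_depth_per_locus: int = 5          # strict ">" as in the coverage rule
    min_individual_fraction: float = 0.85  # strict ">"
    max_mismatch: int = 3
    min_reads_for_genotype: int = 10
    min_allele_depth: int = 2             # verified alleles need depth > this
    min_het_haploids_for_duplicate: int = 2
    low_complexity_threshold: float = 1.0  # DUST triplet score on the 74-mer
    assumed_error_rate: float = 0.01      # for the allele-verification test
    allele_alpha: float = 0.01

    def __post_init__(self):
        if min(self.min_depth_per_locus, self.min_reads_for_genotype,
               self.min_het_haploids_for_duplicate) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_individual_fraction <= 1:
            raise ValueError("min_individual_fraction must be in (0, 1]")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class ClusterResult:
    clusters: pd.DataFrame      # cluster_id, consensus, n_alleles, total_depth
    assignments: pd.DataFrame   # allele, cluster_id ("" if ambiguous), ambiguous
    depth: pd.DataFrame         # clusters x individuals total depth


def dust_score(seq: str) -> float:
    """DUST-style low-complexity score: triplet-collision statistic.

    score = sum_t c_t (c_t - 1) / 2 / (k - 1) over the k = L - 2 overlapping
    triplets.  Uniform-random 74-mers score ~0.56 on average (99th percentile
    ~0.89); perfect dinucleotide repeats score ~18 and mononucleotide runs 36.
    """
    codes = encode(seq)
    if len(codes) < 3:
        raise ValueError("sequence too short for a triplet score")
    trip = codes[:-2].astype(np.int32) * 16 + codes[1:-1] * 4 + codes[2:]
    c = np.bincount(trip, minlength=64)
    k = len(trip)
    return float((c * (c - 1) / 2).sum() / (k - 1))


def cluster_reads(pileups: pd.DataFrame,
                  params: ScreeningParams = ScreeningParams()) -> ClusterResult:
    """Cluster pooled read sequences into candidate loci.

    Distinct sequences are visited in order of decreasing pooled depth
    (ties broken lexicographically).  A sequence joins the single existing
    cluster whose consensus is within ``max_mismatch``; with no such cluster
    it seeds a new one; equidistant membership in two or more clusters flags
    it ambiguous and it is left unassigned.  Consensus sequences are the
    depth-weighted majority base per position, ties broken in ACGT order.
    """
    if pileups.empty:
        empty = pd.DataFrame(columns=["cluster_id", "consensus", "n_alleles",
                                      "total_depth"])
        return ClusterResult(empty,
                             pd.DataFrame(columns=["allele", "cluster_id",
                                                   "ambiguous"]),
                             pd.DataFrame())
    by_seq = (pileups.groupby("allele", sort=False)["depth"].sum()
              .reset_index())
    by_seq = by_seq.sort_values(["depth", "allele"],
                                ascending=[False, True],
                                kind="stable").reset_index(drop=True)
    seqs = by_seq["allele"].tolist()
    depths = by_seq["depth"].to_numpy()
    codes = encode_many(seqs)
    length = codes.shape[1]

    consensus_codes = np.empty((0, length), dtype=np.uint8)
    members: list[list[int]] = []
    assignment = np.full(len(seqs), -1, dtype=np.int64)
    ambiguous = np.zeros(len(seqs), dtype=bool)

    for i in range(len(seqs)):
        if len(members):
            dists = (consensus_codes != codes[i]).sum(axis=1)
            hits = np.flatnonzero(dists <= params.max_mismatch)
        else:
            hits = np.empty(0, dtype=int)
        if len(hits) == 1:
            assignment[i] = hits[0]
            members[hits[0]].append(i)
        elif len(hits) == 0:
            members.append([i])
            assignment[i] = len(members) - 1
            consensus_codes = np.vstack([consensus_codes, codes[i]])
        else:
            ambiguous[i] = True

    # depth-weighted majority consensus per cluster
    final_consensus = []
    for mem in members:
        counts = np.zeros((length, 4), dtype=np.float64)
        for i in mem:
            counts[np.arange(length), codes[i]] += depths[i]
        # argmax takes the first (lexicographically smallest base) on ties
        final_consensus.append("".join("ACGT"[b]
                                       for b in counts.argmax(axis=1)))

    cluster_ids = [f"L{k + 1:05d}" for k in range(len(members))]
    clusters = pd.DataFrame({
        "cluster_id": cluster_ids,
        "consensus": final_consensus,
        "n_alleles": [len(m) for m in members],
        "total_depth": [int(depths[m].sum()) for m in members],
    })
    assignments = pd.DataFrame({
        "allele": seqs,
        "cluster_id": [cluster_ids[a] if a >= 0 else "" for a in assignment],
        "ambiguous": ambiguous,
    })
    assigned = pileups.merge(assignments[["allele", "cluster_id"]],
                             on="allele", how="left")
    assigned = assigned[assigned["cluster_id"] != ""]
    depth = (assigned.pivot_table(index="cluster_id",
                                  columns="individual_id", values="depth",
                                  aggfunc="sum", fill_value=0)
             .reindex(cluster_ids, fill_value=0))
    return ClusterResult(clusters, assignments, depth)


def coverage_filter(clusters: pd.DataFrame, depth: pd.DataFrame,
                    n_individuals: int,
                    params: ScreeningParams = ScreeningParams()
                    ) -> pd.DataFrame:
    """Retain loci sequenced deeply enough in enough individuals.

    A locus is kept when its per-individual depth exceeds
    ``min_depth_per_locus`` in more than ``min_individual_fraction`` x
    ``n_individuals`` individuals (both inequalities strict).
    Returns the temporary reference database with status columns.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    needed = params.min_individual_fraction * n_individuals
    db = clusters.rename(columns={"cluster_id": "locus_id",
                                  "consensus": "sequence"}).copy()
    if db.empty:
        db["status"] = pd.Series(dtype=str)
        db["reason"] = pd.Series(dtype=str)
        db["n_covered"] = pd.Series(dtype=int)
        return db[DB_COLUMNS + ["n_covered"]]
    counts = ((depth > params.min_depth_per_locus).sum(axis=1)
              .reindex(db["locus_id"], fill_value=0).to_numpy())
    keep = counts > needed
    db["status"] = np.where(keep, "unique", "excluded_coverage")
    db["reason"] = np.where(
        keep, "",
        [f"covered in {c} of {n_individuals} individuals" for c in counts])
    db["n_covered"] = counts
    return db[DB_COLUMNS + ["n_covered"]]


def _retained(db: pd.DataFrame) -> pd.Series:
    return db["status"].isin(("unique", "duplicated"))


def self_align_screen(db: pd.DataFrame,
                      params: ScreeningParams = ScreeningParams()
                      ) -> pd.DataFrame:
    """Exclude loci that align to several database loci (repeats).

    Every retained locus is compared against all retained loci; a locus
    matching more than one (itself included) within ``max_mismatch`` is a
    likely repeat, and all members of the matching set are excluded.  The
    relation is symmetric by construction.
    """
    db = db.copy()
    mask = _retained(db)
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) == 0:
        return db
    seqs = db.loc[mask, "sequence"].tolist()
    dists = hamming_matrix(seqs)
    n_hits = (dists <= params.max_mismatch).sum(axis=1)  # includes self
    bad = idx[n_hits > 1]
    db.loc[db.index[bad], "status"] = "excluded_multimap"
    db.loc[db.index[bad], "reason"] = [
        f"matches {h} database loci within {params.max_mismatch} mismatches"
        for h in n_hits[n_hits > 1]]
    return db


def low_complexity_screen(db: pd.DataFrame,
                          params: ScreeningParams = ScreeningParams()
                          ) -> pd.DataFrame:
    """Exclude low-complexity loci (repeat motifs, base runs).

    Uses :func:`dust_score`; loci scoring above
    ``low_complexity_threshold`` are excluded.  The default threshold (1.0)
    was calibrated on uniform-random 74-mers so that fewer than 1% of
    random sequences are masked.
    """
    db = db.copy()
    mask = _retained(db)
    for i in db.index[mask]:
        score = dust_score(db.at[i, "sequence"])
        if score > params.low_complexity_threshold:
            db.at[i, "status"] = "excluded_lowcomplexity"
            db.at[i, "reason"] = f"dust score {score:.2f}"
    return db


def identify_duplicates(db: pd.DataFrame, haploid_calls: dict,
                        params: ScreeningParams = ScreeningParams(),
                        cross_types: dict | None = None) -> pd.DataFrame:
    """Mark duplicated loci from heterozygous haploid genotype calls.

    ``haploid_calls`` maps family id to a genotype table (individuals x
    database loci, entries "a", "a/b" or "-").  A locus is duplicated when
    at least ``min_het_haploids_for_duplicate`` haploid individuals are
    heterozygous within a single family; evidence is deliberately not
    weighted by family size.  Calls from non-haploid crosses are rejected.
    """
    if cross_types is not None:
        for fam, ctype in cross_types.items():
            if ctype != "haploid":
                raise ValueError(
                    f"family {fam}: duplicate identification requires "
                    f"haploid calls, got {ctype!r}")
    db = db.copy()
    retained_ids = set(db.loc[_retained(db), "locus_id"])
    het_support: dict[str, int] = {}
    for fam, calls in haploid_calls.items():
        for locus_id in calls.columns:
            if locus_id not in retained_ids:
                continue
            col = calls[locus_id].astype(str)
            is_het = col.str.contains("/") & (
                col.str.split("/").str[0] != col.str.split("/").str[1])
            n_het = int(is_het.sum())
            het_support[locus_id] = max(het_support.get(locus_id, 0), n_het)
    for i in db.index[_retained(db)]:
        lid = db.at[i, "locus_id"]
        n_het = het_support.get(lid, 0)
        if n_het >= params.min_het_haploids_for_duplicate:
            db.at[i, "status"] = "duplicated"
            db.at[i, "reason"] = f"{n_het} heterozygous haploids"
        else:
            db.at[i, "status"] = "unique"
    return db
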