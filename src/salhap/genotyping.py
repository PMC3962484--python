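"""Read-to-locus assignment and genotype calling.

Genotype calls follow the depth rules used throughout the pipeline: a locus
with fewer than 10 reads in an individual is missing for that individual,
and an individual is heterozygous only when two verified alleles each have
depth greater than two and the total depth is at least 10.  "Verified" means
the allele's depth is inconsistent with sequencing error (a one-sided
binomial test against the assumed per-read error rate).  Three or more
verified alleles indicate paralog collapse beyond the two-allele model and
the call is set missing.

Duplicated loci collapse two paralogs into one observed locus; the
composite offspring genotype classes and their expected haploid segregation
ratios depend only on the dam's genotype at each paralog
(:func:`classify_duplicate_marker`), and mappable paralogs can be recovered
from composite calls by gamete enumeration (:func:`expand_duplicate_calls`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from salhap.refdb import ScreeningParams
from salhap.sequtils import encode_many


def align_to_db(pileups: pd.DataFrame, db: pd.DataFrame,
                params: ScreeningParams = ScreeningParams()) -> pd.DataFrame:
    """Assign each pileup read sequence to a unique database locus.

    A sequence matching exactly one retained database locus within
    ``max_mismatch`` is assigned to it; sequences matching several loci are
    dropped (they cannot be relied upon), sequences matching none stay
    unassigned.  Returns the pileups of assigned reads with a ``db_locus``
    column; drop counts are attached as ``result.attrs["n_multimap"]`` and
    ``result.attrs["n_unassigned"]``.
    """
    retained = db[db["status"].isin(("unique", "duplicated"))]
    out_cols = list(pileups.columns) + ["db_locus"]
    if pileups.empty or retained.empty:
        out = pd.DataFrame(columns=out_cols)
        out.attrs.update(n_multimap=0, n_unassigned=0)
        return out
    seqs = sorted(pileups["allele"].unique())
    dists = (encode_many(retained["sequence"].tolist())[None, :, :]
             != encode_many(seqs)[:, None, :]).sum(axis=2) \
        if len(seqs) * len(retained) <= 4_000_000 else None
    if dists is None:
        from salhap.sequtils import hamming_matrix
        dists = hamming_matrix(seqs, retained["sequence"].tolist())
    hits = dists <= params.max_mismatch
    n_hits = hits.sum(axis=1)
    target = np.where(n_hits == 1, hits.argmax(axis=1), -1)
    db_ids = retained["locus_id"].to_numpy()
    mapping = {seq: (db_ids[t] if t >= 0 else None)
               for seq, t, nh in zip(seqs, target, n_hits)}
    multimap_seqs = {seq for seq, nh in zip(seqs, n_hits) if nh > 1}
    assigned = pileups.copy()
    assigned["db_locus"] = assigned["allele"].map(mapping)
    n_multi = int(assigned["allele"].isin(multimap_seqs).sum())
    dropped = assigned["db_locus"].isna()
    out = assigned[~dropped].reset_index(drop=True)
    out.attrs["n_multimap"] = n_multi
    out.attrs["n_unassigned"] = int(dropped.sum()) - n_multi
    return out


def _verified_alleles(depths: dict, total: int,
                      params: ScreeningParams) -> list:
    """Alleles with depth > min_allele_depth whose depth is inconsistent
    with sequencing error at the assumed per-read error rate."""
    verified = []
    for seq, d in depths.items():
        if d <= params.min_allele_depth:
            continue
        p_err = stats.binom.sf(d - 1, total, params.assumed_error_rate)
        if p_err < params.allele_alpha:
            verified.append(seq)
    return verified


def call_genotype(depths: dict,
                  params: ScreeningParams = ScreeningParams()) -> tuple:
    """Call one individual at one locus from {allele sequence: depth}.

    Returns (call, alleles): call is "missing", "hom" or "het"; alleles the
    supporting sequences (sorted for heterozygotes).  Total depth below
    ``min_reads_for_genotype`` is missing; more than two verified alleles is
    aberrant (possible paralog collapse) and also missing.
    """
    total = int(sum(depths.values()))
    if total < params.min_reads_for_genotype:
        return ("missing", ())
    verified = _verified_alleles(depths, total, params)
    if len(verified) >= 3:
        return ("missing", tuple(sorted(verified)))
    if len(verified) == 2:
        return ("het", tuple(sorted(verified)))
    # deterministic majority: highest depth, ties to smallest sequence
    best_depth = max(depths.values())
    best = min(s for s, d in depths.items() if d == best_depth)
    return ("hom", (best,))


def call_genotypes(assigned_pileups: pd.DataFrame,
                   params: ScreeningParams = ScreeningParams()
                   ) -> pd.DataFrame:
    """Genotype every individual at every assigned locus.

    Returns an individuals x loci table; entries are allele labels ("a",
    "a/b", or "-" for missing).  Labels are assigned per locus by sorted
    allele sequence over all alleles appearing in any call, so they are
    consistent across individuals and families genotyped from the same
    database.
    """
    if assigned_pileups.empty:
        return pd.DataFrame()
    calls: dict[str, dict[str, tuple]] = {}
    used_alleles: dict[str, set] = {}
    grouped = assigned_pileups.groupby(["db_locus", "individual_id"],
                                       sort=True)["depth"]
    depth_by = {key: grp for key, grp in grouped}
    allele_by = {key: grp for key, grp
                 in assigned_pileups.groupby(["db_locus", "individual_id"],
                                             sort=True)["allele"]}
    for key in depth_by:
        locus_id, ind = key
        depths = dict(zip(allele_by[key], depth_by[key]))
        call, alleles = call_genotype(depths, params)
        calls.setdefault(locus_id, {})[ind] = (call, alleles)
        if call in ("hom", "het"):
            used_alleles.setdefault(locus_id, set()).update(alleles)

    individuals = sorted(assigned_pileups["individual_id"].unique())
    loci = sorted(calls)
    table = pd.DataFrame("-", index=individuals, columns=loci, dtype=object)
    letters = "abcdefghij"
    for locus_id in loci:
        labels = {seq: letters[i] if i < len(letters) else f"x{i}"
                  for i, seq in enumerate(sorted(used_alleles.get(locus_id,
                                                                  set())))}
        for ind, (call, alleles) in calls[locus_id].items():
            if call == "hom":
                table.at[ind, locus_id] = labels[alleles[0]]
            elif call == "het":
                table.at[ind, locus_id] = "/".join(
                    sorted(labels[a] for a in alleles))
        table.attrs.setdefault("allele_labels", {})[locus_id] = {
            v: k for k, v in labels.items()}
    return table


# ---------------------------------------------------------------------------
# duplicated-marker segregation model


@dataclass
class DuplicateMarkerClass:
    """Segregation class of a collapsed duplicated locus in a haploid cross.

    ``class_name`` names the dam's genotype pattern at (paralog 1, paralog 2)
    after normalising so any homozygous paralog comes first.  ``expected``
    maps composite offspring genotypes (as call strings, e.g. "a" or "a/b")
    to their expected frequency; ``expansion`` maps unambiguous composite
    genotypes back to the per-paralog gametes.
    """

    class_name: str
    mappable_paralogs: tuple  # subset of (1, 2), in input paralog order
    expected: dict
    expansion: dict
    swapped: bool = False  # True if input paralogs were reordered

    @property
    def is_mappable(self) -> bool:
        return bool(self.mappable_paralogs)


def _composite(g1: str, g2: str) -> str:
    return g1 if g1 == g2 else "/".join(sorted((g1, g2)))


def classify_duplicate_marker(dam_paralog1, dam_paralog2
                              ) -> DuplicateMarkerClass:
    """Classify a duplicated locus from the dam's two paralog genotypes.

    Genotypes are 2-tuples of allele labels sharing one label space (a label
    denotes the same haplotype sequence on either paralog).  Composite
    offspring frequencies come from enumerating the four equally likely
    maternal gamete combinations.  One polymorphic paralog gives an OPP
    locus (one mappable paralog); two polymorphic paralogs with distinct
    allele pairs give a BPP locus (both mappable); identical heterozygous
    genotypes (ab x ab) or two fixed paralogs are unmappable.
    """
    g1, g2 = tuple(dam_paralog1), tuple(dam_paralog2)
    if len(g1) != 2 or len(g2) != 2:
        raise ValueError("paralog genotypes must be 2-tuples of labels")
    swapped = False
    a1, a2 = sorted(set(g1)), sorted(set(g2))
    if len(a1) > 1 and len(a2) == 1:
        g1, g2, a1, a2 = g2, g1, a2, a1
        swapped = True

    expected: dict[str, float] = {}
    producers: dict[str, set] = {}
    for x, y in itertools.product(set(g1), set(g2)):
        comp = _composite(x, y)
        expected[comp] = expected.get(comp, 0.0) + 1.0 / (len(set(g1))
                                                          * len(set(g2)))
        producers.setdefault(comp, set()).add((x, y))
    expansion = {comp: next(iter(pairs))
                 for comp, pairs in producers.items() if len(pairs) == 1}

    if len(a1) == 1 and len(a2) == 1:
        name = "aa_aa" if a1 == a2 else "aa_bb"
        mappable: tuple = ()
    elif len(a1) == 1:
        shared = set(a1) & set(a2)
        name = "aa_ab" if shared else "aa_bc"
        mappable = (1,) if swapped else (2,)
    else:
        if set(a1) == set(a2):
            name, mappable = "ab_ab", ()
        else:
            shared = set(a1) & set(a2)
            name = "ab_ac" if shared else "ab_cd"
            mappable = (1, 2)
    if not mappable:
        expansion = {}
    return DuplicateMarkerClass(name, mappable, expected, expansion, swapped)


def expand_duplicate_calls(calls: pd.Series, cls: DuplicateMarkerClass
                           ) -> pd.DataFrame:
    """Recover per-paralog haploid pseudo-calls from composite calls.

    Returns a frame with columns "P1" and "P2" (in the caller's paralog
    order); entries are allele labels or "-" where the composite call is
    missing, unexpected, or ambiguous.  Only mappable paralogs carry
    information.
    """
    p1, p2 = [], []
    for call in calls.astype(str):
        pair = cls.expansion.get(call)
        if pair is None:
            p1.append("-")
            p2.append("-")
        else:
            x, y = pair
            if cls.swapped:
                x, y = y, x
            p1.append(x)
            p2.append(y)
    return pd.DataFrame({"P1": p1, "P2": p2}, index=calls.index)


def infer_duplicate_class(calls: pd.Series, min_count: int = 2):
    """Reconstruct the dam's paralog genotypes from composite haploid calls.

    The observed composite genotype set of a duplicated locus determines the
    segregation class (and hence the dam's genotype at each paralog) up to
    the paralog labelling, which the mapping stage resolves anyway.
    Genotypes seen in fewer than ``min_count`` offspring are ignored as
    likely errors.  Returns (dam_paralog1, dam_paralog2) or None when the
    observed set fits no two-paralog class.
    """
    col = calls.astype(str)
    col = col[(col != "-") & (col != "nan")]
    counts = col.value_counts()
    gset = sorted(counts[counts >= min_count].index)
    hets = [tuple(g.split("/")) for g in gset if "/" in g]
    homs = [g for g in gset if "/" not in g]
    if len(gset) == 1 and len(hets) == 1:
        (x, y), = hets
        return ((x, x), (y, y))                              # aa x bb
    if len(gset) == 2 and len(homs) == 1 and len(hets) == 1:
        x, (a, b) = homs[0], hets[0]
        if x in (a, b):
            return ((x, x), (x, b if x == a else a))         # aa x ab
    if len(gset) == 2 and len(hets) == 2:
        shared = set(hets[0]) & set(hets[1])
        if len(shared) == 1:
            x = shared.pop()
            y = (set(hets[0]) - {x}).pop()
            z = (set(hets[1]) - {x}).pop()
            return ((x, x), tuple(sorted((y, z))))           # aa x bc
    if len(gset) == 3 and len(homs) == 2 and len(hets) == 1:
        a, b = hets[0]
        if sorted(homs) == sorted((a, b)):
            return ((a, b), (a, b))                          # ab x ab
    if len(gset) == 4 and len(homs) == 1 and len(hets) == 3:
        x = homs[0]
        with_x = [p for p in hets if x in p]
        without = [p for p in hets if x not in p]
        if len(with_x) == 2 and len(without) == 1:
            y, z = sorted(without[0])
            partners = sorted((set(p) - {x}).pop() for p in with_x)
            if partners == [y, z]:
                return ((x, y), (x, z))                      # ab x ac
    if len(gset) == 4 and not homs and len(hets) == 4:
        alleles = sorted({a for p in hets for a in p})
        if len(alleles) == 4:
            u = alleles[0]
            partners = sorted((set(p) - {u}).pop() for p in hets if u in p)
            rest = [a for a in alleles[1:] if a not in partners]
            if len(partners) == 2 and len(rest) == 1:
                v = rest[0]
                v_partners = sorted((set(p) - {v}).pop()
                                    for p in hets if v in p)
                if v_partners == partners:
                    return ((u, v), tuple(partners))         # ab x cd
    return None


def segregation_check(observed, expected: dict, alpha: float = 0.05):
    """Goodness-of-fit of observed genotype counts to class expectations.

    ``observed`` is a mapping or Series of genotype -> count.  Returns
    (statistic, p_value, passed).  Counts in genotype classes with zero
    expectation fail outright.
    """
    obs = pd.Series(observed, dtype=float)
    obs = obs[obs > 0]
    n = obs.sum()
    if n == 0:
        raise ValueError("no scored offspring")
    impossible = [g for g in obs.index if expected.get(g, 0.0) == 0.0]
    if impossible:
        return (float("inf"), 0.0, False)
    keys = sorted(expected)
    o = np.array([obs.get(k, 0.0) for k in keys])
    e = np.array([expected[k] for k in keys]) * n
    stat, pval = stats.chisquare(o, e)
    return (float(stat), float(pval), bool(pval >= alpha))


def composite_truth(genome, truth: pd.DataFrame) -> pd.DataFrame:
    """Collapse paralog-pair columns of a haploid truth matrix into the
    composite genotypes an observer of the merged locus would see."""
    out = {}
    done = set()
    for locus in genome.loci:
        lid = locus.locus_id
        if lid in done:
            continue
        if not locus.is_duplicated:
            out[lid] = truth[lid]
            done.add(lid)
            continue
        partner = next(l for l in genome.loci
                       if l.paralog_id == locus.paralog_id
                       and l.locus_id != lid)
        if truth[lid].astype(str).str.contains("/").any():
            raise ValueError("composite_truth expects haploid truth matrices")
        merged = [
            _composite(x, y)
            for x, y in zip(truth[lid].astype(str),
                            truth[partner.locus_id].astype(str))]
        out[locus.paralog_id] = pd.Series(merged, index=truth.index)
        done.update((lid, partner.locus_id))
    return pd.DataFrame(out, index=truth.index)
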