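"""Two-point linkage analysis, grouping, ordering, merging and anchoring.

Grouping follows the classic escalation protocol: single-linkage transitive
closure over marker pairs with recombination fraction at most ``max_rf`` and
LOD at least the current threshold, starting at ``lod_start`` and raised by
``lod_increment`` until the number of groups reaches ``target_groups`` (the
karyotype's chromosome count).  Marker order within a group minimises the
total adjacent recombinant count (exhaustive for small groups, nearest
neighbour plus 2-opt otherwise); adjacent recombination fractions convert to
cM through a selectable map function (Kosambi by default).  Family maps are
merged through a precedence graph with deterministic conflict dropping, and
groups are anchored to chromosomes by majority vote over anchor markers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

MAP_FUNCTIONS = ("kosambi", "haldane", "morgan")


@dataclass(frozen=True)
class LinkageParams:
    max_rf: float = 0.25
    lod_start: float = 3.0
    lod_increment: float = 1.0
    target_groups: int = 34
    map_function: str = "kosambi"
    min_joint: int = 10  # pairs with fewer joint observations never link

    def __post_init__(self):
        if not 0 < self.max_rf <= 0.5:
            raise ValueError("max_rf must be in (0, 0.5]")
        if self.lod_start <= 0 or self.lod_increment <= 0:
            raise ValueError("LOD start and increment must be positive")
        if self.map_function not in MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")


@dataclass
class LinkageMap:
    """Ordered markers with cumulative cM positions per linkage group."""

    table: pd.DataFrame  # columns: group, marker, position [, chromosome...]
    family_id: str = "consensus"
    final_lod: Optional[float] = None
    conflicts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker", "group",
                                                      "reason"]))

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    def group_table(self, group) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.sort_values("position", kind="stable")

    @property
    def n_groups(self) -> int:
        return self.table["group"].nunique()

    @property
    def total_length(self) -> float:
        return float(self.table.groupby("group")["position"].max().sum())


# ---------------------------------------------------------------------------
# two-point analysis


@dataclass(frozen=True)
class TwoPointResult:
    rf_raw: float   # R/n under the given allele coding
    rf: float       # min-phase estimate, <= 0.5
    lod: float
    n: int
    r: int


def _lod(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """LOD = R log10(2 rf) + (n - R) log10(2 (1 - rf)), rf = R/n."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, r / np.maximum(n, 1), 0.5)
        term1 = np.where(r > 0, r * np.log10(np.maximum(2 * rf, 1e-300)), 0.0)
        term2 = np.where(n - r > 0,
                         (n - r) * np.log10(np.maximum(2 * (1 - rf), 1e-300)),
                         0.0)
    return term1 + term2


def encode_haploid_calls(genotypes: pd.DataFrame
                         ) -> tuple[np.ndarray, list]:
    """Code a haploid genotype table as a markers x individuals int8 matrix.

    Only biallelic single-allele calls are usable: entries with "/" or "-"
    are missing; markers without exactly two observed alleles are dropped.
    Alleles code to 0/1 in sorted order.  Returns (codes, marker_ids).
    """
    codes = []
    kept = []
    for marker in genotypes.columns:
        col = genotypes[marker].astype(str)
        valid = ~col.str.contains("/") & (col != "-") & (col != "nan")
        alleles = sorted(col[valid].unique())
        if len(alleles) != 2:
            continue
        row = np.full(len(col), -1, dtype=np.int8)
        row[(col == alleles[0]).to_numpy()] = 0
        row[(col == alleles[1]).to_numpy()] = 1
        codes.append(row)
        kept.append(marker)
    if not codes:
        return np.zeros((0, len(genotypes)), dtype=np.int8), []
    return np.vstack(codes), kept


def two_point_matrix(codes: np.ndarray, min_joint: int = 10) -> dict:
    """All pairwise two-point estimates from a coded haploid matrix.

    Returns dict of (m x m) arrays: ``rf`` (min-phase), ``rf_raw``, ``lod``,
    ``n`` (joint observations) and ``r`` (min-phase recombinant count).
    Pairs with fewer than ``min_joint`` joint observations get rf 0.5 and
    LOD 0 (never linked).
    """
    a = (codes == 0).astype(np.float32)
    b = (codes == 1).astype(np.float32)
    concordant = a @ a.T + b @ b.T
    discordant = a @ b.T + b @ a.T
    n = concordant + discordant
    r_raw = discordant
    r = np.minimum(discordant, concordant)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, r / np.maximum(n, 1), 0.5)
        rf_raw = np.where(n > 0, r_raw / np.maximum(n, 1), 0.5)
    lod = _lod(r, n)
    weak = n < min_joint
    rf = np.where(weak, 0.5, rf)
    lod = np.where(weak, 0.0, lod)
    return {"rf": rf, "rf_raw": rf_raw, "lod": lod,
            "n": n.astype(np.int64), "r": r.astype(np.int64)}


def two_point(calls_i, calls_j, min_joint: int = 2) -> TwoPointResult:
    """Two-point analysis of one haploid marker pair.

    ``calls_i`` / ``calls_j`` are aligned sequences of single allele labels
    ("-" missing).  The recombination fraction is estimated as R/n over
    jointly scored offspring; because haploid allele coding is arbitrary,
    the reported ``rf`` uses the phase minimising R (values above 0.5 fold
    back), while ``rf_raw`` keeps the coding as given.
    """
    s_i = pd.Series(calls_i).astype(str).reset_index(drop=True)
    s_j = pd.Series(calls_j).astype(str).reset_index(drop=True)
    joint = (~s_i.isin(("-", "nan")) & ~s_j.isin(("-", "nan"))
             & ~s_i.str.contains("/") & ~s_j.str.contains("/"))
    if int(joint.sum()) < min_joint:
        raise ValueError("fewer than the minimum jointly scored offspring")
    s_i, s_j = s_i[joint], s_j[joint]
    ai, aj = sorted(s_i.unique()), sorted(s_j.unique())
    if len(ai) > 2 or len(aj) > 2:
        raise ValueError("two-point analysis requires biallelic calls")
    ci = (s_i == ai[-1]).to_numpy().astype(int)
    cj = (s_j == aj[-1]).to_numpy().astype(int)
    n = len(ci)
    r_raw = int((ci != cj).sum())
    r = min(r_raw, n - r_raw)
    lod = float(_lod(np.array([r]), np.array([n]))[0])
    return TwoPointResult(rf_raw=r_raw / n, rf=r / n, lod=lod, n=n, r=r)


# ---------------------------------------------------------------------------
# grouping


def form_groups(marker_ids: list, rf: np.ndarray, lod: np.ndarray,
                params: LinkageParams = LinkageParams()) -> tuple[dict, float]:
    """Partition markers into linkage groups by LOD escalation.

    Single-linkage components over pairs with rf <= max_rf and LOD >= the
    current threshold; the threshold starts at ``lod_start`` and rises by
    ``lod_increment`` until at least ``target_groups`` groups form (or no
    further escalation can split anything).  Returns ({group_id: [marker]},
    final LOD threshold).  Group ids are "LG01", ... ordered by decreasing
    size then first marker id.
    """
    m = len(marker_ids)
    if m < params.target_groups:
        raise ValueError(f"only {m} markers for {params.target_groups} "
                         f"target groups")
    lod_cap = float(lod.max(initial=0.0))
    threshold = params.lod_start
    while True:
        adj = (rf <= params.max_rf) & (lod >= threshold)
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(csr_matrix(adj),
                                              directed=False)
        if n_comp >= params.target_groups or threshold > lod_cap:
            break
        threshold += params.lod_increment
    groups: dict[int, list] = {}
    for marker, lab in zip(marker_ids, labels):
        groups.setdefault(int(lab), []).append(marker)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    named = {f"LG{k + 1:02d}": sorted(ms) for k, ms in enumerate(ordered)}
    return named, float(threshold)


# ---------------------------------------------------------------------------
# ordering


def map_distance(rf: float, map_function: str = "kosambi") -> float:
    """Convert a recombination fraction to cM."""
    r = min(max(float(rf), 0.0), 0.4999)
    if map_function == "kosambi":
        return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    if map_function == "haldane":
        return -50.0 * np.log(1 - 2 * r)
    if map_function == "morgan":
        return 100.0 * r
    raise ValueError(f"unknown map function {map_function!r}")


def _order_cost(order: list, r: np.ndarray) -> float:
    return float(sum(r[order[k], order[k + 1]] for k in range(len(order) - 1)))


def _greedy_two_opt(reps: list, r: np.ndarray, rf: np.ndarray) -> list:
    # nearest-neighbour construction from the most peripheral marker
    start = int(np.argmax(rf[np.ix_(reps, reps)].sum(axis=1)))
    order = [start]
    remaining = set(range(len(reps))) - {start}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda j: (r[reps[last], reps[j]], j))
        order.append(nxt)
        remaining.discard(nxt)
    # 2-opt: reverse segments while it lowers the adjacent recombinant count
    local = [reps[i] for i in order]
    improved = True
    while improved:
        improved = False
        for i in range(len(local) - 1):
            for j in range(i + 1, len(local)):
                cand = local[:i] + local[i:j + 1][::-1] + local[j + 1:]
                if _order_cost(cand, r) < _order_cost(local, r) - 1e-12:
                    local = cand
                    improved = True
    return local


def order_markers(genotypes: pd.DataFrame, markers: list,
                  params: LinkageParams = LinkageParams()) -> pd.DataFrame:
    """Order one linkage group and assign cumulative cM positions.

    Co-segregating markers (zero recombinants over enough joint
    observations) are binned; the bin representative is the smallest marker
    id.  Bins are ordered to minimise the total adjacent recombinant count —
    exhaustively for up to 8 bins (a brute-force-optimal order), otherwise
    nearest-neighbour construction refined by 2-opt.  Positions accumulate
    adjacent map distances under ``params.map_function``; orientation is
    standardised so the first marker id is lexicographically smaller than
    the last (until anchoring fixes the true orientation).
    """
    markers = list(markers)
    if len(markers) == 1:
        return pd.DataFrame({"marker": markers, "position": [0.0],
                             "bin": markers})
    codes, kept = encode_haploid_calls(genotypes[markers])
    dropped = [m for m in markers if m not in kept]
    tp = two_point_matrix(codes, params.min_joint)
    r, n, rf = tp["r"], tp["n"], tp["rf"]

    # bin co-segregating markers
    m = len(kept)
    bin_adj = (r == 0) & (n >= params.min_joint)
    np.fill_diagonal(bin_adj, False)
    n_bins, bin_labels = connected_components(csr_matrix(bin_adj),
                                              directed=False)
    bins: dict[int, list] = {}
    for i, lab in enumerate(bin_labels):
        bins.setdefault(int(lab), []).append(i)
    reps = [min(members, key=lambda i: kept[i]) for members in bins.values()]
    reps.sort(key=lambda i: kept[i])

    if len(reps) == 1:
        order = reps
    elif len(reps) <= 8:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(len(reps))):
            if perm[0] > perm[-1]:
                continue  # orientation-symmetric
            cand = [reps[k] for k in perm]
            cost = _order_cost(cand, r)
            if cost < best_cost - 1e-12:
                best, best_cost = cand, cost
        order = best
    else:
        order = _greedy_two_opt(reps, r, rf)

    if kept[order[0]] > kept[order[-1]]:
        order = order[::-1]

    positions = [0.0]
    for k in range(len(order) - 1):
        positions.append(positions[-1]
                         + map_distance(rf[order[k], order[k + 1]],
                                        params.map_function))
    rows = []
    label_of = {i: lab for lab, members in bins.items() for i in members}
    for rep, pos in zip(order, positions):
        members = sorted(kept[i] for i in bins[label_of[rep]])
        for marker in members:
            rows.append({"marker": marker, "position": pos,
                         "bin": kept[rep]})
    out = pd.DataFrame(rows, columns=["marker", "position", "bin"])
    if dropped:
        out.attrs["dropped"] = dropped
    return out


def build_map(genotypes: pd.DataFrame,
              params: LinkageParams = LinkageParams(),
              family_id: str = "F1") -> LinkageMap:
    """Full two-point pipeline: encode, group, order, position."""
    codes, kept = encode_haploid_calls(genotypes)
    tp = two_point_matrix(codes, params.min_joint)
    groups, final_lod = form_groups(kept, tp["rf"], tp["lod"], params)
    tables = []
    for gid, markers in groups.items():
        ordered = order_markers(genotypes, markers, params)
        ordered.insert(0, "group", gid)
        tables.append(ordered)
    table = pd.concat(tables, ignore_index=True)
    return LinkageMap(table=table, family_id=family_id, final_lod=final_lod)


# ---------------------------------------------------------------------------
# consensus merging


def _orient_against(reference: dict, order: list) -> list:
    """Flip ``order`` if shared markers run mostly opposite to reference
    ranks; ties keep the given orientation."""
    shared = [m for m in order if m in reference]
    if len(shared) < 2:
        return order
    ranks = [reference[m] for m in shared]
    concord = sum(1 for x, y in itertools.combinations(ranks, 2) if x < y)
    discord = sum(1 for x, y in itertools.combinations(ranks, 2) if x > y)
    return order[::-1] if discord > concord else order


def merge_maps(maps: list, min_shared: int = 2) -> LinkageMap:
    """Merge family maps into a consensus map via a precedence graph.

    Groups across families merge when they share at least ``min_shared``
    markers (transitively).  Each family's order contributes directed
    precedence edges; order conflicts resolve to the majority direction, and
    on ties the marker supported by fewer families is dropped and reported
    (lexicographically larger id dropped on a full tie).  Consensus
    positions are family positions rescaled to the mean group length and
    averaged, made monotone along the topological order.
    """
    if len(maps) < 2:
        raise ValueError("need at least two family maps to merge")
    conflicts: list[dict] = []

    # match groups across families by shared markers
    meta = nx.Graph()
    group_markers: dict[tuple, list] = {}
    for fi, fam_map in enumerate(maps):
        for gid in fam_map.groups:
            sub = fam_map.group_table(gid)
            node = (fi, gid)
            group_markers[node] = list(sub["marker"])
            meta.add_node(node)
    nodes = list(group_markers)
    for u, v in itertools.combinations(nodes, 2):
        if u[0] == v[0]:
            continue
        if len(set(group_markers[u]) & set(group_markers[v])) >= min_shared:
            meta.add_edge(u, v)

    rows = []
    consensus_groups = sorted(
        (sorted(comp) for comp in nx.connected_components(meta)),
        key=lambda comp: min(min(group_markers[n]) for n in comp))
    for k, comp in enumerate(consensus_groups):
        gid = f"LG{k + 1:02d}"
        if len(comp) == 1:
            fi, fam_gid = comp[0]
            if len(maps) > 1:
                logger.warning("group %s of family %s has no merge partner; "
                               "kept family-specific", fam_gid,
                               maps[fi].family_id)
        # orient every family group against the accumulating consensus ranks
        fam_orders, fam_positions = [], []
        reference: dict = {}
        for node in comp:
            fi, fam_gid = node
            sub = maps[fi].group_table(fam_gid)
            order = list(sub["marker"])
            pos = dict(zip(sub["marker"], sub["position"]))
            order = _orient_against(reference, order)
            if order and pos[order[0]] > pos[order[-1]]:
                top = max(pos.values())
                pos = {m: top - p for m, p in pos.items()}
            for rank, marker in enumerate(order):
                reference.setdefault(marker, rank)
            fam_orders.append(order)
            fam_positions.append(pos)

        # rescale to the mean group length
        lengths = [max(p.values()) if p else 0.0 for p in fam_positions]
        target_len = float(np.mean([l for l in lengths if l > 0] or [0.0]))
        scaled: dict[str, list] = {}
        for order, pos, length in zip(fam_orders, fam_positions, lengths):
            scale = target_len / length if length > 0 else 1.0
            for m in order:
                scaled.setdefault(m, []).append(pos[m] * scale)

        # precedence graph with edge multiplicities
        weight: dict[tuple, int] = {}
        support: dict[str, int] = {}
        for order in fam_orders:
            for m in order:
                support[m] = support.get(m, 0) + 1
            for u, v in itertools.combinations(order, 2):
                weight[(u, v)] = weight.get((u, v), 0) + 1
        dropped: set = set()
        graph = nx.DiGraph()
        graph.add_nodes_from(scaled)
        seen = set()
        for (u, v) in sorted(weight):
            if (u, v) in seen or (v, u) in seen:
                continue
            seen.add((u, v))
            w, rev = weight[(u, v)], weight.get((v, u), 0)
            if w > rev:
                graph.add_edge(u, v)
            elif rev > w:
                graph.add_edge(v, u)
            else:
                # tied order conflict: drop the less-supported marker
                victim = max((u, v), key=lambda m: (-support[m], m))
                dropped.add(victim)
        for victim in sorted(dropped):
            conflicts.append({"marker": victim, "group": gid,
                              "reason": "tied order conflict"})
        graph.remove_nodes_from(dropped)
        while True:
            try:
                cycle = nx.find_cycle(graph)
            except nx.NetworkXNoCycle:
                break
            cyc_nodes = sorted({n for edge in cycle for n in edge[:2]})
            victim = max(cyc_nodes, key=lambda m: (-support[m], m))
            conflicts.append({"marker": victim, "group": gid,
                              "reason": "order cycle"})
            graph.remove_node(victim)

        mean_pos = {m: float(np.mean(v)) for m, v in scaled.items()
                    if m not in dropped and m in graph}
        order = list(nx.lexicographical_topological_sort(
            graph, key=lambda m: (mean_pos.get(m, 0.0), m)))
        # monotone consensus positions starting at zero
        positions, cur = [], -np.inf
        for m in order:
            cur = max(cur, mean_pos.get(m, 0.0))
            positions.append(cur)
        if positions:
            base = positions[0]
            positions = [p - base for p in positions]
        for m, p in zip(order, positions):
            rows.append({"group": gid, "marker": m, "position": p})

    table = pd.DataFrame(rows, columns=["group", "marker", "position"])
    return LinkageMap(table=table, family_id="consensus",
                      conflicts=pd.DataFrame(
                          conflicts, columns=["marker", "group", "reason"]))


# ---------------------------------------------------------------------------
# anchoring


def anchor_groups(lmap: LinkageMap, anchors: pd.DataFrame) -> LinkageMap:
    """Label groups with chromosomes by majority anchor vote and orient
    them p-arm first.

    ``anchors`` needs columns ``marker`` and ``chromosome``; an optional
    ``position`` column (the anchors' previously established cM positions,
    oriented p-arm first) orients groups by rank concordance, and an
    optional ``arm`` column ("p"/"q") is the fallback orientation rule.
    Groups whose anchors disagree get the majority chromosome and a
    conflict record; anchorless groups stay unlabelled.
    """
    if not {"marker", "chromosome"}.issubset(anchors.columns):
        raise ValueError("anchor table needs marker and chromosome columns")
    anchor_chrom = dict(zip(anchors["marker"], anchors["chromosome"]))
    anchor_arm = (dict(zip(anchors["marker"], anchors["arm"]))
                  if "arm" in anchors.columns else {})
    anchor_pos = (dict(zip(anchors["marker"], anchors["position"]))
                  if "position" in anchors.columns else {})
    table = lmap.table.copy()
    table["chromosome"] = ""
    conflicts = [dict(c) for _, c in lmap.conflicts.iterrows()]
    for gid in lmap.groups:
        mask = table["group"] == gid
        sub = table[mask].sort_values("position", kind="stable")
        votes = pd.Series([anchor_chrom[m] for m in sub["marker"]
                           if m in anchor_chrom])
        if votes.empty:
            continue
        counts = votes.value_counts()
        winner = sorted(counts[counts == counts.max()].index)[0]
        if len(counts) > 1:
            losers = {c: int(n) for c, n in counts.items() if c != winner}
            conflicts.append({"marker": "", "group": gid,
                              "reason": f"anchor conflict: {winner} vs "
                                        f"{losers}"})
        table.loc[mask, "chromosome"] = winner
        # orient p-arm first: by concordance with known anchor positions
        # when available, else by mean position of p- vs q-arm anchors
        flip = False
        known = [(p, anchor_pos[m]) for m, p in zip(sub["marker"],
                                                    sub["position"])
                 if anchor_chrom.get(m) == winner and m in anchor_pos]
        if len(known) >= 2:
            concord = sum(1 for (x1, y1), (x2, y2)
                          in itertools.combinations(known, 2)
                          if (x1 - x2) * (y1 - y2) > 0)
            discord = sum(1 for (x1, y1), (x2, y2)
                          in itertools.combinations(known, 2)
                          if (x1 - x2) * (y1 - y2) < 0)
            flip = discord > concord
        else:
            p_pos = [p for m, p in zip(sub["marker"], sub["position"])
                     if anchor_chrom.get(m) == winner
                     and anchor_arm.get(m) == "p"]
            q_pos = [p for m, p in zip(sub["marker"], sub["position"])
                     if anchor_chrom.get(m) == winner
                     and anchor_arm.get(m) == "q"]
            flip = bool(p_pos and q_pos
                        and np.mean(p_pos) > np.mean(q_pos))
        if flip:
            top = sub["position"].max()
            table.loc[mask, "position"] = top - table.loc[mask, "position"]
    table = (table.sort_values(["group", "position", "marker"], kind="stable")
             .reset_index(drop=True))
    return LinkageMap(table=table, family_id=lmap.family_id,
                      final_lod=lmap.final_lod,
                      conflicts=pd.DataFrame(
                          conflicts, columns=["marker", "group", "reason"]))
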