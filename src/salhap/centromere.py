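"""Half-tetrad analysis: centromere mapping and crossover statistics.

In gynogenetic diploids (second polar body retained) a locus is heterozygous
only if an exchange separated it from its centromere during the maternal
meiosis, so the fraction of heterozygous offspring y rises from 0 at the
centromere toward a telomeric plateau: 1 under complete crossover
interference, 2/3 without interference.  The centromere of each linkage
group is the region where y stays near zero; the maximum proportion of
heterozygotes (MPH) per arm summarises the interference regime, and under
complete interference y/2 is the marker-centromere recombination fraction
(distance y/2 x 100 cM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from salhap.linkage import LinkageMap

PROFILE_COLUMNS = ["group", "marker", "position", "y", "n"]


def _is_het(entry: str) -> bool:
    if "/" not in entry:
        return False
    a, b = entry.split("/", 1)
    return a != b


def het_profile(genotypes: pd.DataFrame, lmap: LinkageMap,
                exclude: Optional[set] = None) -> pd.DataFrame:
    """Per-locus heterozygote fraction of gynogenetic-diploid offspring.

    Markers must be placed on the map and scored in at least one offspring;
    ``exclude`` removes loci (e.g. duplicated ones, which cannot be reliably
    genotyped in gynogenetic diploids).  Returns a table (group, marker,
    position, y, n) sorted by group and position.
    """
    exclude = exclude or set()
    rows = []
    for _, rec in lmap.table.iterrows():
        marker = rec["marker"]
        if marker in exclude or marker not in genotypes.columns:
            continue
        col = genotypes[marker].astype(str)
        scored = col[(col != "-") & (col != "nan")]
        if scored.empty:
            continue
        n = len(scored)
        y = float(np.mean([_is_het(g) for g in scored]))
        rows.append({"group": rec["group"], "marker": marker,
                     "position": rec["position"], "y": y, "n": n})
    prof = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return prof.sort_values(["group", "position"],
                            kind="stable").reset_index(drop=True)


@dataclass
class CentromereCall:
    group: str
    interval: Optional[tuple]      # (cM, cM) span of the near-zero region
    chromosome_type: str           # metacentric | acrocentric | unresolved
    y_floor: float
    distances: pd.Series           # per-marker gene-centromere distance, cM

    @property
    def midpoint(self) -> Optional[float]:
        if self.interval is None:
            return None
        return 0.5 * (self.interval[0] + self.interval[1])


def locate_centromere(profile: pd.DataFrame,
                      y_floor: Optional[float] = None) -> CentromereCall:
    """Locate the centromere of one linkage group from its y profile.

    The centromere interval is the longest run of consecutive mapped loci
    with y <= y_floor (default 2/n, tolerating one miscalled offspring).
    The group is metacentric if loci with y above the floor flank the
    interval on both sides, acrocentric if on one side only; with no
    near-zero locus the centromere is unresolved.  Per-marker
    gene-centromere distances assume complete interference (y/2 x 100 cM).
    """
    if len(profile) < 3:
        raise ValueError("need at least three profiled loci in the group")
    prof = profile.sort_values("position", kind="stable").reset_index(
        drop=True)
    group = prof["group"].iloc[0]
    if y_floor is None:
        y_floor = 2.0 / float(prof["n"].max())
    distances = pd.Series(50.0 * prof["y"].to_numpy(),
                          index=prof["marker"], name="centromere_dist_cM")

    low = (prof["y"] <= y_floor).to_numpy()
    runs = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(low) - 1))
    if not runs:
        return CentromereCall(group, None, "unresolved", y_floor, distances)
    best = max(runs, key=lambda se: (se[1] - se[0], -se[0]))
    lo, hi = best
    if lo == 0 and hi == len(low) - 1:
        return CentromereCall(group, None, "unresolved", y_floor, distances)
    interval = (float(prof["position"].iloc[lo]),
                float(prof["position"].iloc[hi]))
    flank_left = lo > 0
    flank_right = hi < len(low) - 1
    ctype = "metacentric" if (flank_left and flank_right) else "acrocentric"
    return CentromereCall(group, interval, ctype, y_floor, distances)


def compute_mph(profile: pd.DataFrame, call: CentromereCall) -> dict:
    """Maximum proportion of heterozygotes per arm of one group.

    Loci are assigned to arms by their side of the centromere-interval
    midpoint (the map is oriented p-arm first).  Arms without loci report
    NaN (e.g. when all distal loci were duplicated and unscorable).
    """
    if call.interval is None:
        raise ValueError("centromere not located for this group")
    mid = call.midpoint
    prof = profile.sort_values("position", kind="stable")
    out = {}
    for arm, mask in (("p", prof["position"] < mid),
                      ("q", prof["position"] > mid)):
        ys = prof.loc[mask, "y"]
        out[arm] = float(ys.max()) if len(ys) else float("nan")
    return out


def _phase_codes(genotypes: pd.DataFrame, markers: list) -> np.ndarray:
    """Code haploid calls 0/1 per marker and orient codings along the map
    so that adjacent markers agree for most offspring (greedy maternal
    phasing; a global flip does not change switch counts)."""
    n_ind = len(genotypes)
    coded = np.full((len(markers), n_ind), -1, dtype=np.int8)
    for k, marker in enumerate(markers):
        col = genotypes[marker].astype(str)
        valid = ~col.str.contains("/") & (col != "-") & (col != "nan")
        alleles = sorted(col[valid].unique())
        if len(alleles) != 2:
            continue
        row = np.full(n_ind, -1, dtype=np.int8)
        row[(col == alleles[0]).to_numpy()] = 0
        row[(col == alleles[1]).to_numpy()] = 1
        coded[k] = row
    prev = None
    for k in range(len(markers)):
        if (coded[k] >= 0).sum() == 0:
            continue
        if prev is not None:
            joint = (coded[k] >= 0) & (coded[prev] >= 0)
            disagree = int((coded[k][joint] != coded[prev][joint]).sum())
            agree = int(joint.sum()) - disagree
            if disagree > agree:
                coded[k][coded[k] >= 0] ^= 1
        prev = k
    return coded


def count_crossovers(genotypes: pd.DataFrame, lmap: LinkageMap,
                     centromere_midpoints: dict,
                     phase: Optional[dict] = None) -> pd.DataFrame:
    """Count crossovers per progeny per chromosome arm in a haploid family.

    The crossover count is the number of maternal-phase switches along the
    ordered markers of the arm.  ``centromere_midpoints`` maps group id to
    the centromere position on that group's map (markers split into arms on
    either side).  Phase is inferred by greedy adjacent-marker phasing
    unless ``phase`` supplies marker -> hap0 allele labels.  Arms with
    fewer than two scored markers are skipped.  Returns a long table
    (individual, group, arm, n_markers, crossovers); the double-crossover
    frequency is ``attrs["double_crossover_freq"]``.
    """
    rows = []
    for gid in lmap.groups:
        if gid not in centromere_midpoints:
            continue
        mid = centromere_midpoints[gid]
        sub = lmap.group_table(gid)
        markers = [m for m in sub["marker"] if m in genotypes.columns]
        positions = dict(zip(sub["marker"], sub["position"]))
        for arm in ("p", "q"):
            arm_markers = [m for m in markers
                           if (positions[m] < mid) == (arm == "p")]
            if len(arm_markers) < 2:
                continue
            if phase is not None:
                coded = np.full((len(arm_markers), len(genotypes)), -1,
                                dtype=np.int8)
                for k, marker in enumerate(arm_markers):
                    col = genotypes[marker].astype(str)
                    hap0 = phase.get(marker)
                    valid = (~col.str.contains("/") & (col != "-")
                             & (col != "nan"))
                    coded[k][valid.to_numpy() & (col == hap0).to_numpy()] = 0
                    coded[k][valid.to_numpy() & (col != hap0).to_numpy()] = 1
            else:
                coded = _phase_codes(genotypes, arm_markers)
            for i, ind in enumerate(genotypes.index):
                seq = coded[:, i]
                seq = seq[seq >= 0]
                if len(seq) < 2:
                    continue
                switches = int((seq[1:] != seq[:-1]).sum())
                rows.append({"individual": ind, "group": gid, "arm": arm,
                             "n_markers": len(seq),
                             "crossovers": switches})
    table = pd.DataFrame(rows, columns=["individual", "group", "arm",
                                        "n_markers", "crossovers"])
    if len(table):
        table.attrs["double_crossover_freq"] = float(
            (table["crossovers"] >= 2).mean())
    else:
        table.attrs["double_crossover_freq"] = float("nan")
    return table
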