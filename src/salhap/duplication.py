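"""Homeologous-arm divergence: duplicated-locus distribution and homeologies.

After whole genome duplication, arms still engaging in occasional
homeologous pairing retain recently diverged duplicated loci, typically
concentrated distal to the centromere.  This module computes the
kernel-smoothed proportion of duplicated markers along each group, infers
homeologous arm pairs from duplicated loci with both paralogs polymorphic
(BPP — the only class where both paralogs can be mapped), summarises
duplicate content per arm, and aligns two locus databases to build
cross-species homology tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from salhap.sequtils import hamming_matrix


def duplicate_density(map_table: pd.DataFrame, duplicated,
                      bandwidth: float = 2.0,
                      grid_step: float = 0.5) -> pd.DataFrame:
    """Kernel-smoothed proportion of duplicated markers along each group.

    Marker positions are irregular, so a Gaussian kernel (bandwidth in cM,
    default 2) estimates the local fraction of duplicated loci on a regular
    grid covering [0, group length].  ``duplicated`` maps marker -> bool.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    dup = pd.Series(duplicated)
    rows = []
    for gid, sub in map_table.groupby("group", sort=True):
        pos = sub["position"].to_numpy(dtype=float)
        flags = np.array([bool(dup.get(m, False)) for m in sub["marker"]],
                         dtype=float)
        grid = np.arange(0.0, pos.max() + grid_step / 2, grid_step)
        w = np.exp(-0.5 * ((grid[:, None] - pos[None, :]) / bandwidth) ** 2)
        dens = (w @ flags) / np.maximum(w.sum(axis=1), 1e-300)
        for g, d in zip(grid, dens):
            rows.append({"group": gid, "position": float(g),
                         "proportion": float(d)})
    return pd.DataFrame(rows, columns=["group", "position", "proportion"])


def infer_homeologies(marker_arms, bpp_pairs: pd.DataFrame,
                      min_support: int = 1) -> pd.DataFrame:
    """Tally homeologous arm pairs from mapped BPP paralog pairs.

    ``marker_arms`` maps each mapped pseudo-marker to its arm label;
    ``bpp_pairs`` has columns (pair_id, marker_1, marker_2) naming the two
    mapped paralogs of each BPP locus.  Pairs whose paralogs land on the
    same arm are anomalous and reported separately
    (``attrs["anomalous"]``); arm pairs are unordered and calls are sorted
    by decreasing support.
    """
    arms = pd.Series(marker_arms)
    tally: dict[tuple, list] = {}
    anomalous = []
    for _, rec in bpp_pairs.iterrows():
        m1, m2 = rec["marker_1"], rec["marker_2"]
        if m1 not in arms.index or m2 not in arms.index:
            continue
        a1, a2 = arms[m1], arms[m2]
        if not a1 or not a2 or pd.isna(a1) or pd.isna(a2):
            continue
        if a1 == a2:
            anomalous.append(rec.get("pair_id", m1))
            continue
        key = tuple(sorted((str(a1), str(a2))))
        tally.setdefault(key, []).append(rec.get("pair_id", m1))
    rows = [{"arm_a": k[0], "arm_b": k[1], "support": len(v),
             "pairs": ";".join(map(str, sorted(v)))}
            for k, v in tally.items() if len(v) >= min_support]
    out = pd.DataFrame(rows, columns=["arm_a", "arm_b", "support", "pairs"])
    out = out.sort_values(["support", "arm_a", "arm_b"],
                          ascending=[False, True, True],
                          kind="stable").reset_index(drop=True)
    out.attrs["anomalous"] = sorted(map(str, anomalous))
    return out


def arm_duplicate_summary(marker_arms, marker_classes,
                          top_k: int = 16) -> pd.DataFrame:
    """Per-arm counts of unique / OPP / BPP markers and duplicate fractions.

    ``marker_classes`` maps marker -> "unique" | "OPP" | "BPP"; markers with
    no arm label are summarised under "unassigned".  The fraction of all
    duplicated markers captured by the ``top_k`` arms with most duplicates
    is attached as ``attrs["top_arm_fraction"]``.
    """
    arms = pd.Series(marker_arms)
    classes = pd.Series(marker_classes)
    rows: dict[str, dict] = {}
    for marker, cls in classes.items():
        arm = str(arms.get(marker, "") or "unassigned")
        rec = rows.setdefault(arm, {"arm": arm, "n_unique": 0, "n_OPP": 0,
                                    "n_BPP": 0})
        if cls == "OPP":
            rec["n_OPP"] += 1
        elif cls == "BPP":
            rec["n_BPP"] += 1
        else:
            rec["n_unique"] += 1
    out = pd.DataFrame(sorted(rows.values(), key=lambda r: r["arm"]))
    if out.empty:
        out = pd.DataFrame(columns=["arm", "n_unique", "n_OPP", "n_BPP",
                                    "n_duplicated", "dup_fraction"])
        out.attrs["top_arm_fraction"] = float("nan")
        return out
    out["n_duplicated"] = out["n_OPP"] + out["n_BPP"]
    total = out["n_unique"] + out["n_duplicated"]
    out["dup_fraction"] = np.where(total > 0, out["n_duplicated"] / total, 0.0)
    all_dup = int(out["n_duplicated"].sum())
    top = out.sort_values(["n_duplicated", "arm"],
                          ascending=[False, True]).head(top_k)
    out.attrs["top_arm_fraction"] = (
        float(top["n_duplicated"].sum() / all_dup) if all_dup else float("nan"))
    return out.reset_index(drop=True)


def crossdb_align(db_a: pd.DataFrame, db_b: pd.DataFrame,
                  max_mismatch: int = 3) -> pd.DataFrame:
    """Reciprocally unique matches between two locus databases.

    Databases are frames with ``locus_id`` and ``sequence`` columns (equal
    locus length required).  A pair is retained only when each locus matches
    exactly one locus of the other database within ``max_mismatch`` — the
    strict reading of "aligned uniquely".  Returns (locus_a, locus_b,
    mismatches).
    """
    seq_a = db_a["sequence"].tolist()
    seq_b = db_b["sequence"].tolist()
    if not seq_a or not seq_b:
        return pd.DataFrame(columns=["locus_a", "locus_b", "mismatches"])
    if len(seq_a[0]) != len(seq_b[0]):
        raise ValueError("databases have different locus lengths")
    dists = hamming_matrix(seq_a, seq_b)
    hits = dists <= max_mismatch
    unique_a = hits.sum(axis=1) == 1
    unique_b = hits.sum(axis=0) == 1
    rows = []
    ids_a = db_a["locus_id"].to_numpy()
    ids_b = db_b["locus_id"].to_numpy()
    for i in np.flatnonzero(unique_a):
        j = int(hits[i].argmax())
        if unique_b[j]:
            rows.append({"locus_a": ids_a[i], "locus_b": ids_b[j],
                         "mismatches": int(dists[i, j])})
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "mismatches"])
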