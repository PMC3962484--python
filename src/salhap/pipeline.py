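"""End-to-end orchestration: simulate -> refdb -> genotype -> map ->
centromere -> duplication, driven by one YAML config and one seed.

Every stage writes plain-text outputs under the run directory and records
them in a manifest before the next stage starts; identical config + seed
reproduce byte-identical tables.  The global seed fans out to fixed
per-stage child seeds so stages are independently rerunnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from salhap import io
from salhap.centromere import (compute_mph, count_crossovers, het_profile,
                               locate_centromere)
from salhap.duplication import (arm_duplicate_summary, duplicate_density,
                                infer_homeologies, crossdb_align)
from salhap.genome import (ChromosomeDef, GenomeConfig, HomeologPair,
                           LocusLayout, LocusSpec, build_genome,
                           standard_karyotype)
from salhap.genotyping import (align_to_db, call_genotypes,
                               classify_duplicate_marker,
                               expand_duplicate_calls, infer_duplicate_class)
from salhap.linkage import LinkageParams, anchor_groups, build_map, merge_maps
from salhap.meiosis import CrossSpec, simulate_cross, simulate_panel
from salhap.reads import simulate_reads
from salhap.refdb import (ScreeningParams, cluster_reads, coverage_filter,
                          identify_duplicates, low_complexity_screen,
                          self_align_screen)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "refdb", "genotype", "map", "centromere", "duplication")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_digest(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across reruns)."""
    ss = np.random.SeedSequence([int(base_seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def genome_from_config(cfg: dict, seed: int):
    g = cfg.get("genome")
    if g is None:
        raise ValueError("config is missing the genome section")
    if "chromosomes" in g:
        chroms = [ChromosomeDef(**c) for c in g["chromosomes"]]
    else:
        chroms = standard_karyotype(**g.get("karyotype", {}))
    homeologs = []
    for h in g.get("homeologs", []):
        h = dict(h)
        if "classes" in h:
            h["classes"] = tuple(h["classes"])
        homeologs.append(HomeologPair(**h))
    loci = None
    layout = None
    if "loci" in g:
        loci = [LocusSpec(**l) for l in g["loci"]]
    else:
        layout = LocusLayout(**g.get("layout", {}))
    config = GenomeConfig(chromosomes=chroms, homeolog_pairs=homeologs,
                          loci=loci, layout=layout, rng_seed=seed)
    return build_genome(config)


def crosses_from_config(cfg: dict) -> list:
    crosses = []
    for c in cfg.get("crosses", []):
        crosses.append(CrossSpec(
            cross_type=c["type"], n_offspring=int(c["n_offspring"]),
            family_id=str(c.get("family_id", f"F{len(crosses) + 1}")),
            interference=c.get("interference", "complete"),
            nu=c.get("nu")))
    return crosses


def _params_from(cfg: dict, key: str, cls):
    return cls(**cfg.get(key, {}))


class PipelineRun:
    """Mutable run state shared across stages."""

    def __init__(self, cfg: dict, out_dir, seed: int):
        self.cfg = cfg
        self.out = Path(out_dir)
        self.seed = int(seed)
        self.manifest = {"config_digest": config_digest(cfg),
                         "seed": self.seed, "tool": "salhap",
                         "stages": []}

    def record(self, stage: str, outputs: list):
        self.manifest["stages"].append(
            {"stage": stage, "outputs": [str(p) for p in outputs],
             "status": "ok"})
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    A stage failure propagates with the stage name attached.
    """
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(cfg, out, seed)
    state: dict = {}
    for stage in STAGES:
        try:
            outputs = _STAGE_FUNCS[stage](run, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") \
                from exc
        run.record(stage, outputs)
    return run.manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(run: PipelineRun, state: dict) -> list:
    cfg, out = run.cfg, run.out / "sim"
    out.mkdir(parents=True, exist_ok=True)
    genome = genome_from_config(cfg, stage_seed(run.seed, "simulate"))
    crosses = crosses_from_config(cfg)
    if not crosses:
        raise ValueError("config defines no crosses")
    rng = np.random.default_rng(stage_seed(run.seed, "simulate") + 1)
    reads_cfg = dict(mean_depth=40.0, dispersion=5.0, error_rate=0.005)
    reads_cfg.update(cfg.get("reads", {}))

    outputs = []
    io.write_fasta(genome.fasta_records(), out / "loci.fasta")
    io.write_tsv(genome.loci_df(), out / "truth_loci.tsv")
    io.write_tsv(genome.centromere_table(), out / "truth_centromeres.tsv")
    io.write_tsv(genome.homeolog_table(), out / "truth_homeologs.tsv")
    outputs += [out / "loci.fasta", out / "truth_loci.tsv",
                out / "truth_centromeres.tsv", out / "truth_homeologs.tsv"]

    pileups = {}
    panel_n = int(cfg.get("panel", {}).get("n_individuals", 0))
    if panel_n:
        panel = simulate_panel(genome, panel_n, rng)
        pileups["panel"] = simulate_reads(
            genome, panel, reads_cfg["mean_depth"], reads_cfg["dispersion"],
            reads_cfg["error_rate"], rng)
        io.write_tsv(pileups["panel"], out / "pileups_panel.tsv")
        outputs.append(out / "pileups_panel.tsv")

    truth = {}
    for spec in crosses:
        truth[spec.family_id] = simulate_cross(genome, spec, rng)
        pileups[spec.family_id] = simulate_reads(
            genome, truth[spec.family_id], reads_cfg["mean_depth"],
            reads_cfg["dispersion"], reads_cfg["error_rate"], rng)
        io.write_genotypes(truth[spec.family_id],
                           out / f"truth_genotypes_{spec.family_id}.tsv")
        io.write_tsv(pileups[spec.family_id],
                     out / f"pileups_{spec.family_id}.tsv")
        outputs += [out / f"truth_genotypes_{spec.family_id}.tsv",
                    out / f"pileups_{spec.family_id}.tsv"]

    state.update(genome=genome, crosses=crosses, truth=truth,
                 pileups=pileups, panel_n=panel_n)
    return outputs


def _stage_refdb(run: PipelineRun, state: dict) -> list:
    cfg, out = run.cfg, run.out / "refdb"
    out.mkdir(parents=True, exist_ok=True)
    params = _params_from(cfg, "screening", ScreeningParams)
    pileups = state["pileups"]
    panel_n = state["panel_n"]
    if not panel_n:
        raise ValueError("reference database requires a panel section")
    clustered = cluster_reads(pileups["panel"], params)
    db = coverage_filter(clustered.clusters, clustered.depth, panel_n, params)
    db = self_align_screen(db, params)
    db = low_complexity_screen(db, params)

    # genotype every cross against the screened database
    calls = {}
    for spec in state["crosses"]:
        assigned = align_to_db(pileups[spec.family_id], db, params)
        calls[spec.family_id] = call_genotypes(assigned, params)
    haploid_calls = {s.family_id: calls[s.family_id]
                     for s in state["crosses"] if s.cross_type == "haploid"}
    if haploid_calls:
        db = identify_duplicates(db, haploid_calls, params)

    io.write_refdb_fasta(db, out / "refdb.fasta")
    io.write_tsv(db, out / "refdb.tsv")

    # truth locus -> database locus id map (unique loci only: collapsed
    # duplicates match two truth paralogs and drop out of the reciprocal map)
    truth_df = pd.DataFrame(state["genome"].fasta_records(),
                            columns=["locus_id", "sequence"])
    retained = db[db["status"].isin(("unique", "duplicated"))]
    idmap = crossdb_align(truth_df, retained[["locus_id", "sequence"]],
                          params.max_mismatch)
    idmap = idmap.rename(columns={"locus_a": "truth_locus",
                                  "locus_b": "db_locus"})
    # collapsed duplicated loci: map each db locus to its truth paralog pair
    dup_rows = []
    dup_ids = set(db.loc[db["status"] == "duplicated", "locus_id"])
    if dup_ids:
        from salhap.sequtils import hamming_matrix
        dup_db = db[db["locus_id"].isin(dup_ids)]
        dists = hamming_matrix(truth_df["sequence"].tolist(),
                               dup_db["sequence"].tolist())
        for j, db_lid in enumerate(dup_db["locus_id"]):
            for i in np.flatnonzero(dists[:, j] <= params.max_mismatch):
                dup_rows.append({"truth_locus": truth_df["locus_id"].iloc[i],
                                 "db_locus": db_lid})
    dupmap = pd.DataFrame(dup_rows, columns=["truth_locus", "db_locus"])
    io.write_tsv(idmap, out / "idmap.tsv")
    io.write_tsv(dupmap, out / "idmap_duplicated.tsv")

    state.update(db=db, calls=calls, idmap=idmap, dupmap=dupmap,
                 screening=params)
    return [out / "refdb.fasta", out / "refdb.tsv", out / "idmap.tsv",
            out / "idmap_duplicated.tsv"]


def _stage_genotype(run: PipelineRun, state: dict) -> list:
    out = run.out / "genotypes"
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    for fam, table in state["calls"].items():
        io.write_genotypes(table, out / f"{fam}.tsv")
        outputs.append(out / f"{fam}.tsv")
    return outputs


def _expand_family_duplicates(calls: pd.DataFrame, dup_ids: set):
    """Add per-paralog pseudo-markers for mappable duplicated loci.

    Returns (augmented genotype table, {pseudo marker: OPP|BPP},
    {locus: (pseudo P1, pseudo P2)} for BPP loci).
    """
    extra = {}
    classes = {}
    bpp = {}
    for lid in sorted(dup_ids & set(calls.columns)):
        parents = infer_duplicate_class(calls[lid])
        if parents is None:
            continue
        cls = classify_duplicate_marker(*parents)
        if not cls.is_mappable:
            continue
        expanded = expand_duplicate_calls(calls[lid], cls)
        names = {}
        for pno in cls.mappable_paralogs:
            name = f"{lid}_P{pno}"
            extra[name] = expanded[f"P{pno}"]
            classes[name] = "BPP" if len(cls.mappable_paralogs) == 2 else "OPP"
            names[pno] = name
        if len(cls.mappable_paralogs) == 2:
            bpp[lid] = (names[1], names[2])
    base = calls[[c for c in calls.columns if c not in dup_ids]]
    if extra:
        base = pd.concat([base, pd.DataFrame(extra, index=calls.index)],
                         axis=1)
    return base, classes, bpp


def _stage_map(run: PipelineRun, state: dict) -> list:
    cfg, out = run.cfg, run.out / "map"
    out.mkdir(parents=True, exist_ok=True)
    genome = state["genome"]
    lp_cfg = dict(cfg.get("linkage", {}))
    lp_cfg.setdefault("target_groups", genome.n_chromosomes)
    params = LinkageParams(**lp_cfg)
    db = state["db"]
    dup_ids = set(db.loc[db["status"] == "duplicated", "locus_id"])

    family_maps = []
    marker_classes: dict = {}
    bpp_pairs: dict = {}
    outputs = []
    for spec in state["crosses"]:
        if spec.cross_type != "haploid":
            continue
        fam = spec.family_id
        augmented, classes, bpp = _expand_family_duplicates(
            state["calls"][fam], dup_ids)
        marker_classes.update(classes)
        bpp_pairs.update(bpp)
        fam_map = build_map(augmented, params, family_id=fam)
        family_maps.append(fam_map)
        io.write_tsv(fam_map.table, out / f"map_{fam}.tsv")
        outputs.append(out / f"map_{fam}.tsv")
    if not family_maps:
        raise ValueError("no haploid family to map")

    consensus = (merge_maps(family_maps) if len(family_maps) > 1
                 else family_maps[0])

    # anchors emulate previously mapped markers: a few unique loci per
    # chromosome with known chromosome and arm, via the truth id map
    idmap = dict(zip(state["idmap"]["truth_locus"],
                     state["idmap"]["db_locus"]))
    n_anchor = int(cfg.get("anchors_per_chromosome", 3))
    anchor_rows = []
    mapped = set(consensus.table["marker"])
    for chrom_name, chrom in genome.chromosomes.items():
        cands = [l for l in genome.loci
                 if l.chromosome == chrom_name and not l.is_duplicated
                 and idmap.get(l.locus_id) in mapped]
        cands.sort(key=lambda l: l.position)
        if not cands:
            continue
        take = (cands if len(cands) <= n_anchor else
                [cands[int(round(i * (len(cands) - 1) / (n_anchor - 1)))]
                 for i in range(n_anchor)])
        for locus in take:
            arm, _ = chrom.arm_of(locus.position)
            anchor_rows.append({"marker": idmap[locus.locus_id],
                                "chromosome": chrom_name, "arm": arm,
                                "position": locus.position})
    anchors = pd.DataFrame(anchor_rows,
                           columns=["marker", "chromosome", "arm",
                                    "position"])
    anchored = anchor_groups(consensus, anchors)

    io.write_tsv(anchored.table, out / "map_consensus.tsv")
    io.write_tsv(anchored.conflicts, out / "conflicts.tsv")
    io.write_tsv(anchors, out / "anchors.tsv")
    outputs += [out / "map_consensus.tsv", out / "conflicts.tsv",
                out / "anchors.tsv"]
    state.update(family_maps=family_maps, consensus=anchored,
                 marker_classes=marker_classes, bpp_pairs=bpp_pairs,
                 dup_ids=dup_ids)
    return outputs


def _stage_centromere(run: PipelineRun, state: dict) -> list:
    out = run.out / "centromere"
    out.mkdir(parents=True, exist_ok=True)
    consensus = state["consensus"]
    dup_ids = state["dup_ids"]
    outputs = []

    gyno_tables = [state["calls"][s.family_id] for s in state["crosses"]
                   if s.cross_type == "gynogenetic_diploid"]
    midpoints: dict = {}
    intervals: dict = {}
    calls_rows = []
    if gyno_tables:
        pooled = pd.concat(gyno_tables, axis=0)
        profile = het_profile(pooled, consensus, exclude=dup_ids)
        io.write_tsv(profile, out / "profile_pooled.tsv")
        outputs.append(out / "profile_pooled.tsv")
        for gid, sub in profile.groupby("group", sort=True):
            if len(sub) < 3:
                continue
            call = locate_centromere(sub)
            row = {"group": gid, "type": call.chromosome_type,
                   "interval_lo": (call.interval[0] if call.interval
                                   else float("nan")),
                   "interval_hi": (call.interval[1] if call.interval
                                   else float("nan")),
                   "y_floor": call.y_floor, "mph_p": float("nan"),
                   "mph_q": float("nan")}
            if call.interval is not None:
                midpoints[gid] = call.midpoint
                intervals[gid] = call.interval
                mph = compute_mph(sub, call)
                row["mph_p"], row["mph_q"] = mph["p"], mph["q"]
            calls_rows.append(row)
        io.write_tsv(pd.DataFrame(calls_rows), out / "centromeres.tsv")
        outputs.append(out / "centromeres.tsv")

    haploids = [s for s in state["crosses"] if s.cross_type == "haploid"]
    if haploids and midpoints:
        fam = haploids[0].family_id
        xo = count_crossovers(state["calls"][fam], consensus, midpoints)
        io.write_tsv(xo, out / f"crossovers_{fam}.tsv")
        outputs.append(out / f"crossovers_{fam}.tsv")
        state["crossovers"] = xo
    state["centromere_midpoints"] = midpoints
    state["centromere_intervals"] = intervals
    return outputs


def _marker_arms(consensus, intervals: dict) -> pd.Series:
    """Arm label per mapped marker: side of the centromere interval.

    Markers inside the interval go to the nearer edge; groups without a
    located centromere or chromosome label get an empty arm label.
    """
    arms = {}
    for _, rec in consensus.table.iterrows():
        gid, marker = rec["group"], rec["marker"]
        chrom = rec.get("chromosome", "")
        span = intervals.get(gid)
        if span is None or not chrom:
            arms[marker] = ""
            continue
        lo, hi = span
        pos = rec["position"]
        if pos < lo:
            arm = "p"
        elif pos > hi:
            arm = "q"
        else:
            arm = "p" if (pos - lo) < (hi - pos) else "q"
        arms[marker] = f"{chrom}{arm}"
    return pd.Series(arms)


def _stage_duplication(run: PipelineRun, state: dict) -> list:
    cfg, out = run.cfg, run.out / "duplication"
    out.mkdir(parents=True, exist_ok=True)
    consensus = state["consensus"]
    marker_classes = dict(state["marker_classes"])
    for marker in consensus.table["marker"]:
        marker_classes.setdefault(marker, "unique")
    duplicated = {m: c in ("OPP", "BPP") for m, c in marker_classes.items()}

    density = duplicate_density(
        consensus.table, duplicated,
        bandwidth=float(cfg.get("density_bandwidth", 2.0)))
    io.write_tsv(density, out / "density.tsv")

    arms = _marker_arms(consensus, state.get("centromere_intervals", {}))
    bpp = pd.DataFrame(
        [{"pair_id": lid, "marker_1": p1, "marker_2": p2}
         for lid, (p1, p2) in sorted(state["bpp_pairs"].items())],
        columns=["pair_id", "marker_1", "marker_2"])
    homeologies = infer_homeologies(arms, bpp,
                                    min_support=int(cfg.get("min_support",
                                                            1)))
    io.write_tsv(homeologies, out / "homeologies.tsv")

    mapped_classes = {m: c for m, c in marker_classes.items()
                      if m in set(consensus.table["marker"])}
    summary = arm_duplicate_summary(arms, mapped_classes,
                                    top_k=int(cfg.get("top_k_arms", 16)))
    io.write_tsv(summary, out / "arm_summary.tsv")
    return [out / "density.tsv", out / "homeologies.tsv",
            out / "arm_summary.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "refdb": _stage_refdb,
    "genotype": _stage_genotype,
    "map": _stage_map,
    "centromere": _stage_centromere,
    "duplication": _stage_duplication,
}


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(scale: str = "tiny", seed: int = 0) -> dict:
    """Ready-made pipeline configs for tests and demos.

    ``tiny`` is a two-chromosome genome (one metacentric, one acrocentric,
    40 loci, 20 offspring per family) that runs the full chain in seconds;
    ``demo`` is the full 34-chromosome karyotype with the haploid families
    of 46/48/72, gynogenetic families of 84/90/93 and a 44-offspring diploid
    cross, plus a 159-individual database panel.
    """
    if scale == "tiny":
        return {
            "seed": int(seed),
            "genome": {
                "karyotype": {"n_metacentric": 1, "n_acrocentric": 1,
                              "metacentric_arm": 40.0,
                              "acrocentric_arm": 50.0},
                # odd marker counts put one marker at the metacentric
                # centromere, which the half-tetrad profile needs
                "layout": {"markers_per_chromosome": 17, "spacing": "even",
                           "dam_het_prob": 1.0},
                "homeologs": [{"arm_a": "Ots01q", "arm_b": "Ots02q",
                               "divergence": 2, "n_pairs": 4}],
            },
            "panel": {"n_individuals": 24},
            "crosses": [
                {"family_id": "HapA", "type": "haploid", "n_offspring": 20},
                {"family_id": "HapB", "type": "haploid", "n_offspring": 20},
                {"family_id": "GynA", "type": "gynogenetic_diploid",
                 "n_offspring": 20},
            ],
            "reads": {"mean_depth": 40.0, "dispersion": 5.0,
                      "error_rate": 0.0},
            # 20 offspring carry little linkage information; a LOD-2 start
            # suits that sample size (LOD 3 suits the 46-72 family sizes)
            "linkage": {"target_groups": 2, "lod_start": 2.0},
            "anchors_per_chromosome": 3,
        }
    if scale == "demo":
        homeologs = [
            ("Ots03p", "Ots23q"), ("Ots15p", "Ots17q"), ("Ots09q", "Ots27q"),
            ("Ots11p", "Ots34q"), ("Ots01q", "Ots06q"), ("Ots02q", "Ots32q"),
            ("Ots04q", "Ots12q"), ("Ots07p", "Ots14p"),
        ]
        return {
            "seed": int(seed),
            "genome": {
                "karyotype": {"n_metacentric": 16, "n_acrocentric": 18,
                              "metacentric_arm": 50.0,
                              "acrocentric_arm": 60.0},
                "layout": {"markers_per_chromosome": 13, "spacing": "even",
                           "dam_het_prob": 1.0},
                "homeologs": [{"arm_a": a, "arm_b": b, "divergence": 2,
                               "n_pairs": 8} for a, b in homeologs],
            },
            "panel": {"n_individuals": 159},
            "crosses": [
                {"family_id": "HapA", "type": "haploid", "n_offspring": 46},
                {"family_id": "HapB", "type": "haploid", "n_offspring": 48},
                {"family_id": "HapC", "type": "haploid", "n_offspring": 72},
                {"family_id": "GynA", "type": "gynogenetic_diploid",
                 "n_offspring": 84},
                {"family_id": "GynB", "type": "gynogenetic_diploid",
                 "n_offspring": 90},
                {"family_id": "GynC", "type": "gynogenetic_diploid",
                 "n_offspring": 93},
                {"family_id": "Dip", "type": "diploid", "n_offspring": 44},
            ],
            "reads": {"mean_depth": 40.0, "dispersion": 5.0,
                      "error_rate": 0.005},
            "linkage": {"target_groups": 34},
            "anchors_per_chromosome": 3,
        }
    raise ValueError(f"unknown fixture scale {scale!r}")
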