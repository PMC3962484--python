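"""Plain-text I/O: FASTA locus databases and tab-separated tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records, path):
    """Write (locus_id, sequence) pairs as FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=str(lid), description="")
                   for lid, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fasta(path) -> pd.DataFrame:
    rows = [{"locus_id": rec.id, "sequence": str(rec.seq)}
            for rec in SeqIO.parse(str(path), "fasta")]
    return pd.DataFrame(rows, columns=["locus_id", "sequence"])


def write_refdb_fasta(db: pd.DataFrame, path):
    """Reference database FASTA; status and reason ride in the header."""
    seq_records = []
    for _, rec in db.iterrows():
        desc = f"status={rec['status']}"
        if rec.get("reason"):
            desc += f" reason={str(rec['reason']).replace(' ', '_')}"
        seq_records.append(SeqRecord(Seq(rec["sequence"]),
                                     id=str(rec["locus_id"]),
                                     description=desc))
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_refdb_fasta(path) -> pd.DataFrame:
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(kv.split("=", 1) for kv in rec.description.split()[1:]
                    if "=" in kv)
        rows.append({"locus_id": rec.id, "sequence": str(rec.seq),
                     "status": tags.get("status", "unique"),
                     "reason": tags.get("reason", "").replace("_", " ")})
    return pd.DataFrame(rows, columns=["locus_id", "sequence", "status",
                                       "reason"])


def write_tsv(df: pd.DataFrame, path, index: bool = False):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_genotypes(path) -> pd.DataFrame:
    """Genotype matrix TSV: first column individual id, rest loci."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df.fillna("-")


def write_genotypes(genotypes: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = genotypes.copy()
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t")


def read_pileups(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"individual_id": str, "locus_id": str,
                            "allele": str, "depth": int})
    return df
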