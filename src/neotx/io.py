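"""Readers and writers for the pipeline's plain-text formats.

Count matrices, sample tables and result tables travel as TSV; transcript
sets as FASTA; externally computed similarity hits as standard 12-column
BLAST tabular output (outfmt 6).  Write->read round-trips are identity for
all tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orthology import Contig, HitRecord

__all__ = [
    "read_count_matrix",
    "read_sample_table",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_tsv",
    "read_tsv",
]

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "species", "age", "treatment")

#: Standard BLAST outfmt-6 column names.
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column ``gene_id``) of integer counts.

    Non-integer or negative cells raise, naming gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ValueError(
            f"{path}: first column must be named 'gene_id', got {df.index.name!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ValueError(f"{path}: non-numeric values in column {bad!r}")
    frac = np.mod(arr, 1) != 0
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValueError(
            f"{path}: non-integer count {arr[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return df.astype(np.int64)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV; requires sample_id/species/age/treatment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    bad_age = set(df["age"]) - {"adult", "juvenile"}
    if bad_age:
        raise ValueError(f"{path}: age must be adult/juvenile, got {sorted(bad_age)}")
    return df


def read_fasta(path: str | Path) -> list[Contig]:
    """Read transcripts as :class:`Contig` records (wrapped lines, any case)."""
    contigs = [
        Contig(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [c.id for c in contigs]
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"{path}: duplicate contig id {dup!r}")
    return contigs


def write_fasta(contigs, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Parse standard 12-column BLAST tabular hits into HitRecords.

    The e-value comes from column 11 and the bit score from column 12.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST6_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(BLAST6_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                score = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}")
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative e-value")
            hits.append(HitRecord(fields[0], fields[1], score, evalue))
    return hits


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a table as TSV with stable float formatting (round-trippable)."""
    table.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
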