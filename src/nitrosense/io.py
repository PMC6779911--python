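"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV except promoters/genomes (FASTA, via Biopython) and
motifs (MEME minimal text, see :mod:`nitrosense.motifs`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("length")


def read_peptides(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_coordinates(path) -> pd.DataFrame:
    """BED-like gene coordinate table: 0-based half-open, with strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "contig", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    return df


def read_labeling(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metabolite_conc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
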