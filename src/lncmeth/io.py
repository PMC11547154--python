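"""Tabular and sequence I/O for the pipeline's interchange formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct table (TSV/CSV by extension): columns
    sample, assay, replicate, ct; empty/NA ct means undetermined."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def read_cohort_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(list(records), str(path), "fasta")
    return path
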