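"""File I/O: FASTA proteomes, TSV tables, PSSM matrices.

TSV headers match the column names used throughout the pipeline (see
README).  Protein coordinates in all site tables are 1-based.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .kinase import KinasePSSM

__all__ = [
    "read_fasta", "write_fasta",
    "read_table", "write_table",
    "read_pssm", "read_pssm_dir",
]


def read_fasta(path) -> dict[str, str]:
    """Protein id -> sequence (uppercase)."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(proteome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "site_positions": str, "localization_scores": str,
    } if "quant" in str(path) else None)
    for col in ("site_positions", "localization_scores"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pssm(path, name: str | None = None, family: str = "") -> KinasePSSM:
    """Read one kinase matrix from delimited text.

    Layout: optional ``# name: X`` / ``# family: Y`` comment lines, then a
    tab-separated table whose first column is ``offset`` (-6..+6) and
    remaining columns are residues.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    k, v = line.lstrip("#").split(":", 1)
                    meta[k.strip().lower()] = v.strip()
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if "offset" not in df.columns:
        raise ValidationError(f"PSSM {path}: missing 'offset' column")
    df = df.set_index("offset")
    return KinasePSSM(
        name=name or meta.get("name", path.stem),
        family=family or meta.get("family", ""),
        weights=df,
    )


def read_pssm_dir(directory) -> list[KinasePSSM]:
    return [read_pssm(p) for p in sorted(Path(directory).glob("*.tsv"))]
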