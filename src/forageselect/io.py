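"""Readers and writers for the pipeline's plain-text tables and FASTA files.

All tables are TSV with a header row; FASTA goes through Bio.SeqIO and is
normalized to uppercase on read. Readers validate required columns and
refuse empty tables so a truncated file fails loudly, not silently.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_table", "write_table", "read_fasta", "write_fasta", "read_family_map"]


def read_table(path, required: tuple = (), name: str = "table") -> pd.DataFrame:
    """Read a TSV with a header row, checking required columns.

    Extra columns are preserved (with a warning); an empty table raises.
    """
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"no records: {name} at {path} is empty")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{name} at {path} missing required columns: {sorted(missing)}")
    extra = set(df.columns) - set(required)
    if required and extra:
        warnings.warn(f"{name}: extra columns preserved: {sorted(extra)}")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
    return path


def read_fasta(path) -> dict:
    """FASTA as an id -> uppercase-sequence dict (wrapped or unwrapped)."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no records: FASTA at {path} is empty")
    return records


def write_fasta(seqs: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s.upper()), id=str(i), description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_family_map(path) -> dict:
    """Species -> food-item map from a two-column TSV (species_id, family)."""
    df = read_table(path, required=("species_id", "family"), name="family map")
    return dict(zip(df["species_id"], df["family"]))
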