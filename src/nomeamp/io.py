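"""FASTA / TSV readers and writers shared by the CLI stages."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import AmpliconReference

__all__ = [
    "read_reference_fasta",
    "read_clones_fasta",
    "write_clones_fasta",
    "write_reference_fasta",
    "read_ct_table",
    "write_tsv",
]

CT_COLUMNS = ["region", "position_bp", "assay", "condition",
              "replicate", "ct", "input_fraction"]


def read_reference_fasta(path: str | Path,
                         genomic_offset: int = 0) -> AmpliconReference:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: expected a single reference record, "
            f"found {len(records)}")
    record = records[0]
    return AmpliconReference(name=record.id, sequence=str(record.seq),
                             genomic_offset=genomic_offset)


def read_clones_fasta(path: str | Path) -> list[tuple[str, str]]:
    clones = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not clones:
        raise ValueError(f"{path}: no clone records found")
    return clones


def write_clones_fasta(clones: list[tuple[str, str]],
                       path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in clones]
    SeqIO.write(records, str(path), "fasta")


def write_reference_fasta(reference: AmpliconReference,
                          path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(reference.sequence), id=reference.name,
                           description="")], str(path), "fasta")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ValueError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    return table


def write_tsv(frame: pd.DataFrame, path: str | Path,
              index: bool = False) -> None:
    """Deterministic TSV output: fixed float format, POSIX newlines."""
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g",
                 lineterminator="\n")
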