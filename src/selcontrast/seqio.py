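"""Readers and writers for the on-disk formats the pipeline consumes.

FASTA parsing is delegated to Biopython; annotation tables, per-column
alignment-reliability scores and per-tip aligned-column counts are plain TSV
read through pandas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

ANNOTATION_GROUPS = ("testis-region", "ovary-region", "tail-region", "ubiquitous")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Sequences are uppercased and RNA is normalized to DNA (U -> T).
    Raises on duplicate ids or an empty file.
    """
    records: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_column_scores(path) -> list[float]:
    """Per-column alignment reliability scores, one value per line
    (optionally ``column<TAB>score``)."""
    df = pd.read_csv(path, sep="\t", header=None)
    return [float(v) for v in df.iloc[:, -1]]


def write_column_scores(path, scores) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(scores):
            fh.write(f"{i + 1}\t{s:g}\n")


def read_aligned_columns(path) -> dict[str, int]:
    """TSV of ``tip_id<TAB>aligned_columns`` used by the ortholog pruner."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tip", "columns"])
    return dict(zip(df["tip"].astype(str), df["columns"].astype(int)))


@dataclass
class AnnotationTable:
    """Maps reference-species transcripts to annotation groups.

    Groups follow the body-region expression classification (testis-region /
    ovary-region / tail-region / ubiquitous, plus low-expressed transcripts
    kept only for filtering).  Expression levels, where present, are
    whole-body read counts.
    """

    group: dict[str, str] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for t, g in self.group.items():
            if g not in ANNOTATION_GROUPS and g != "low-expressed":
                raise ValueError(f"unknown annotation group {g!r} for {t}")

    @classmethod
    def read(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(group=dict(zip(df["transcript_id"], df["group"])))
        if "expression" in df.columns:
            table.expression = dict(zip(df["transcript_id"], df["expression"].astype(float)))
        return table

    def write(self, path) -> None:
        rows = []
        for t, g in self.group.items():
            row = {"transcript_id": t, "group": g}
            if t in self.expression:
                row["expression"] = self.expression[t]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
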