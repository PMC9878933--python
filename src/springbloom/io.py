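"""Flat-file I/O: abundance tables, FASTA sequences, alignment tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mobilome import GenomeRecord
from .profiles import AlignmentRecord, ReadHit

__all__ = [
    "write_abundance_tsv",
    "read_abundance_tsv",
    "write_fasta",
    "read_fasta",
    "read_alignments_tsv",
    "read_readhits_tsv",
]

ABUNDANCE_COLUMNS = ["sample_id", "day", "depth", "taxon_id", "unit", "value"]


def write_abundance_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=ABUNDANCE_COLUMNS)


def read_abundance_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(ABUNDANCE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    return frame


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description=r.role) for r in records),
        str(path),
        "fasta",
    )


def read_fasta(path, role: str = "contig", circular: bool = False) -> list[GenomeRecord]:
    return [
        GenomeRecord(rec.id, str(rec.seq), circular=circular, role=role)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_alignments_tsv(path, sample_id: str = "") -> list[AlignmentRecord]:
    """Blast-like tab-separated records: qseqid, sseqid, pident, length[, qcovs]."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["qseqid", "sseqid", "pident", "length", "qcovs"])
    return [
        AlignmentRecord(
            read_or_query_id=str(r.qseqid),
            target_id=str(r.sseqid),
            aligned_length_bp=int(r.length),
            percent_identity=float(r.pident),
            query_coverage=100.0 if pd.isna(r.qcovs) else float(r.qcovs),
            sample_id=sample_id,
        )
        for r in frame.itertuples()
    ]


def read_readhits_tsv(path) -> list[ReadHit]:
    """Read-hit table: read_id, sample_id, marker, taxonomy(;-joined),
    percent_identity[, flags(,-joined)]."""
    frame = pd.read_csv(path, sep="\t")
    hits = []
    for r in frame.itertuples():
        flags = frozenset()
        if hasattr(r, "flags") and isinstance(r.flags, str) and r.flags:
            flags = frozenset(r.flags.split(","))
        hits.append(ReadHit(
            read_id=str(r.read_id),
            marker=str(r.marker),
            best_hit_taxonomy=tuple(str(r.taxonomy).split(";")),
            percent_identity=float(r.percent_identity),
            flags=flags,
            sample_id=str(r.sample_id),
        ))
    return hits
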