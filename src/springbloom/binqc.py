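"""MAG hygiene: contig cleaning, rRNA consistency, quality gating, rhodopsins.

Cleaning rules for genomic bins:

* a contig is removed when more than 30% of its genes have no hit or hit
  eukaryotes/viruses (strict >), or when its own majority taxonomy
  conflicts with the bin consensus class;
* contigs whose 16S/23S rRNA classification disagrees with the bin's
  external (whole-bin) taxonomy are removed;
* bins pass quality gating only with > 40% completeness and < 5%
  contamination (strict, as stated).

The bin consensus class is the modal class over all gene-level calls,
computed once before any removal (single-pass cleaning, no iteration);
ties break toward the externally supplied bin taxonomy when given, else
lexicographically.  A contig's own taxonomy is its modal gene-level class.

Rhodopsin classification is a pure residue lookup at bacteriorhodopsin
numbering: motifs DTE/DTG/ATI at positions 85/89/96 indicate outward
proton pumping; residue 93 sets spectral tuning (L = green-absorbing,
Q = blue-absorbing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "JUNK_CALLS",
    "consensus_class",
    "clean_contigs",
    "rrna_consistency",
    "gate_bins",
    "RhodopsinCall",
    "classify_rhodopsin",
]

#: Gene calls that count against a contig (not real prokaryotic taxonomy).
JUNK_CALLS = frozenset({"no hit", "eukaryote", "virus"})

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _rank_label(call: str, rank: int | None) -> str:
    """Label at a taxonomy rank; plain labels pass through unchanged."""
    if rank is None or ";" not in call:
        return call
    parts = call.split(";")
    return parts[rank] if rank < len(parts) else parts[-1]


def consensus_class(
    genes: pd.DataFrame, external_taxon: str | None = None, rank: int | None = None
) -> str | None:
    """Modal class over all gene calls of a bin, junk calls excluded.

    Ties break toward ``external_taxon`` when it is among the tied labels,
    else lexicographically.
    """
    calls = [_rank_label(c, rank) for c in genes.call if c not in JUNK_CALLS]
    if not calls:
        return None
    counts = Counter(calls)
    top = max(counts.values())
    tied = sorted(label for label, n in counts.items() if n == top)
    if external_taxon is not None and _rank_label(external_taxon, rank) in tied:
        return _rank_label(external_taxon, rank)
    return tied[0]


def clean_contigs(
    genes: pd.DataFrame,
    frac_threshold: float = 0.30,
    external_taxon: str | None = None,
    rank: int | None = None,
) -> pd.DataFrame:
    """Single-pass consensus cleaning of one bin's contigs.

    ``genes`` has columns contig_id, call (one row per gene).  Returns one
    row per contig with ``retained`` and a reason code.  Contigs with zero
    gene calls cannot be evaluated and are flagged but retained.
    """
    consensus = consensus_class(genes, external_taxon, rank)
    rows = []
    for contig_id, group in genes.groupby("contig_id", sort=True):
        n_genes = len(group)
        if n_genes == 0:
            rows.append({"contig_id": contig_id, "retained": True, "reason": "no genes: not evaluated"})
            continue
        junk = sum(c in JUNK_CALLS for c in group.call)
        retained, reason = True, ""
        if junk / n_genes > frac_threshold:
            retained, reason = False, "junk fraction"
        else:
            own = consensus_class(group, rank=rank)
            if own is not None and consensus is not None and own != consensus:
                retained, reason = False, "consensus conflict"
        rows.append({"contig_id": contig_id, "retained": retained, "reason": reason})
    return pd.DataFrame(rows, columns=["contig_id", "retained", "reason"])


def rrna_consistency(
    rrna_calls: pd.DataFrame,
    bin_taxon: str,
    rank: int | None = None,
) -> pd.DataFrame:
    """Remove contigs whose 16S/23S call disagrees with the bin taxonomy.

    ``rrna_calls`` has columns contig_id, rrna_taxon; contigs without rRNA
    never appear here and are untouched by construction.  Unmappable
    (empty) calls are flagged but retained.
    """
    want = _rank_label(bin_taxon, rank)
    rows = []
    for row in rrna_calls.itertuples():
        call = _rank_label(str(row.rrna_taxon), rank)
        if not call or call == "nan":
            rows.append({"contig_id": row.contig_id, "retained": True, "reason": "unmappable rRNA call"})
        elif call == want:
            rows.append({"contig_id": row.contig_id, "retained": True, "reason": ""})
        else:
            rows.append({"contig_id": row.contig_id, "retained": False, "reason": "rRNA conflict"})
    return pd.DataFrame(rows, columns=["contig_id", "retained", "reason"])


def gate_bins(
    quality: pd.DataFrame,
    min_completeness: float = 40.0,
    max_contamination: float = 5.0,
) -> pd.DataFrame:
    """Quality gate: completeness > 40 and contamination < 5, both strict."""
    rows = []
    for row in quality.itertuples():
        comp, cont = row.completeness, row.contamination
        if pd.isna(comp) or pd.isna(cont):
            rows.append({"bin_id": row.bin_id, "passed": False, "reason": "unscored"})
        elif comp > min_completeness and cont < max_contamination:
            rows.append({"bin_id": row.bin_id, "passed": True, "reason": ""})
        else:
            reason = "completeness" if comp <= min_completeness else "contamination"
            rows.append({"bin_id": row.bin_id, "passed": False, "reason": reason})
    return pd.DataFrame(rows, columns=["bin_id", "passed", "reason"])


PUMP_MOTIFS = frozenset({"DTE", "DTG", "ATI"})
TUNING = {"L": "green", "Q": "blue"}


@dataclass(frozen=True)
class RhodopsinCall:
    protein_id: str
    motif: str  # residues 85/89/96, bacteriorhodopsin numbering
    residue_93: str
    pump_call: str  # proton_pump | other
    tuning_call: str  # green | blue | other


def classify_rhodopsin(motif: str, residue_93: str, protein_id: str = "") -> RhodopsinCall:
    """Pump and spectral-tuning call from the helix-3 motif and residue 93."""
    motif = motif.upper().replace("-", "")
    residue_93 = residue_93.upper()
    if len(motif) != 3 or not set(motif) <= _AA or residue_93 not in _AA:
        raise ValueError("residues must be single-letter amino acids (motif of 3)")
    pump = "proton_pump" if motif in PUMP_MOTIFS else "other"
    tuning = TUNING.get(residue_93, "other")
    return RhodopsinCall(protein_id, motif, residue_93, pump, tuning)
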