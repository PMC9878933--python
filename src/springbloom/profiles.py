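"""Read-level profiling: subsampling, rRNA classification, recruitment.

Implements the read-based abundance estimation steps: seeded uniform read
subsampling, 16S/18S read classification with the high-copy-lineage and
organelle exclusion rules, per-sample relative-abundance aggregation, and
fragment-recruitment filtering (>= 50 bp aligned, >= 95% identity) followed
by coverage-per-Gbp normalization.

Coverage per Gbp is defined on aligned bases:

    CPG = (sum aligned_length_bp / genome_length_bp) / (sample_bases_bp / 1e9)

A ``hits x read length`` compatibility mode is available where only hit
counts are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReadHit",
    "AlignmentRecord",
    "subsample_reads",
    "classify_rrna_reads",
    "aggregate_profile",
    "filter_recruitment",
    "coverage_per_gbp",
    "EXCLUDED_18S_LINEAGES",
    "ORGANELLE_FLAGS",
]

#: 18S lineages excluded because of extreme rRNA operon copy numbers
#: (dinoflagellates, ciliates) or multicellularity (metazoans).
EXCLUDED_18S_LINEAGES = frozenset({"Dinoflagellata", "Ciliophora", "Metazoa"})
#: Non-nuclear rRNA sources excluded for both markers.
ORGANELLE_FLAGS = frozenset({"chloroplast", "mitochondrion", "nucleomorph"})


@dataclass(frozen=True)
class ReadHit:
    """Best database hit of one candidate rRNA read."""

    read_id: str
    marker: str  # 16S | 18S
    best_hit_taxonomy: tuple[str, ...]
    percent_identity: float
    flags: frozenset = frozenset()
    sample_id: str = ""

    def __post_init__(self):
        if self.marker not in ("16S", "18S"):
            raise ValueError(f"unknown marker {self.marker!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
        if not self.best_hit_taxonomy:
            raise ValueError("taxonomy must be non-empty")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read- or fragment-level alignment feeding the recruitment filter."""

    read_or_query_id: str
    target_id: str
    aligned_length_bp: int
    percent_identity: float
    query_coverage: float = 100.0
    sample_id: str = ""

    def __post_init__(self):
        if self.aligned_length_bp < 1:
            raise ValueError("aligned_length_bp must be >= 1")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValueError("query_coverage outside [0, 100]")


def subsample_reads(read_ids, n: int, seed: int):
    """Uniform sample of min(n, total) read ids without replacement.

    The selected *set* depends only on the id set and the seed, not on the
    input order (ids are sorted before drawing).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ids = sorted(read_ids)
    if n >= len(ids):
        return list(ids)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(picked)]


def classify_rrna_reads(hits, identity_threshold: float = 95.0) -> pd.DataFrame:
    """Apply the identity floor and exclusion rules to candidate rRNA reads.

    A read is retained iff identity >= threshold, it carries no
    organelle/nucleomorph flag, and (for 18S) its taxonomy does not fall in
    a high-copy or metazoan lineage.  Excluded reads keep a reason code.
    """
    rows = []
    for h in hits:
        reason = ""
        if h.percent_identity < identity_threshold:
            reason = "below identity threshold"
        elif h.flags & ORGANELLE_FLAGS:
            reason = "organelle"
        elif h.marker == "18S" and set(h.best_hit_taxonomy) & EXCLUDED_18S_LINEAGES:
            reason = "high-copy lineage"
        rows.append({
            "read_id": h.read_id,
            "sample_id": h.sample_id,
            "marker": h.marker,
            "taxonomy": ";".join(h.best_hit_taxonomy),
            "percent_identity": h.percent_identity,
            "retained": reason == "",
            "reason": reason,
        })
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "marker", "taxonomy",
                                       "percent_identity", "retained", "reason"])


def aggregate_profile(classified: pd.DataFrame, rank: int = 1) -> pd.DataFrame:
    """Per-sample relative abundances (%) over retained reads at one rank.

    ``rank`` indexes the taxonomy path (0 = domain).  Samples with zero
    retained reads come back as flagged empty rows rather than NaN ratios.
    """
    out = []
    for sample_id, group in classified.groupby("sample_id", sort=True):
        kept = group[group.retained]
        if kept.empty:
            out.append({"sample_id": sample_id, "taxon": "", "percent": np.nan,
                        "flagged_empty": True})
            continue
        labels = kept.taxonomy.str.split(";").map(
            lambda path: path[rank] if rank < len(path) else path[-1])
        counts = labels.value_counts()
        for taxon, c in counts.sort_index().items():
            out.append({"sample_id": sample_id, "taxon": taxon,
                        "percent": 100.0 * c / len(kept), "flagged_empty": False})
    return pd.DataFrame(out, columns=["sample_id", "taxon", "percent", "flagged_empty"])


def filter_recruitment(records, min_len: int = 50, min_id: float = 95.0):
    """Keep alignments with length >= min_len and identity >= min_id.

    Boundaries are inclusive ("at least").  Idempotent by construction.
    """
    return [r for r in records
            if r.aligned_length_bp >= min_len and r.percent_identity >= min_id]


def coverage_per_gbp(
    records=None,
    genome_length_bp: float = None,
    sample_bases_bp: float = None,
    *,
    aligned_bases_bp: float | None = None,
    mode: str = "aligned_bases",
    read_length_bp: int = 150,
) -> float:
    """Normalized abundance: genome coverage per Gbp of sample sequence.

    Either pass filtered ``records`` or ``aligned_bases_bp`` directly.
    ``mode='hits_times_readlen'`` approximates aligned bases as
    len(records) * read_length_bp.
    """
    if genome_length_bp is None or genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be > 0")
    if sample_bases_bp is None or sample_bases_bp <= 0:
        raise ValueError("sample_bases_bp must be > 0")
    if aligned_bases_bp is None:
        records = list(records or [])
        if mode == "aligned_bases":
            aligned_bases_bp = float(sum(r.aligned_length_bp for r in records))
        elif mode == "hits_times_readlen":
            aligned_bases_bp = float(len(records) * read_length_bp)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    coverage = aligned_bases_bp / genome_length_bp
    return coverage / (sample_bases_bp / 1e9)
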