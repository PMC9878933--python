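"""Phage dereplication and host-evidence linking.

Dereplication follows the all-vs-all matching recipe: two phage genomes
belong to one cluster when they share > 95% nucleotide identity over > 95%
of the shorter genome (strict thresholds), and clusters are the connected
components of the passing-edge graph (single linkage).  The representative
of a cluster is its longest member (ties by id).

Pairwise matching is ungapped seed-and-extend: exact 15-mer seeds select
candidate diagonals, and on each diagonal maximal-scoring segments
(match +1, mismatch -3, minimum segment score 25) are extracted.  Reported
coverage is the union of segment projections on the shorter genome;
identity is the length-weighted mean over segments.  The scoring scheme is
the contract — a slow exhaustive scan over all diagonals must agree within
1 identity point and 2 coverage points.

Host evidence combines four routes: phage-borne marker genes (whiB ->
Actinobacteriota; the cyanobacterial sigma factor TIGR02997 ->
Cyanobacteria), attB/tRNA site sharing, CRISPR spacer matches, and generic
shared sequence, the latter three all at >= 30 bp, >= 97% identity, >= 97%
query coverage on either strand.  Short-query matching runs through edlib
infix alignment; circular phage targets are searched as doubled sequences
with coordinates reported modulo length.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord",
    "MatchEdge",
    "HostEvidence",
    "pairwise_match",
    "all_vs_all",
    "dereplicate",
    "marker_host",
    "site_match",
    "evidence_report",
    "maximal_segments",
    "revcomp",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
_CODE[ord(b"N")] = 4  # allowed; always counts as mismatch

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(sequence: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({sequence.upper()[i] for i in np.where(arr == 255)[0][:5]})
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return arr


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence with a role tag and optional annotations."""

    id: str
    sequence: str
    circular: bool = False
    gene_labels: tuple[str, ...] = ()
    role: str = "phage"  # phage | host | contig

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        _encode(self.sequence)  # validates alphabet

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchEdge:
    query_id: str
    target_id: str
    percent_identity: float
    coverage: float  # % of the shorter genome covered by alignments
    coverage_of: str  # id of the genome the coverage refers to
    aligned_length_bp: int


@dataclass(frozen=True)
class HostEvidence:
    phage_id: str
    evidence_type: str  # marker_whiB | marker_sigma_TIGR02997 | attB_tRNA | crispr_spacer | shared_sequence
    host_id: str
    host_taxon: str
    aligned_length_bp: int = 0
    percent_identity: float = 100.0
    query_coverage: float = 100.0
    strand: str = "+"
    target_start: int = -1
    conflicting: bool = False


# ---------------------------------------------------------------------------
# Ungapped segment machinery
# ---------------------------------------------------------------------------

#: Score mask applied to already-extracted segments.  Large enough that no
#: later segment can span a masked region, small enough that cumulative
#: sums keep integer-level float precision on 60 kb genomes.
_MASK = -1e6


def maximal_segments(
    match: np.ndarray,
    match_score: float = 1.0,
    mismatch_cost: float = 3.0,
    min_score: float = 25.0,
) -> list[tuple[int, int, int]]:
    """Disjoint maximal-scoring segments of a boolean match array.

    Returns (start, end, n_matches) with end exclusive.  Segments are
    extracted best-first via prefix sums; each extraction is O(n).
    """
    score = np.where(match, match_score, -mismatch_cost).astype(np.float64)
    segments = []
    while True:
        c = np.empty(len(score) + 1)
        c[0] = 0.0
        np.cumsum(score, out=c[1:])
        minacc = np.minimum.accumulate(c[:-1])
        ending = c[1:] - minacc
        j = int(np.argmax(ending))
        if ending[j] < min_score:
            break
        i = int(np.argmin(c[: j + 1]))
        n_matches = int(match[i : j + 1].sum())
        segments.append((i, j + 1, n_matches))
        score[i : j + 1] = _MASK
    return sorted(segments)


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """4-ary encoding of every k-mer; k-mers containing N get value -1."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    powers = 4 ** np.arange(k, dtype=np.int64)
    values = windows @ powers
    values[(windows >= 4).any(axis=1)] = -1
    return values


def _seed_diagonals(codes_a: np.ndarray, codes_b: np.ndarray, k: int) -> np.ndarray:
    """Diagonals (posA - posB) carrying at least one exact shared k-mer."""
    va = _kmer_values(codes_a, k)
    vb = _kmer_values(codes_b, k)
    order = np.argsort(vb, kind="stable")
    vb_sorted = vb[order]
    lo = np.searchsorted(vb_sorted, va, side="left")
    hi = np.searchsorted(vb_sorted, va, side="right")
    counts = np.minimum(hi - lo, 8)  # cap repeats from low-complexity k-mers
    valid = (counts > 0) & (va >= 0)
    reps = counts[valid]
    pos_a = np.repeat(np.nonzero(valid)[0], reps)
    offsets = np.arange(int(reps.sum())) - np.repeat(np.cumsum(reps) - reps, reps)
    pos_b = order[np.repeat(lo[valid], reps) + offsets]
    return np.unique(pos_a - pos_b)


def _merge_intervals(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        start = max(start, last_end)
        if end > start:
            total += end - start
            last_end = end
    return total


_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def pairwise_match(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 15,
    min_score: float = 25.0,
) -> MatchEdge:
    """Ungapped seed-and-extend comparison of two genomes, both strands.

    Coverage is measured on the shorter genome of the pair (the permissive
    reading, tolerant of assembly-length differences between near-identical
    genomes); segments from the reverse orientation are mapped back before
    taking the coverage union.
    """
    codes_a = _encode(a.sequence)
    codes_b_fwd = _encode(b.sequence)
    lb = len(codes_b_fwd)
    shorter = a if a.length_bp <= b.length_bp else b
    intervals: list[tuple[int, int]] = []
    total_matches = 0
    total_len = 0
    for reverse in (False, True):
        codes_b = _RC_CODE[codes_b_fwd[::-1]] if reverse else codes_b_fwd
        for d in _seed_diagonals(codes_a, codes_b, k):
            a_start = max(int(d), 0)
            b_start = max(-int(d), 0)
            length = min(len(codes_a) - a_start, lb - b_start)
            if length < k:
                continue
            seg_a = codes_a[a_start : a_start + length]
            seg_b = codes_b[b_start : b_start + length]
            match = (seg_a == seg_b) & (seg_a < 4)
            for s, e, n_match in maximal_segments(match, min_score=min_score):
                total_matches += n_match
                total_len += e - s
                if shorter is a:
                    intervals.append((a_start + s, a_start + e))
                elif reverse:
                    intervals.append((lb - (b_start + e), lb - (b_start + s)))
                else:
                    intervals.append((b_start + s, b_start + e))
    covered = _merge_intervals(intervals)
    identity = 100.0 * total_matches / total_len if total_len else 0.0
    coverage = 100.0 * covered / shorter.length_bp
    return MatchEdge(a.id, b.id, identity, coverage, shorter.id, total_len)


def all_vs_all(
    genomes: list[GenomeRecord],
    k: int = 15,
    sample_stride: int = 32,
    min_shared: int = 2,
) -> list[MatchEdge]:
    """Pairwise matches for candidate pairs sharing sampled exact k-mers.

    A sparse inverted index (every ``sample_stride``-th k-mer) screens the
    quadratic pair space; genuinely related genomes at the dereplication
    thresholds share thousands of k-mers and are never missed, while
    unrelated pairs almost never reach ``min_shared`` sampled collisions.
    """
    index: dict[int, list[int]] = defaultdict(list)
    for gi, g in enumerate(genomes):
        codes = _encode(g.sequence)
        fwd = _kmer_values(codes, k)[::sample_stride]
        rev = _kmer_values(_RC_CODE[codes[::-1]], k)[::sample_stride]
        for v in np.unique(np.concatenate([fwd, rev])):
            if v >= 0:
                index[int(v)].append(gi)
    shared = defaultdict(int)
    for members in index.values():
        for i, j in itertools.combinations(members, 2):
            shared[(i, j)] += 1
    edges = []
    for (i, j), count in sorted(shared.items()):
        if count >= min_shared:
            edges.append(pairwise_match(genomes[i], genomes[j], k=k))
    return edges


def dereplicate(
    edges: list[MatchEdge],
    genomes: list[GenomeRecord],
    min_identity: float = 95.0,
    min_coverage: float = 95.0,
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage clusters at strict > identity / > coverage thresholds.

    Returns (clusters, representatives); clusters are sorted id lists,
    singletons included.  Representative = longest member, ties by id.
    """
    ids = {g.id for g in genomes}
    parent = {gid: gid for gid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e.query_id not in ids or e.target_id not in ids:
            raise ValueError(f"edge references unknown genome: {e.query_id} - {e.target_id}")
        if e.percent_identity > min_identity and e.coverage > min_coverage:
            ra, rb = find(e.query_id), find(e.target_id)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = defaultdict(list)
    for gid in sorted(ids):
        groups[find(gid)].append(gid)
    clusters = sorted(groups.values())
    lengths = {g.id: g.length_bp for g in genomes}
    representatives = [
        min(cluster, key=lambda gid: (-lengths[gid], gid)) for cluster in clusters
    ]
    return clusters, representatives


# ---------------------------------------------------------------------------
# Host evidence
# ---------------------------------------------------------------------------

MARKER_HOSTS = {
    "whiB": ("marker_whiB", "Actinobacteriota"),
    "TIGR02997": ("marker_sigma_TIGR02997", "Cyanobacteria"),
}


def marker_host(genome: GenomeRecord) -> list[HostEvidence]:
    """Host calls from phage-borne marker genes; both markers -> conflict."""
    found = [MARKER_HOSTS[label] for label in MARKER_HOSTS if label in genome.gene_labels]
    conflict = len({taxon for _, taxon in found}) > 1
    return [
        HostEvidence(genome.id, ev_type, host_id="", host_taxon=taxon, conflicting=conflict)
        for ev_type, taxon in found
    ]


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(alignment columns, matches, query-consumed columns) from an
    edlib extended CIGAR (=, X, I, D)."""
    columns = matches = query_cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
        if ch in "=XI":  # columns consuming the query
            query_cols += n
    return columns, matches, query_cols


def site_match(
    query: str,
    phage: GenomeRecord,
    min_len: int = 30,
    min_identity: float = 97.0,
    min_query_coverage: float = 97.0,
    evidence_type: str = "shared_sequence",
    host_id: str = "",
    host_taxon: str = "",
) -> HostEvidence | None:
    """Best match of a short query (spacer, tRNA site, host fragment).

    Both strands are searched; circular phages are searched on a doubled
    sequence with the start coordinate reported modulo genome length.
    Evidence is emitted only when aligned length, identity and query
    coverage all reach the thresholds (inclusive).
    """
    query = query.upper()
    if len(query) < 1:
        raise ValueError("empty query")
    _encode(query)
    target = phage.sequence + phage.sequence[: len(phage.sequence) - 1] if phage.circular else phage.sequence
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        columns, matches, query_cols = _cigar_stats(res["cigar"])
        identity = 100.0 * matches / columns if columns else 0.0
        qcov = 100.0 * min(query_cols, len(query)) / len(query)
        start = res["locations"][0][0]
        cand = (identity, strand == "+", columns, matches, qcov, strand, start)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return None
    identity, _, columns, matches, qcov, strand, start = best
    if columns < min_len or identity < min_identity or qcov < min_query_coverage:
        return None
    return HostEvidence(
        phage_id=phage.id,
        evidence_type=evidence_type,
        host_id=host_id,
        host_taxon=host_taxon,
        aligned_length_bp=columns,
        percent_identity=identity,
        query_coverage=qcov,
        strand=strand,
        target_start=start % phage.length_bp,
    )


def evidence_report(phage_ids, evidence: list[HostEvidence]) -> pd.DataFrame:
    """One row per phage consolidating all evidence routes.

    A single host call is made only when every evidence item agrees on one
    taxon; disagreements are flagged, never silently resolved.
    """
    by_phage: dict[str, list[HostEvidence]] = defaultdict(list)
    for ev in evidence:
        by_phage[ev.phage_id].append(ev)
    rows = []
    for pid in phage_ids:
        items = by_phage.get(pid, [])
        taxa = sorted({ev.host_taxon for ev in items if ev.host_taxon})
        if not items:
            call, agree = "unassigned", True
        elif len(taxa) == 1:
            call, agree = taxa[0], True
        else:
            call, agree = "conflict", False
        rows.append({
            "phage_id": pid,
            "n_evidence": len(items),
            "evidence_types": ",".join(sorted({ev.evidence_type for ev in items})),
            "host_taxa": ",".join(taxa),
            "host_call": call,
            "agreement": agree,
        })
    return pd.DataFrame(rows, columns=["phage_id", "n_evidence", "evidence_types",
                                       "host_taxa", "host_call", "agreement"])
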