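"""Sequence fixtures with planted, machine-readable ground truth.

Generates phage genome families at controlled pairwise identity, host
genomes carrying CRISPR spacers and shared tRNA/attB sites pointing at
designated phages, and genomic bins with planted contaminant contigs.

The alphabet is uppercase ACGT and all mutations are substitutions, so
every planted identity is exactly computable: a copy mutated at
``round((1 - identity) * L)`` distinct positions realizes the target
identity to within half a position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..mobilome import GenomeRecord
from ..seeding import rng_for

__all__ = [
    "random_genome",
    "mutate_copy",
    "synth_phage_population",
    "synth_hosts_and_bins",
    "PhagePopulation",
    "HostBinFixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(length: int, rng: np.random.Generator) -> str:
    if length < 1:
        raise ValueError("length must be >= 1")
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_copy(sequence: str, identity_target: float, rng: np.random.Generator) -> str:
    """Substitute exactly round((1 - target) * L) positions to other bases."""
    if not (0.5 < identity_target <= 1.0):
        raise ValueError("identity target must lie in (0.5, 1.0]")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n_sub = int(round((1.0 - identity_target) * len(arr)))
    if n_sub == 0:
        return sequence
    positions = rng.choice(len(arr), size=n_sub, replace=False)
    shifts = rng.integers(1, 4, size=n_sub)  # always a different base
    idx = np.searchsorted(_BASES, arr[positions])
    arr[positions] = _BASES[(idx + shifts) % 4]
    return arr.tobytes().decode("ascii")


_HOST_CLASSES = [
    ("Actinobacteriota", ("whiB",)),
    ("Cyanobacteria", ("TIGR02997",)),
    (None, ()),
]


@dataclass
class PhagePopulation:
    records: list[GenomeRecord]
    #: every within-family pair (the planted duplicate truth)
    pairs: pd.DataFrame  # columns: a, b, family, identity_target
    #: per-record family and intended host class
    members: pd.DataFrame  # columns: genome_id, family, host_class, length_bp


def synth_phage_population(
    family_sizes,
    identity_targets=(0.97,),
    seed: int = 0,
    length_range: tuple[int, int] = (10_000, 60_000),
    circular: bool = False,
) -> PhagePopulation:
    """Phage families: one random ancestor plus substitution-mutated copies.

    ``family_sizes`` gives the number of genomes per family;
    ``identity_targets`` (cycled over families) sets the ancestor-copy
    identity.  Gene labels plant host-marker genes per family
    (whiB / TIGR02997 / none, cycled).
    """
    rng = rng_for(seed, "synth_phage_population")
    records, pair_rows, member_rows = [], [], []
    for fam, size in enumerate(family_sizes):
        target = float(identity_targets[fam % len(identity_targets)])
        if not (0.5 < target <= 1.0):
            raise ValueError("identity target must lie in (0.5, 1.0]")
        host_class, labels = _HOST_CLASSES[fam % len(_HOST_CLASSES)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = random_genome(length, rng)
        fam_ids = []
        for i in range(size):
            seq = ancestor if i == 0 else mutate_copy(ancestor, target, rng)
            gid = f"F{fam:03d}_{i}"
            records.append(GenomeRecord(gid, seq, circular=circular, gene_labels=labels, role="phage"))
            member_rows.append({"genome_id": gid, "family": fam,
                                "host_class": host_class, "length_bp": length})
            fam_ids.append(gid)
        for i in range(len(fam_ids)):
            for j in range(i + 1, len(fam_ids)):
                pair_rows.append({"a": fam_ids[i], "b": fam_ids[j],
                                  "family": fam, "identity_target": target})
    return PhagePopulation(
        records,
        pd.DataFrame(pair_rows, columns=["a", "b", "family", "identity_target"]),
        pd.DataFrame(member_rows, columns=["genome_id", "family", "host_class", "length_bp"]),
    )


@dataclass
class HostBinFixture:
    hosts: list[GenomeRecord]
    #: planted CRISPR spacers: host_id, spacer_id, sequence, source phage,
    #: number of planted mismatches
    spacers: pd.DataFrame
    #: planted tRNA/attB sites shared verbatim between host and phage
    trna_sites: pd.DataFrame
    #: per-gene taxonomy calls of binned contigs
    bin_genes: pd.DataFrame  # bin_id, contig_id, gene_index, call
    bin_quality: pd.DataFrame  # bin_id, completeness, contamination
    #: planted contaminant contigs (ground truth for cleaning)
    contaminants: pd.DataFrame  # bin_id, contig_id
    host_taxa: dict[str, str]


def synth_hosts_and_bins(
    phages: PhagePopulation,
    seed: int = 0,
    n_hosts: int = 20,
    host_length: int = 30_000,
    spacer_length: int = 32,
    spacer_mismatches: tuple[int, ...] = (0, 1),
    trna_length: int = 80,
    n_bins: int = 6,
    contigs_per_bin: int = 10,
    genes_per_contig: int = 10,
    contamination_fraction: float = 0.2,
    bin_classes: tuple[str, ...] = ("Actinomycetia", "Bacteroidia", "Gammaproteobacteria"),
) -> HostBinFixture:
    """Hosts with planted phage links, plus bins with planted contamination.

    Host *i* is linked to phage family ``i mod n_families``: it archives
    CRISPR spacers copied from that family's representative (one per entry
    of ``spacer_mismatches``) and shares one verbatim tRNA-site substring
    with it.  Bins get ``contamination_fraction`` of their contigs planted
    as contaminants whose genes call a different class.
    """
    if n_hosts > 0 and not phages.records:
        raise ValueError("phage population required to plant spacers")
    rng = rng_for(seed, "synth_hosts_and_bins")
    reps = {int(row.family): row.genome_id
            for row in phages.members.itertuples() if row.genome_id.endswith("_0")}
    by_id = {g.id: g for g in phages.records}
    host_class_of = dict(zip(phages.members.genome_id, phages.members.host_class))

    hosts, spacer_rows, trna_rows = [], [], []
    host_taxa = {}
    families = sorted(reps)
    for h in range(n_hosts):
        fam = families[h % len(families)]
        phage = by_id[reps[fam]]
        if spacer_length > phage.length_bp or trna_length > phage.length_bp:
            raise ValueError("requested site longer than source phage")
        host_id = f"H{h:03d}"
        taxon = host_class_of.get(phage.id) or "Bacteroidota"
        host_taxa[host_id] = taxon
        seq = np.frombuffer(random_genome(host_length, rng).encode("ascii"), np.uint8).copy()
        # tRNA/attB site: phage substring embedded verbatim in the host
        site_start = int(rng.integers(0, phage.length_bp - trna_length + 1))
        site = phage.sequence[site_start : site_start + trna_length]
        host_pos = int(rng.integers(0, host_length - trna_length + 1))
        seq[host_pos : host_pos + trna_length] = np.frombuffer(site.encode("ascii"), np.uint8)
        hosts.append(GenomeRecord(host_id, seq.tobytes().decode("ascii"), role="host"))
        trna_rows.append({"host_id": host_id, "site_id": f"{host_id}_trna0",
                          "sequence": site, "source_phage_id": phage.id,
                          "phage_start": site_start})
        for si, n_mm in enumerate(spacer_mismatches):
            start = int(rng.integers(0, phage.length_bp - spacer_length + 1))
            spacer = phage.sequence[start : start + spacer_length]
            if n_mm:
                spacer = mutate_copy(spacer, 1.0 - n_mm / spacer_length, rng)
            spacer_rows.append({"host_id": host_id, "spacer_id": f"{host_id}_sp{si}",
                                "sequence": spacer, "source_phage_id": phage.id,
                                "planted_mismatches": n_mm, "phage_start": start})

    gene_rows, quality_rows, contam_rows = [], [], []
    for b in range(n_bins):
        bin_id = f"bin{b:02d}"
        own = bin_classes[b % len(bin_classes)]
        other = bin_classes[(b + 1) % len(bin_classes)]
        n_contam = int(round(contamination_fraction * contigs_per_bin))
        contam_idx = set(rng.choice(contigs_per_bin, size=n_contam, replace=False).tolist())
        for c in range(contigs_per_bin):
            contig_id = f"{bin_id}_c{c:02d}"
            contaminant = c in contam_idx
            if contaminant:
                contam_rows.append({"bin_id": bin_id, "contig_id": contig_id})
            for g in range(genes_per_contig):
                if contaminant:
                    call = other if g < genes_per_contig - 1 else "no hit"
                else:
                    call = own if g < genes_per_contig - 1 else "no hit"
                gene_rows.append({"bin_id": bin_id, "contig_id": contig_id,
                                  "gene_index": g, "call": call})
        quality_rows.append({"bin_id": bin_id,
                             "completeness": float(rng.uniform(45, 99)),
                             "contamination": float(rng.uniform(0, 4.5))})

    return HostBinFixture(
        hosts=hosts,
        spacers=pd.DataFrame(spacer_rows, columns=["host_id", "spacer_id", "sequence",
                                                   "source_phage_id", "planted_mismatches", "phage_start"]),
        trna_sites=pd.DataFrame(trna_rows, columns=["host_id", "site_id", "sequence",
                                                    "source_phage_id", "phage_start"]),
        bin_genes=pd.DataFrame(gene_rows, columns=["bin_id", "contig_id", "gene_index", "call"]),
        bin_quality=pd.DataFrame(quality_rows, columns=["bin_id", "completeness", "contamination"]),
        contaminants=pd.DataFrame(contam_rows, columns=["bin_id", "contig_id"]),
        host_taxa=host_taxa,
    )
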