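"""Phage matching, dereplication and host-evidence linking."""

import numpy as np
import pytest

from springbloom import mobilome as mob
from springbloom import synth

from oracles import exhaustive_match, revcomp, sliding_window_best


class TestPairwiseMatch:
    def test_self_match_is_perfect(self, phage_30kb):
        e = mob.pairwise_match(phage_30kb, phage_30kb)
        assert e.percent_identity == pytest.approx(100.0)
        assert e.coverage == pytest.approx(100.0)

    def test_planted_identity_recovered(self, small_phage_pop):
        by_id = {g.id: g for g in small_phage_pop.records}
        row = small_phage_pop.pairs[small_phage_pop.pairs.identity_target == 0.97].iloc[0]
        e = mob.pairwise_match(by_id[row.a], by_id[row.b])
        assert e.percent_identity / 100 == pytest.approx(0.97, abs=0.005)
        assert e.coverage > 95.0

    def test_reverse_complement_duplicate_detected(self):
        rng = np.random.default_rng(4)
        a = mob.GenomeRecord("a", synth.random_genome(15_000, rng))
        b = mob.GenomeRecord("b", revcomp(a.sequence))
        e = mob.pairwise_match(a, b)
        assert e.percent_identity == pytest.approx(100.0)
        assert e.coverage == pytest.approx(100.0)

    def test_unrelated_random_genomes_have_negligible_coverage(self):
        rng = np.random.default_rng(7)
        a = mob.GenomeRecord("a", synth.random_genome(30_000, rng))
        b = mob.GenomeRecord("b", synth.random_genome(30_000, rng))
        assert mob.pairwise_match(a, b).coverage < 5.0

    def test_non_acgtn_characters_rejected(self):
        with pytest.raises(ValueError):
            mob.GenomeRecord("bad", "ACGTRY")

    @pytest.mark.parametrize("identity", [0.97, 0.9])
    def test_agrees_with_exhaustive_diagonal_oracle(self, identity):
        """Seeded extension vs every-diagonal scan: within 1 identity point
        and 2 coverage points on ~1 kb pairs."""
        rng = np.random.default_rng(int(identity * 100))
        anc = synth.random_genome(1000, rng)
        copy = synth.mutate_copy(anc, identity, rng)
        a, b = mob.GenomeRecord("a", anc), mob.GenomeRecord("b", copy)
        e = mob.pairwise_match(a, b)
        oid, ocov = exhaustive_match(anc, copy)
        assert abs(e.percent_identity - oid) <= 1.0
        assert abs(e.coverage - ocov) <= 2.0

    def test_partial_overlap_agrees_with_oracle(self):
        """One 300 bp shared block inside otherwise unrelated 1 kb genomes."""
        rng = np.random.default_rng(9)
        a_seq = synth.random_genome(1000, rng)
        b_seq = synth.random_genome(1000, rng)
        b_seq = b_seq[:400] + a_seq[100:400] + b_seq[700:]
        a, b = mob.GenomeRecord("a", a_seq), mob.GenomeRecord("b", b_seq)
        e = mob.pairwise_match(a, b)
        oid, ocov = exhaustive_match(a_seq, b_seq)
        assert abs(e.coverage - ocov) <= 2.0
        assert e.coverage == pytest.approx(30.0, abs=2.0)


class TestDereplication:
    def _genomes(self, n):
        return [mob.GenomeRecord(f"g{i}", "ACGT" * (10 + i)) for i in range(n)]

    def test_no_passing_edges_gives_singletons(self):
        genomes = self._genomes(5)
        edges = [mob.MatchEdge("g0", "g1", 94.0, 99.0, "g0", 100)]
        clusters, reps = mob.dereplicate(edges, genomes)
        assert len(clusters) == 5 and all(len(c) == 1 for c in clusters)

    def test_thresholds_are_strict(self):
        genomes = self._genomes(2)
        at_boundary = [mob.MatchEdge("g0", "g1", 95.0, 95.0, "g0", 100)]
        clusters, _ = mob.dereplicate(at_boundary, genomes)
        assert len(clusters) == 2  # > 95 required, 95.0 does not pass
        above = [mob.MatchEdge("g0", "g1", 95.1, 95.1, "g0", 100)]
        clusters, _ = mob.dereplicate(above, genomes)
        assert len(clusters) == 1

    def test_single_linkage_chain(self):
        """A-B and B-C pass, A-C fails -> still one cluster {A, B, C}."""
        genomes = self._genomes(3)
        edges = [mob.MatchEdge("g0", "g1", 96, 96, "g0", 1),
                 mob.MatchEdge("g1", "g2", 96, 96, "g1", 1),
                 mob.MatchEdge("g0", "g2", 80, 50, "g0", 1)]
        clusters, reps = mob.dereplicate(edges, genomes)
        assert clusters == [["g0", "g1", "g2"]]
        assert reps == ["g2"]  # longest member

    def test_unknown_genome_in_edge_rejected(self):
        with pytest.raises(ValueError):
            mob.dereplicate([mob.MatchEdge("g0", "nope", 99, 99, "g0", 1)],
                            self._genomes(2))

    def test_matches_networkx_components_on_random_graphs(self):
        import networkx as nx
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            genomes = self._genomes(n)
            edges = []
            passing = []
            for _ in range(int(rng.integers(0, 3 * n))):
                i, j = rng.integers(0, n, 2)
                if i == j:
                    continue
                ident = float(rng.uniform(80, 100))
                cov = float(rng.uniform(80, 100))
                edges.append(mob.MatchEdge(f"g{i}", f"g{j}", ident, cov, f"g{i}", 1))
                if ident > 95 and cov > 95:
                    passing.append((f"g{i}", f"g{j}"))
            clusters, _ = mob.dereplicate(edges, genomes)
            g = nx.Graph()
            g.add_nodes_from(f"g{i}" for i in range(n))
            g.add_edges_from(passing)
            expected = sorted(sorted(c) for c in nx.connected_components(g))
            assert clusters == expected

    def test_input_order_invariance(self, small_phage_pop):
        edges = mob.all_vs_all(small_phage_pop.records)
        c1, r1 = mob.dereplicate(edges, small_phage_pop.records)
        c2, r2 = mob.dereplicate(list(reversed(edges)),
                                 list(reversed(small_phage_pop.records)))
        assert c1 == c2 and r1 == r2

    def test_planted_families_recovered(self, small_phage_pop):
        edges = mob.all_vs_all(small_phage_pop.records)
        clusters, _ = mob.dereplicate(edges, small_phage_pop.records)
        assert len(clusters) == 3
        truth = small_phage_pop.members.groupby("family").genome_id.apply(
            lambda s: sorted(s)).tolist()
        assert sorted(clusters) == sorted(truth)


class TestMarkerHost:
    def _phage(self, labels):
        return mob.GenomeRecord("p", "ACGT" * 100, gene_labels=tuple(labels))

    def test_whib_means_actinobacteriota(self):
        (ev,) = mob.marker_host(self._phage(["terL", "whiB"]))
        assert ev.host_taxon == "Actinobacteriota" and not ev.conflicting

    def test_sigma_factor_means_cyanobacteria(self):
        (ev,) = mob.marker_host(self._phage(["TIGR02997"]))
        assert ev.host_taxon == "Cyanobacteria"

    def test_both_markers_flagged_conflicting(self):
        evs = mob.marker_host(self._phage(["whiB", "TIGR02997"]))
        assert len(evs) == 2 and all(ev.conflicting for ev in evs)

    def test_no_marker_no_evidence(self):
        assert mob.marker_host(self._phage(["terL"])) == []


class TestSiteMatch:
    def test_planted_spacer_hit(self, phage_30kb):
        spacer = phage_30kb.sequence[5000:5032]
        ev = mob.site_match(spacer, phage_30kb, evidence_type="crispr_spacer")
        assert ev is not None
        assert (ev.aligned_length_bp, ev.percent_identity, ev.query_coverage) == (32, 100.0, 100.0)
        assert ev.target_start == 5000 and ev.strand == "+"

    def test_reverse_strand_hit_reported(self, phage_30kb):
        spacer = revcomp(phage_30kb.sequence[5000:5032])
        ev = mob.site_match(spacer, phage_30kb)
        assert ev is not None and ev.strand == "-" and ev.target_start == 5000

    def test_one_mismatch_in_32bp_fails_identity_floor(self, phage_30kb):
        """31/32 = 96.9% < 97%: no evidence."""
        rng = np.random.default_rng(3)
        spacer = synth.mutate_copy(phage_30kb.sequence[5000:5032], 31 / 32, rng)
        assert mob.site_match(spacer, phage_30kb) is None

    def test_29bp_exact_match_fails_length_floor(self, phage_30kb):
        assert mob.site_match(phage_30kb.sequence[100:129], phage_30kb) is None

    def test_circular_origin_spanning_site(self):
        rng = np.random.default_rng(5)
        seq = synth.random_genome(10_000, rng)
        phage = mob.GenomeRecord("circ", seq, circular=True)
        wrapped = seq[-16:] + seq[:16]  # spans the origin
        ev = mob.site_match(wrapped, phage)
        assert ev is not None and ev.target_start == 10_000 - 16

    def test_empty_query_rejected(self, phage_30kb):
        with pytest.raises(ValueError):
            mob.site_match("", phage_30kb)

    def test_agrees_with_sliding_window_oracle(self, phage_30kb):
        """Hit/no-hit and coordinates equal the brute-force scan for planted
        queries at 0, 1 and 2 mismatches."""
        rng = np.random.default_rng(6)
        for n_mm in (0, 1, 2):
            start = int(rng.integers(0, 29_000))
            q = phage_30kb.sequence[start:start + 40]
            if n_mm:
                q = synth.mutate_copy(q, 1 - n_mm / 40, rng)
            mism, pos, strand = sliding_window_best(q, phage_30kb.sequence)
            expect_hit = (40 - mism) / 40 * 100 >= 97.0
            ev = mob.site_match(q, phage_30kb)
            assert (ev is not None) == expect_hit
            if ev is not None:
                assert (ev.target_start, ev.strand) == (pos, strand)


class TestEvidenceReport:
    def test_agreement_conflict_and_unassigned(self):
        evidence = [
            mob.HostEvidence("p1", "marker_whiB", "", "Actinobacteriota"),
            mob.HostEvidence("p1", "crispr_spacer", "H1", "Actinobacteriota"),
            mob.HostEvidence("p2", "marker_whiB", "", "Actinobacteriota"),
            mob.HostEvidence("p2", "crispr_spacer", "H2", "Cyanobacteria"),
        ]
        report = mob.evidence_report(["p1", "p2", "p3"], evidence)
        rows = report.set_index("phage_id")
        assert rows.loc["p1"].host_call == "Actinobacteriota" and rows.loc["p1"].agreement
        assert rows.loc["p2"].host_call == "conflict" and not rows.loc["p2"].agreement
        assert rows.loc["p3"].host_call == "unassigned"
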