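"""Simulator: growth update, observation noise, planted sequence truth."""

import math

import numpy as np
import pandas as pd
import pytest

from springbloom import mobilome as mob
from springbloom import synth
from springbloom.synth.community import PATTERN_ANCHORS

from oracles import sliding_window_best


def _one_taxon(mu, grazing, viral, init=100.0):
    return synth.TaxonSpec("t", gross_rate_h=mu, grazing_mortality_frac=grazing,
                           viral_mortality_frac=viral, init_abundance=init)


class TestGrowthUpdate:
    def test_pure_exponential_without_mortality(self, design):
        """m = 0, mu = ln2/24h: abundance doubles per day at every sampling day."""
        spec = _one_taxon(math.log(2) / 24.0, 0.0, 0.0)
        truth = synth.simulate_community([spec], design)
        s = truth.series("t", "epi")
        expected = 100.0 * 2.0 ** (s.day - s.day.iloc[0])
        assert np.allclose(s.value, expected, rtol=1e-12)

    def test_production_discount_closed_form(self):
        """N=100, gross doubling in 48 h, s=0.45 -> 145 after one 48 h step."""
        design = synth.SamplingDesign(epi_days=(0, 2), hypo_days=(0, 2))
        spec = _one_taxon(math.log(2) / 48.0, 0.24, 0.31)
        truth = synth.simulate_community([spec], design)
        assert truth.series("t", "epi").value.iloc[1] == pytest.approx(145.0, rel=1e-12)

    def test_rate_scaling_mode(self):
        design = synth.SamplingDesign(epi_days=(0, 2), hypo_days=(0, 2))
        spec = _one_taxon(math.log(2) / 48.0, 0.24, 0.31)
        truth = synth.simulate_community([spec], design, mode="rate_scaling")
        assert truth.series("t", "epi").value.iloc[1] == pytest.approx(
            100.0 * math.exp(0.45 * math.log(2)), rel=1e-12)

    def test_seeded_determinism_is_bitwise(self, design):
        specs = synth.pattern_taxa(seed=5)
        t1 = synth.simulate_community(specs, design)
        t2 = synth.simulate_community(synth.pattern_taxa(seed=5), design)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            _one_taxon(0.01, 0.6, 0.5)  # m >= 1
        with pytest.raises(ValueError):
            _one_taxon(float("nan"), 0.0, 0.0)
        with pytest.raises(ValueError):
            _one_taxon(0.01, 0.0, 0.0, init=0.0)

    def test_pattern_anchors_are_reproduced_exactly(self, design):
        """The rate schedules derived from anchor levels invert exactly."""
        specs = synth.pattern_taxa(n_per_category=1, seed=0, jitter=0.0)
        truth = synth.simulate_community(specs, design)
        s = truth.series("C1", "epi")
        anchors = PATTERN_ANCHORS["C"]["epi"]
        ratio = s.value.iloc[-1] / s.value.iloc[0]
        assert ratio == pytest.approx(anchors[37] / anchors[1], rel=1e-9)


class TestCardfishRendering:
    def test_noise_off_returns_exact_fractions(self, design):
        specs = [_one_taxon(0.0, 0.0, 0.0, init=250.0),
                 synth.TaxonSpec("other", gross_rate_h=0.0, grazing_mortality_frac=0,
                                 viral_mortality_frac=0, init_abundance=750.0)]
        truth = synth.simulate_community(specs, design)
        out = synth.render_cardfish(truth, noise=False)
        assert np.allclose(out[out.taxon_id == "t"].value, 25.0)
        cells = synth.render_cardfish(truth, noise=False, unit="cells_per_ml")
        assert np.allclose(cells[cells.taxon_id == "t"].value, 250.0)

    def test_absent_taxon_reports_zero(self, design):
        specs = [synth.TaxonSpec("epi_only", depth_niche="epi", init_abundance=100.0),
                 synth.TaxonSpec("everywhere", init_abundance=100.0)]
        truth = synth.simulate_community(specs, design)
        out = synth.render_cardfish(truth, noise=True)
        hypo = out[(out.taxon_id == "epi_only") & (out.depth == "hypo")]
        assert (hypo.value == 0).all()

    def test_binomial_counting_noise_is_calibrated(self, design):
        """Fraction 0.3, n=1000 cells, 200 replicates: mean within 3 SE of 30%."""
        specs = [_one_taxon(0.0, 0.0, 0.0, init=300.0),
                 synth.TaxonSpec("other", init_abundance=700.0)]
        truth = synth.simulate_community(specs, design)
        values = []
        for seed in range(200):
            out = synth.render_cardfish(truth, noise=True, seed=seed)
            values.append(out[out.taxon_id == "t"].value.iloc[0])
        se = math.sqrt(0.3 * 0.7 / 1000) * 100 / math.sqrt(200)
        assert abs(np.mean(values) - 30.0) < 3 * se


class TestRecruitmentRendering:
    def test_noise_off_is_linear_in_abundance(self, design):
        base = [_one_taxon(0.0, 0.0, 0.0, init=100.0)]
        doubled = [_one_taxon(0.0, 0.0, 0.0, init=200.0)]
        cpg1 = synth.render_recruitment(synth.simulate_community(base, design), noise=False)
        cpg2 = synth.render_recruitment(synth.simulate_community(doubled, design), noise=False)
        assert np.allclose(2 * cpg1.value, cpg2.value)

    def test_poisson_noise_is_calibrated(self):
        """Expected 400 hits, 100 replicates: mean CPG within 3 SE."""
        design = synth.SamplingDesign(epi_days=(1,), hypo_days=(1,), depths=("epi",))
        # lambda = reads * N * L / C = 2e7 * 20 * 2e6 / 2e12 = 400
        spec = _one_taxon(0.0, 0.0, 0.0, init=20.0)
        truth = synth.simulate_community([spec], design)
        expected = synth.render_recruitment(truth, noise=False).value.iloc[0]
        draws = [synth.render_recruitment(truth, noise=True, seed=s).value.iloc[0]
                 for s in range(100)]
        se = expected / math.sqrt(400) / math.sqrt(100)
        assert abs(np.mean(draws) - expected) < 3 * se

    def test_degenerate_empty_community_rejected(self, design):
        spec = synth.TaxonSpec("gone", depth_niche="epi", init_abundance=10.0)
        truth = synth.simulate_community([spec], design)
        with pytest.raises(ValueError, match="degenerate"):
            synth.render_recruitment(truth, noise=False)  # hypo total is zero


class TestSequenceFixtures:
    def test_identity_one_gives_byte_identical_copies(self):
        pop = synth.synth_phage_population([2], identity_targets=[1.0], seed=1)
        assert pop.records[0].sequence == pop.records[1].sequence

    def test_empty_population(self):
        pop = synth.synth_phage_population([], seed=1)
        assert pop.records == [] and pop.pairs.empty

    def test_identity_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synth.synth_phage_population([2], identity_targets=[0.4], seed=1)

    def test_realized_identity_matches_target_by_alignment_oracle(self):
        """0.97 target on ~30 kb: global-alignment identity within +-0.005."""
        import edlib
        pop = synth.synth_phage_population([2], identity_targets=[0.97], seed=2,
                                           length_range=(30_000, 30_000))
        a, b = pop.records[0].sequence, pop.records[1].sequence
        dist = edlib.align(a, b, mode="NW")["editDistance"]
        assert 1 - dist / len(a) == pytest.approx(0.97, abs=0.005)

    def test_planted_spacer_found_verbatim(self, small_phage_pop, host_fixture):
        by_id = {g.id: g for g in small_phage_pop.records}
        row = host_fixture.spacers[host_fixture.spacers.planted_mismatches == 0].iloc[0]
        mism, start, strand = sliding_window_best(row.sequence, by_id[row.source_phage_id].sequence)
        assert mism == 0 and start == row.phage_start and strand == "+"

    def test_planted_mismatch_spacer_has_expected_identity(self, small_phage_pop, host_fixture):
        """32 bp spacer with 1 planted mismatch: best identity 31/32."""
        by_id = {g.id: g for g in small_phage_pop.records}
        row = host_fixture.spacers[host_fixture.spacers.planted_mismatches == 1].iloc[0]
        mism, _, _ = sliding_window_best(row.sequence, by_id[row.source_phage_id].sequence)
        assert mism == 1
        assert (32 - mism) / 32 == pytest.approx(31 / 32)

    def test_trna_site_is_shared_verbatim(self, small_phage_pop, host_fixture):
        by_id = {g.id: g for g in small_phage_pop.records}
        row = host_fixture.trna_sites.iloc[0]
        host = next(h for h in host_fixture.hosts if h.id == row.host_id)
        assert row.sequence in host.sequence
        assert row.sequence in by_id[row.source_phage_id].sequence

    def test_zero_contamination_bins_survive_cleaning(self, small_phage_pop):
        from springbloom import binqc
        fixture = synth.synth_hosts_and_bins(small_phage_pop, seed=3, n_hosts=2,
                                             contamination_fraction=0.0)
        for _, genes in fixture.bin_genes.groupby("bin_id"):
            assert binqc.clean_contigs(genes).retained.all()
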