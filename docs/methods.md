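# Methods

This note documents the models, the defaults and the design choices behind
`springbloom`, and what the synthetic validation does and does not show.

## Growth kinetics

**Model.** Populations grow exponentially at a gross rate μ (h⁻¹) between
sampling points, while a fixed fraction m of gross production is lost
before observation — by default m = 0.55, split into 0.24 grazing and 0.31
viral lysis, the multi-lake average used for temperate bacterioplankton.
Two readings of "correcting for mortality" are implemented:

* `production_discount` (default): only the surviving share s = 1 − m of
  newly produced cells accumulates, N₂ = N₁(1 + s(e^{μΔt} − 1)). The
  estimator inverts this exactly, so simulator and estimator form a
  closed pair. This form is nonlinear in Δt: the ratio of estimated to
  observed doubling time varies with growth increment, which matches the
  group-to-group variability such corrections show in practice, whereas a
  constant multiplicative correction cannot.
* `rate_scaling`: μ = r/s, the simple multiplicative alternative, kept for
  sensitivity analyses.

**Interval rule.** Only adjacent sampling points with N₂/N₁ ≥ 1.25 enter
the estimate ("a change of at least 25%", read as an *increase*, since a
rate can only be computed from growth and the rule exists to isolate the
fastest-growing episodes / skip lag phases). The boundary is inclusive.
Intervals starting at zero abundance are skipped with a warning record.

**Units and pooling.** Estimates depend only on abundance ratios, so % of
DAPI, cells·ml⁻¹ and coverage per Gbp are handled identically; times are
internal hours (day labels × 24). Group summaries pool qualifying
intervals across all member series (all probes or MAGs of a group) rather
than averaging per-series means; a per-series mode can be assembled from
`estimate_series` directly. Epilimnion and hypolimnion series are analyzed
separately, never merged.

**Unit-convention caveat.** A CARD-FISH series expressed as % of DAPI is a
ratio to a changing community total, so its interval ratios differ from
cell-density ratios whenever the total drifts. Both renderings are
generated and the kinetics acceptance grid evaluates both conventions
under both correction modes; on simulated data the production-discount /
cells·ml⁻¹ combination is the uniquely exact one.

**Grazing totals.** Total protistan grazing is Σ_g (mean uptake rate of
grazer g, bacteria·grazer⁻¹·h⁻¹) × (in-situ abundance, grazers·ml⁻¹) × 24,
reported in bacteria·ml⁻¹·day⁻¹ with per-grazer contributions.

## Read profiling

Read subsampling is uniform without replacement and order-independent
(ids sorted before drawing). rRNA reads are retained at ≥ 95% identity
(inclusive) with three exclusion rules: organelle/nucleomorph flags;
and, for 18S, lineages with extreme rRNA operon copy numbers or
multicellularity (Dinoflagellata, Ciliophora, Metazoa). Per-sample
relative abundances are percentages over retained reads and sum to 100;
samples with zero retained reads are flagged rather than divided by zero.

Recruitment alignments pass at ≥ 50 bp and ≥ 95% identity (inclusive,
"at least"); query coverage is deliberately not part of the read filter.
Coverage per Gbp uses aligned bases:

    CPG = (Σ aligned bp / genome bp) / (sample bp / 10⁹),

with a `hits_times_readlen` compatibility mode when only hit counts are
known. CPG is linear in hit count and invariant in expectation under
uniform read subsampling (both properties are tested).

## Succession analysis

Rows of the (taxon × sample) matrix are Z-scored with the sample SD
(n − 1); constant rows map to zeros so clustering stays total. Row
distance is 1 − Spearman ρ (not halved: anticorrelated trajectories should
be maximally distant), with mean ranks for ties; rows with zero rank
variance get distance 1 to all others and are flagged. Clustering is
average linkage (UPGMA) on that distance; dendrograms can be serialized to
Newick.

The four succession archetypes are verbal categories operationalized with
explicit thresholds on per-depth Z-scored series (defaults: θ_high = +0.5,
θ_low = 0, peak prominence θ_peak = 1.5 Z, peak width ≤ 2 sampling
intervals; windows: start = days 1–4, bloom = 7–18, clear water = 30–37,
late hypolimnion = days ≥ 21):

* **D** ≥ 1 narrow prominent epilimnion peak and late hypolimnion below θ_low;
* **B** start ≥ θ_high, late hypolimnion ≥ θ_high, end < θ_low;
* **C** end ≥ θ_high, positive monotone trend, late hypolimnion < θ_low;
* **A** start and end both ≥ θ_high;

with precedence D > B > C > A (sharper, more specific patterns win).
Because the published categories are qualitative, these rules are a
documented operationalization: the generator's archetype prototypes are
the ground truth the classifier is validated against, and real-data
category membership cannot be scored this way.

Observer concordance is a Pearson correlation on day-matched pairs
(Spearman optional), with unmatched days dropped and reported.

## Mobilome

**Pairwise matching contract.** A local alignment is an ungapped maximal-
scoring diagonal segment (match +1, mismatch −3, minimum score 25,
N counts as mismatch). Reported identity is the length-weighted mean over
segments; coverage is the union of segment projections on the *shorter*
genome (the permissive reading, tolerant of assembly-length differences
within a cluster). The production path seeds diagonals with exact 15-mers
on both strands and extracts segments with an O(n) prefix-sum routine;
correctness is defined against an exhaustive every-diagonal scan, to
within 1 identity point and 2 coverage points. The ungapped model is
exact for the simulator's substitution-only fixtures and a deliberate
simplification for real indel-bearing genomes.

**Dereplication.** Edges pass at identity > 95 and coverage > 95 (strict,
as printed); clusters are connected components (single linkage) via
union-find, with the longest member (ties by id) as representative.
Candidate pairs for all-vs-all matching come from a sparse inverted index
of sampled k-mers (both strands, every 32nd position, ≥ 2 shared).

**Host evidence.** Marker genes give class-level calls (whiB →
Actinobacteriota; TIGR02997 → Cyanobacteria; both → flagged conflict).
Short queries (CRISPR spacers, tRNA/attB sites, host fragments) are
aligned with edlib infix alignment on both strands; evidence requires
aligned length ≥ 30 bp, identity ≥ 97%, query coverage ≥ 97% (inclusive).
The short sequence is always the query. An e-value condition is not
re-implemented: at ≥ 30 bp and ≥ 97% identity it is implied for
genome-scale targets, and the length floor is enforced instead. Circular
genomes are searched on a doubled sequence with start coordinates reported
modulo length. The evidence report makes a single host call only when all
routes agree on one taxon; disagreements are flagged, never resolved.

## MAG hygiene

Contig cleaning is single-pass: the bin consensus class (modal class over
all gene calls, junk calls excluded, ties toward the external taxonomy
else lexicographic) is computed once, then a contig is removed when its
no-hit/eukaryote/virus gene fraction exceeds 0.30 (strict >; exactly 30%
is kept) or its own modal class conflicts with the consensus. rRNA
consistency removes contigs whose 16S/23S classification disagrees with
the bin's external taxonomy at the comparison rank; contigs without rRNA
are untouched. Quality gating passes bins with completeness > 40 and
contamination < 5, both strict; unscored bins are excluded with a reason.
The comparison rank is configurable because class-level labels are not
stable across all clades.

Rhodopsin calls are pure residue lookups at bacteriorhodopsin numbering:
motifs DTE/DTG/ATI (positions 85/89/96) → outward proton pump; residue 93
L → green-absorbing, Q → blue-absorbing; anything else → other. Input is
case-insensitive and total over the 20-letter alphabet.

## The simulator

The generator emulates the statistical structure the analyses assume, not
the ecology itself:

* deterministic growth trajectories on the study grid (13 epilimnion days
  at 2–3-day spacing over 37 days; a weekly hypolimnion subset), with the
  production-discount mortality update;
* CARD-FISH counting as a binomial draw of probe-positive cells among
  1000 DAPI-inspected cells per sample (per-taxon independent binomials;
  the community total is taken as known when converting to cells·ml⁻¹);
* fragment recruitment as Poisson read hits with expectation
  reads × N × genome length / C, where C = 2 × 10¹² bp is a fixed
  reference scale chosen so that typical abundances (10⁵–10⁶ cells·ml⁻¹)
  map to coverage-per-Gbp values of order 10–100 at 2 × 10⁷ reads of
  150 bp; keeping C fixed makes CPG exactly linear in single-taxon
  abundance;
* sequences over uppercase ACGT with substitution-only mutation, so
  planted identities, spacer mismatches and family memberships are exactly
  computable;
* archetype prototypes realized as gross-rate schedules derived from
  anchor trajectories (log-linear between anchors), with lognormal
  per-member jitter so category members share a shape without being
  affine copies; prototype mortality is zero because anchors encode net
  trajectories and the grazing/viral split cannot affect shape.

One global integer seed drives a per-operation stream (operation name
hashed into the seed sequence), so noise-on renderings are reproducible
and independent across channels; noise-off renderings are deterministic
and seed-free.

Not emulated: nutrient dynamics, temperature forcing, realistic read error
profiles or FASTQ output, indels, inter-taxon count correlations beyond
the shared denominator, or uncertainty in total cell counts. Passing the
synthetic checks therefore demonstrates the correctness of the estimators
against their own model assumptions — exact inversion, calibrated noise
propagation, planted-truth recovery — not their robustness to the many
ways real data deviate from those assumptions.

**Validation scenario sizes.** The kinetics scenario runs one focal taxon
(gross doubling 37 h, 10⁵ cells·ml⁻¹ initial) over a static 2 × 10⁶
cells·ml⁻¹ background; sustained exponential growth across all 37 days is
a stylized test condition, not a realistic trajectory. Dereplication is
validated on 679 genomes in 175 families of 10–60 kb (a realistic survey
scale) plus 100 random edge-set trials of ≤ 50 genomes; host
linking on 20 hosts × 50 phages with 0- and 1-mismatch 32 bp spacer
plants; succession on 12 taxa (3 per archetype) with 20 noisy replicate
renderings; exhaustive-oracle comparisons for pairwise matching use ~1 kb
sequences where the quadratic scan is cheap.

## Known limitations

* The ungapped matching model understates identity for indel-divergent
  genomes; real assemblies should be dereplicated with alignment-based
  ANI when indels matter.
* The binomial CARD-FISH model ignores filter/field heterogeneity and
  counts each taxon independently rather than multinomially.
* Archetype thresholds are calibrated to Z-scored shapes with 13/6
  sampling points; sparser grids may need wider peak-width limits.
* The % of DAPI unit is a ratio estimator; doubling times computed from it
  inherit the community-total trend (see the unit-convention caveat).
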