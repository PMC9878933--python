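# springbloom

Analysis toolkit for high-frequency microbial time series of the freshwater
spring bloom, built around the bespoke computations such studies need but
general tools do not provide:

* **In-situ growth kinetics** — observed and mortality-corrected doubling
  times from abundance time series (CARD-FISH counts, cells·ml⁻¹, or
  metagenomic coverage per Gbp);
* **Read profiling** — seeded read subsampling, 16S/18S rRNA read
  classification with high-copy-lineage/organelle exclusion rules, and
  fragment-recruitment filtering with coverage-per-Gbp normalization;
* **Succession patterns** — row Z-scoring, average-linkage clustering under
  Spearman rank-correlation distance, rule-based assignment of taxa to four
  succession archetypes, and cross-observer concordance;
* **Mobilome** — phage genome dereplication by single-linkage clustering at
  the 95/95 identity/coverage thresholds, and host prediction from marker
  genes (whiB, TIGR02997), attB/tRNA sites, CRISPR spacers and shared
  sequence at ≥ 30 bp / ≥ 97% identity / ≥ 97% query coverage;
* **MAG hygiene** — gene-taxonomy contig cleaning, rRNA-vs-bin consistency,
  completeness/contamination gating, rhodopsin motif classification;
* **Simulator** (`springbloom.synth`) — a seeded generator of community
  trajectories, CARD-FISH/recruitment observations and sequence fixtures
  with machine-readable ground truth, so every stage can be validated
  end to end.

## The core statistic

For adjacent sampling times t₀, t₁ (hours) with abundances N₁, N₂, an
interval qualifies when N₂/N₁ ≥ 1.25 (a ≥ 25% increase). The observed net
growth rate and doubling time are

    r = ln(N₂/N₁) / (t₁ − t₀),        dt_obs = ln 2 / r .

Field estimates put mean bacterioplankton mortality at m = 0.55 of gross
production (0.24 grazing + 0.31 viral lysis). Assuming only the surviving
fraction s = 1 − m of newly produced cells accumulates,

    N₂ = N₁ · (1 + s·(e^{μΔt} − 1)),

the gross ("estimated") rate is recovered by the production-discount
inversion

    μ = ln(1 + (N₂/N₁ − 1)/s) / Δt,   dt_est = ln 2 / μ ,

with a simpler multiplicative alternative μ = r/s available as
`rate_scaling`. Group summaries pool qualifying intervals across all member
series and report mean ± sample SD.

## Worked example

Simulate one taxon growing at a gross doubling time of 37 h under 55%
mortality, observe it by CARD-FISH counting with binomial noise (1000 DAPI
cells per sample), and estimate its kinetics:

```python
from springbloom import synth, kinetics

design = synth.SamplingDesign(rng_seed=1)
truth = synth.simulate_community(synth.kinetics_scenario(gross_doubling_h=37.0), design)
obs = synth.render_cardfish(truth, noise=True, unit="cells_per_ml", seed=1)

series = kinetics.series_from_frame(obs, "target", depth="epi")
est = kinetics.estimate_series(series)
summary = kinetics.summarize_group([est], group_id="target")
print(f"qualifying intervals : {summary.n_intervals}")
print(f"observed doubling    : {summary.dt_obs_mean_h:.2f} +/- {summary.dt_obs_sd_h:.2f} h")
print(f"estimated doubling   : {summary.dt_est_mean_h:.2f} +/- {summary.dt_est_sd_h:.2f} h")
```

prints

```
qualifying intervals : 12
observed doubling    : 61.70 +/- 7.35 h
estimated doubling   : 37.05 +/- 2.31 h
```

All 12 epilimnion sampling intervals exceed the +25% rule; the observed
doubling time (net of mortality, ~62 h) is roughly 1.7× the
mortality-corrected estimate, which recovers the simulated 37 h gross
doubling time to within counting noise.

A `springbloom` command-line entry point exposes the same machinery as
subcommands (`synthgen`, `profile-rrna`, `recruit`, `kinetics`,
`succession`, `binqc`); run `springbloom --help`.

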