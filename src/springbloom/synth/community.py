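"""Seeded simulator of bloom community time series and their observation.

The simulator produces a ground-truth abundance trajectory per taxon and
depth on the study's sampling grid, then renders it through the two
observation channels used downstream:

* CARD-FISH counting — a binomial draw of probe-positive cells among a
  fixed number of DAPI-inspected cells, reported either as % of DAPI or
  converted to cells per ml;
* fragment recruitment — Poisson read hits proportional to
  abundance x genome length, normalized to coverage per Gbp with the same
  formula the profiling module applies to real alignments.

Growth follows gross exponential kinetics discounted by mortality: over a
sampling interval of length dt the update is

    N(t+dt) = N(t) * (1 + s * (exp(mu*dt) - 1)),   s = 1 - m,

where m is the summed grazing + viral mortality fraction (default
0.24 + 0.31 = 0.55).  Only the surviving share s of newly produced cells
accumulates, so the kinetics module's default mortality correction inverts
this update exactly.  A multiplicative alternative exp(mu*s*dt) is kept for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from ..seeding import rng_for

__all__ = [
    "EPI_DAYS",
    "HYPO_DAYS",
    "TaxonSpec",
    "SamplingDesign",
    "CommunityTruth",
    "simulate_community",
    "render_cardfish",
    "render_recruitment",
    "pattern_taxa",
    "kinetics_scenario",
    "PATTERN_ANCHORS",
]

#: Epilimnion sampling days (2-3 day spacing over 37 days, 13 samples).
EPI_DAYS: tuple[int, ...] = (1, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 30, 37)
#: Hypolimnion sampling days (weekly subset).
HYPO_DAYS: tuple[int, ...] = (1, 7, 14, 21, 30, 37)

DEPTHS = ("epi", "hypo")


def _as_schedule(rate, depth: str):
    """Normalize a growth-rate spec to a {day_start: mu} mapping for one depth.

    Accepted forms: scalar (both depths, all days); {day: mu} (both depths);
    {depth: scalar-or-{day: mu}}.
    """
    if isinstance(rate, Mapping):
        keys = list(rate.keys())
        if keys and all(isinstance(k, str) for k in keys):
            rate = rate.get(depth, 0.0)
        if not isinstance(rate, Mapping):
            return {0: float(rate)}
        return {float(k): float(v) for k, v in sorted(rate.items())}
    return {0: float(rate)}


def _mu_at(schedule: Mapping[float, float], day: float) -> float:
    """Rate in force on the interval starting at ``day`` (step function)."""
    mu = 0.0
    for start, value in sorted(schedule.items()):
        if day >= start:
            mu = value
    return mu


@dataclass(frozen=True)
class TaxonSpec:
    """Ground-truth parameters of one simulated population.

    ``gross_rate_h`` is the gross exponential growth rate mu in 1/h; it may
    be a per-day / per-depth schedule to create peaks and transitions.
    Mortality fractions partition gross production lost to grazers and to
    viral lysis (defaults 0.24 and 0.31, i.e. 55% total).
    """

    taxon_id: str
    taxonomy_path: tuple[str, ...] = ("Bacteria",)
    depth_niche: str = "both"  # epi | hypo | both
    pattern_category: str | None = None  # ground truth for succession tests
    gross_rate_h: float | Mapping = 0.0
    grazing_mortality_frac: float = 0.24
    viral_mortality_frac: float = 0.31
    init_abundance: float | Mapping[str, float] = 1e5  # cells/ml
    genome_length_bp: int = 2_000_000

    def __post_init__(self):
        m = self.grazing_mortality_frac + self.viral_mortality_frac
        if not (0.0 <= m < 1.0):
            raise ValueError(f"{self.taxon_id}: total mortality {m} outside [0, 1)")
        if self.depth_niche not in ("epi", "hypo", "both"):
            raise ValueError(f"bad depth_niche {self.depth_niche!r}")
        for depth in DEPTHS:
            for mu in _as_schedule(self.gross_rate_h, depth).values():
                if not math.isfinite(mu):
                    raise ValueError(f"{self.taxon_id}: non-finite growth rate")
        if min(self._inits().values()) <= 0:
            raise ValueError(f"{self.taxon_id}: init_abundance must be > 0")
        if self.genome_length_bp <= 0:
            raise ValueError(f"{self.taxon_id}: genome_length_bp must be positive")

    def _inits(self) -> dict[str, float]:
        if isinstance(self.init_abundance, Mapping):
            return {d: float(self.init_abundance.get(d, list(self.init_abundance.values())[0])) for d in DEPTHS}
        return {d: float(self.init_abundance) for d in DEPTHS}

    @property
    def survival(self) -> float:
        return 1.0 - self.grazing_mortality_frac - self.viral_mortality_frac

    def occupies(self, depth: str) -> bool:
        return self.depth_niche in ("both", depth)


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling grid and observation effort.

    ``reference_community_bases`` fixes the proportionality between
    cells/ml x genome bp and expected read hits, so that recruitment output
    is linear in any single taxon's abundance (no renormalization against
    the realized community total).
    """

    epi_days: tuple[float, ...] = EPI_DAYS
    hypo_days: tuple[float, ...] = HYPO_DAYS
    depths: tuple[str, ...] = DEPTHS
    dapi_cells_counted: int = 1000
    reads_per_sample: int = 20_000_000
    read_length_bp: int = 150
    reference_community_bases: float = 2e12
    rng_seed: int = 0

    def __post_init__(self):
        for days in (self.epi_days, self.hypo_days):
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("sampling days must be strictly increasing")
        if self.dapi_cells_counted < 1 or self.reads_per_sample < 1:
            raise ValueError("observation effort must be >= 1")

    def days(self, depth: str) -> tuple[float, ...]:
        return self.epi_days if depth == "epi" else self.hypo_days

    @property
    def sample_bases_bp(self) -> float:
        return float(self.reads_per_sample) * self.read_length_bp


@dataclass
class CommunityTruth:
    """Noise-free abundance N(t) per (taxon, depth, day), cells/ml."""

    abundance: pd.DataFrame  # columns: taxon_id, depth, day, value
    specs: dict[str, TaxonSpec]
    design: SamplingDesign

    def series(self, taxon_id: str, depth: str) -> pd.DataFrame:
        sel = self.abundance.query("taxon_id == @taxon_id and depth == @depth")
        return sel.sort_values("day").reset_index(drop=True)

    def totals(self, depth: str) -> pd.Series:
        sel = self.abundance[self.abundance.depth == depth]
        return sel.groupby("day")["value"].sum()

    def categories(self) -> dict[str, str | None]:
        """Machine-readable planted pattern ground truth."""
        return {t: s.pattern_category for t, s in self.specs.items()}


def simulate_community(
    specs: Sequence[TaxonSpec],
    design: SamplingDesign,
    mode: str = "production_discount",
) -> CommunityTruth:
    """Propagate every taxon over the sampling grid at each depth.

    Deterministic (the growth model carries no noise; stochasticity enters
    only through the observation renderers).
    """
    if not specs:
        raise ValueError("need at least one TaxonSpec")
    if mode not in ("production_discount", "rate_scaling"):
        raise ValueError(f"unknown mortality mode {mode!r}")
    rows = []
    for spec in specs:
        inits = spec._inits()
        s = spec.survival
        for depth in design.depths:
            days = design.days(depth)
            if not spec.occupies(depth):
                rows.extend((spec.taxon_id, depth, d, 0.0) for d in days)
                continue
            sched = _as_schedule(spec.gross_rate_h, depth)
            n = inits[depth]
            rows.append((spec.taxon_id, depth, days[0], n))
            for d0, d1 in zip(days, days[1:]):
                dt_h = (d1 - d0) * 24.0
                mu = _mu_at(sched, d0)
                if mode == "production_discount":
                    n = n * (1.0 + s * (math.exp(mu * dt_h) - 1.0))
                else:
                    n = n * math.exp(mu * s * dt_h)
                rows.append((spec.taxon_id, depth, d1, n))
    frame = pd.DataFrame(rows, columns=["taxon_id", "depth", "day", "value"])
    return CommunityTruth(frame, {s.taxon_id: s for s in specs}, design)


def _sample_id(depth: str, day: float) -> str:
    return f"{depth}_d{int(day):02d}" if float(day).is_integer() else f"{depth}_d{day}"


def render_cardfish(
    truth: CommunityTruth,
    design: SamplingDesign | None = None,
    *,
    noise: bool = True,
    unit: str = "percent_dapi",
    seed: int | None = None,
) -> pd.DataFrame:
    """CARD-FISH rendering: binomial counting of probe-positive cells.

    ``unit='percent_dapi'`` reports 100 * count / cells_counted;
    ``unit='cells_per_ml'`` multiplies the estimated fraction by the true
    community total (probe counting is the only noise source modelled).
    With ``noise=False`` exact fractions are returned, independent of seed.
    """
    design = design or truth.design
    if unit not in ("percent_dapi", "cells_per_ml"):
        raise ValueError(f"unknown unit {unit!r}")
    rng = rng_for(design.rng_seed if seed is None else seed, "render_cardfish")
    n_counted = design.dapi_cells_counted
    out = []
    for depth in design.depths:
        totals = truth.totals(depth)
        for day in design.days(depth):
            total = totals.get(day)
            if total is None:
                raise ValueError(f"truth does not cover {depth} day {day}")
            sel = truth.abundance.query("depth == @depth and day == @day")
            for _, row in sel.iterrows():
                frac = row.value / total if total > 0 else 0.0
                if not (0.0 <= frac <= 1.0 + 1e-12):
                    raise ValueError("corrupted truth: taxon fraction outside [0, 1]")
                frac = min(frac, 1.0)
                frac_hat = rng.binomial(n_counted, frac) / n_counted if noise else frac
                value = 100.0 * frac_hat if unit == "percent_dapi" else frac_hat * total
                out.append((_sample_id(depth, day), day, depth, row.taxon_id, unit, value))
    return pd.DataFrame(out, columns=["sample_id", "day", "depth", "taxon_id", "unit", "value"])


def render_recruitment(
    truth: CommunityTruth,
    design: SamplingDesign | None = None,
    *,
    noise: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fragment-recruitment rendering: Poisson read hits -> coverage per Gbp.

    Expected hits = reads_per_sample * N * genome_length /
    reference_community_bases; realized hits are Poisson draws.  The
    reported value goes through :func:`springbloom.profiles.coverage_per_gbp`
    so renderer and estimator share a single normalization.
    """
    from .. import profiles  # local import: profiles does not import synth

    design = design or truth.design
    rng = rng_for(design.rng_seed if seed is None else seed, "render_recruitment")
    out = []
    for depth in design.depths:
        totals = truth.totals(depth)
        for day in design.days(depth):
            if totals.get(day, 0.0) <= 0:
                raise ValueError(f"degenerate scenario: zero community abundance at {depth} day {day}")
            sel = truth.abundance.query("depth == @depth and day == @day")
            for _, row in sel.iterrows():
                genome_len = truth.specs[row.taxon_id].genome_length_bp
                lam = design.reads_per_sample * row.value * genome_len / design.reference_community_bases
                hits = float(rng.poisson(lam)) if noise else lam
                cpg = profiles.coverage_per_gbp(
                    aligned_bases_bp=hits * design.read_length_bp,
                    genome_length_bp=genome_len,
                    sample_bases_bp=design.sample_bases_bp,
                )
                out.append((_sample_id(depth, day), day, depth, row.taxon_id, "coverage_per_gbp", cpg))
    return pd.DataFrame(out, columns=["sample_id", "day", "depth", "taxon_id", "unit", "value"])


# ---------------------------------------------------------------------------
# Succession pattern prototypes
# ---------------------------------------------------------------------------

# Net abundance anchors (cells/ml) realizing the four succession archetypes:
#   A generalists, high at both ends of the study window;
#   B cold-adapted, epilimnion-high early then transitioning to hypolimnion;
#   C warm-adapted, monotone rise peaking in the clear-water phase;
#   D bloom specialists with short-lived epilimnion spikes.
PATTERN_ANCHORS: dict[str, dict[str, dict[float, float]]] = {
    "A": {
        "epi": {1: 100, 4: 100, 7: 40, 9: 25, 11: 15, 14: 12, 16: 11, 18: 10,
                21: 15, 23: 20, 25: 30, 30: 70, 37: 100},
        "hypo": {1: 20, 7: 20, 14: 20, 21: 20, 30: 20, 37: 20},
    },
    "B": {
        "epi": {1: 100, 4: 90, 7: 80, 9: 65, 11: 50, 14: 40, 16: 32, 18: 25,
                21: 18, 23: 13, 25: 10, 30: 5, 37: 2},
        "hypo": {1: 5, 7: 5, 14: 5, 21: 20, 30: 60, 37: 100},
    },
    "C": {
        "epi": {1: 2, 4: 3, 7: 4.5, 9: 6, 11: 8, 14: 11, 16: 15, 18: 20,
                21: 27, 23: 35, 25: 45, 30: 70, 37: 100},
        "hypo": {1: 50, 7: 40, 14: 25, 21: 15, 30: 8, 37: 5},
    },
    "D": {
        "epi": {1: 5, 4: 5, 7: 5, 9: 5, 11: 80, 14: 5, 16: 5, 18: 5,
                21: 5, 23: 5, 25: 5, 30: 5, 37: 5},
        "hypo": {1: 30, 7: 25, 14: 18, 21: 12, 30: 6, 37: 3},
    },
}
_ANCHOR_SCALE = 1e3  # anchors above are in units of 1e3 cells/ml


def _schedule_from_anchors(anchors: Mapping[float, float]) -> dict[float, float]:
    """Gross-rate schedule reproducing the anchor trajectory with m = 0."""
    days = sorted(anchors)
    sched = {}
    for d0, d1 in zip(days, days[1:]):
        dt_h = (d1 - d0) * 24.0
        sched[d0] = math.log(anchors[d1] / anchors[d0]) / dt_h
    return sched


def pattern_taxa(
    n_per_category: int = 3,
    seed: int = 0,
    jitter: float = 0.1,
    categories: Iterable[str] = ("A", "B", "C", "D"),
) -> list[TaxonSpec]:
    """Taxa realizing the succession archetypes, with per-member variation.

    Each member's anchor levels are jittered lognormally (sd ``jitter`` on
    the log scale) and scaled by a random overall factor, so members of a
    category share a shape without being affine copies.  Prototype
    mortality fractions are zero: anchors encode *net* trajectories and the
    grazing/viral split is irrelevant to pattern shape.
    """
    rng = rng_for(seed, "pattern_taxa")
    specs = []
    for cat in categories:
        base = PATTERN_ANCHORS[cat]
        for i in range(n_per_category):
            scale = _ANCHOR_SCALE * float(rng.uniform(0.5, 2.0))
            anchors = {
                depth: {d: v * scale * float(np.exp(rng.normal(0.0, jitter)))
                        for d, v in base[depth].items()}
                for depth in DEPTHS
            }
            specs.append(TaxonSpec(
                taxon_id=f"{cat}{i + 1}",
                taxonomy_path=("Bacteria", f"Phylum_{cat}"),
                depth_niche="both",
                pattern_category=cat,
                gross_rate_h={d: _schedule_from_anchors(anchors[d]) for d in DEPTHS},
                grazing_mortality_frac=0.0,
                viral_mortality_frac=0.0,
                init_abundance={d: anchors[d][1] for d in DEPTHS},
            ))
    return specs


def kinetics_scenario(
    gross_doubling_h: float = 37.0,
    grazing_frac: float = 0.24,
    viral_frac: float = 0.31,
    init_abundance: float = 1e5,
    background_abundance: float = 2e6,
) -> list[TaxonSpec]:
    """One exponentially growing focal taxon over a static background.

    The focal taxon grows at gross rate ln2 / ``gross_doubling_h`` with the
    default 55% mortality discount; the background taxon is flat and only
    provides the denominator for CARD-FISH fractions.
    """
    return [
        TaxonSpec(
            taxon_id="target",
            taxonomy_path=("Bacteria", "Actinobacteriota"),
            gross_rate_h=math.log(2.0) / gross_doubling_h,
            grazing_mortality_frac=grazing_frac,
            viral_mortality_frac=viral_frac,
            init_abundance=init_abundance,
            genome_length_bp=1_400_000,
        ),
        TaxonSpec(
            taxon_id="background",
            taxonomy_path=("Bacteria", "Mixed"),
            gross_rate_h=0.0,
            grazing_mortality_frac=0.0,
            viral_mortality_frac=0.0,
            init_abundance=background_abundance,
            genome_length_bp=3_000_000,
        ),
    ]
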