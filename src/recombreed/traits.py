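"""Trait architecture: marker panels, QTL assignment, effects, phenotypes.

Additive model throughout: genetic value g = sum_i a_i * dose_i with dose
the count of the allele coded 1 (0/1/2).  No dominance or epistasis.
Effect magnitudes are |N(0,1)| draws whose signs are overwritten by one of
five coupling/repulsion scenarios; effects are rescaled so the reference
population has additive variance exactly 1, and the phenotype error
variance is fixed from heritability at that moment and held constant
afterwards (so realized heritability drifts as variance erodes under
selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .populations import FounderSet, Population, VariantAnnotation

#: Fractions of annotated loci entering the deleterious-variant QTL
#: candidate pool each replicate: 90% of high-impact, 25% of nonsynonymous.
DV_HIGH_FRACTION = 0.9
DV_NONSYN_FRACTION = 0.25

SCENARIOS = (1, 2, 3, 4, 5)
#: Probability that a QTL effect sign is positive, for the Bernoulli
#: scenarios (2, 3, 5); scenarios 1 and 4 are deterministic patterns.
_SIGN_PROB = {2: 2.0 / 3.0, 3: 0.5, 5: 1.0 / 3.0}


@dataclass
class TraitArchitecture:
    """QTL locus indices (global, map-ordered) and their additive effects."""

    qtl_idx: np.ndarray
    effects: np.ndarray
    qtl_type: str = "R"
    scenario: int = 1

    def __post_init__(self):
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.qtl_idx.shape != self.effects.shape:
            raise ValueError("qtl_idx and effects must align")
        if np.any(np.diff(self.qtl_idx) <= 0):
            raise ValueError("qtl_idx must be strictly increasing (map order)")

    @property
    def n_qtl(self) -> int:
        return self.qtl_idx.size

    def with_effects(self, effects: np.ndarray) -> "TraitArchitecture":
        return replace(self, effects=np.asarray(effects, dtype=float))

    def to_table(self, gmap=None) -> pd.DataFrame:
        df = pd.DataFrame({"locus": self.qtl_idx, "effect": self.effects})
        if gmap is not None:
            chrom = gmap.chrom_of_locus()[self.qtl_idx]
            df.insert(0, "chromosome", [gmap.chromosomes[c].name or str(c) for c in chrom])
            df["position"] = gmap.all_positions()[self.qtl_idx]
        return df


@dataclass
class PhenotypeModel:
    """Heritability and the error variance frozen at standardization time."""

    h2: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_e < 0:
            raise ValueError("error variance must be non-negative")

    @classmethod
    def from_heritability(cls, h2: float, var_a: float = 1.0) -> "PhenotypeModel":
        """sigma2_e = varA (1 - H2) / H2, with varA = 1 after standardization."""
        if not 0 < h2 <= 1:
            raise ValueError("heritability must be in (0, 1]")
        return cls(h2, var_a * (1.0 - h2) / h2)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_snpchip(founders: FounderSet, per_bin: int = 10,
                   rng: np.random.Generator | None = None,
                   bin_width: float = 0.01) -> np.ndarray:
    """Marker panel: up to ``per_bin`` SNPs drawn uniformly per 1-cM bin.

    Empty bins contribute nothing; bins with fewer SNPs than ``per_bin``
    contribute all of them.  The default of 10 per bin yields ~1200 markers
    on a 1.22 M chromosome.  Returns sorted global locus indices.
    """
    rng = np.random.default_rng() if rng is None else rng
    picks: list[np.ndarray] = []
    for ci, chrom in enumerate(founders.map.chromosomes):
        base = founders.map.offsets[ci]
        bins = np.floor(chrom.positions / bin_width).astype(int)
        for b in np.unique(bins):
            members = np.where(bins == b)[0]
            take = members if members.size <= per_bin else rng.choice(members, per_bin, replace=False)
            picks.append(base + take)
    return np.sort(np.concatenate(picks)) if picks else np.empty(0, dtype=int)


def sample_dv_pool(annotations: VariantAnnotation, rng: np.random.Generator) -> np.ndarray:
    """Deleterious-variant QTL candidate pool, re-drawn each replicate.

    Exactly round(0.9 * n_high) high-impact and round(0.25 * n_nonsyn)
    nonsynonymous loci, sampled without replacement (round = half-up).
    """
    high = np.where(annotations.high_impact)[0]
    nonsyn = np.where(annotations.nonsynonymous)[0]
    if high.size == 0 and nonsyn.size == 0:
        raise ValueError("no annotated loci available for a deleterious-variant QTL run")
    take_h = round_half_up(DV_HIGH_FRACTION * high.size)
    take_n = round_half_up(DV_NONSYN_FRACTION * nonsyn.size)
    picked = []
    if take_h:
        picked.append(rng.choice(high, take_h, replace=False))
    if take_n:
        picked.append(rng.choice(nonsyn, take_n, replace=False))
    return np.sort(np.concatenate(picked)) if picked else np.empty(0, dtype=int)


def qtl_counts_per_chrom(founders: FounderSet, n_per_chrom: int,
                         d_group_n: int | None = None) -> np.ndarray:
    """Per-chromosome QTL counts, with the D-subgenome reduction if set."""
    counts = np.full(founders.map.n_chrom, n_per_chrom, dtype=int)
    if d_group_n is not None:
        counts[np.array(founders.genome_group) == "D"] = d_group_n
    return counts


def assign_qtl(founders: FounderSet, qtl_type: str, n_per_chrom,
               marker_set: np.ndarray, rng: np.random.Generator,
               dv_pool: np.ndarray | None = None) -> np.ndarray:
    """Draw QTL loci per chromosome, disjoint from the marker panel.

    ``R`` draws uniformly from non-marker loci; ``DV`` draws uniformly from
    the candidate pool minus markers.  ``n_per_chrom`` may be a scalar or a
    per-chromosome sequence.
    """
    gmap = founders.map
    counts = np.broadcast_to(np.asarray(n_per_chrom, dtype=int), (gmap.n_chrom,))
    markers = np.zeros(gmap.n_loci, dtype=bool)
    markers[np.asarray(marker_set, dtype=int)] = True
    in_pool = None
    if qtl_type == "DV":
        if dv_pool is None:
            raise ValueError("DV QTL assignment requires a candidate pool")
        in_pool = np.zeros(gmap.n_loci, dtype=bool)
        in_pool[np.asarray(dv_pool, dtype=int)] = True
    elif qtl_type != "R":
        raise ValueError(f"unknown qtl_type {qtl_type!r}")
    chosen = []
    for ci in range(gmap.n_chrom):
        sl = gmap.chrom_slice(ci)
        ok = ~markers[sl]
        if in_pool is not None:
            ok &= in_pool[sl]
        eligible = np.where(ok)[0] + gmap.offsets[ci]
        name = gmap.chromosomes[ci].name or str(ci)
        if eligible.size == 0 and counts[ci] > 0:
            raise ValueError(f"empty QTL candidate pool on chromosome {name}")
        if eligible.size < counts[ci]:
            raise ValueError(
                f"chromosome {name}: only {eligible.size} eligible loci for {counts[ci]} QTL")
        chosen.append(rng.choice(eligible, counts[ci], replace=False))
    return np.sort(np.concatenate(chosen))


def assign_effect_signs(magnitudes: np.ndarray, scenario: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Apply a coupling/repulsion scenario's sign pattern to |effect| draws.

    Scenario 1: all positive.  2/3/5: each sign positive with probability
    2/3, 1/2, 1/3 (genome-wide Bernoulli draws).  4: strict alternation
    along map order across chromosome boundaries, first sign random.
    Magnitudes must already be in QTL map order.
    """
    mags = np.abs(np.asarray(magnitudes, dtype=float))
    n = mags.size
    if scenario == 1:
        signs = np.ones(n)
    elif scenario in _SIGN_PROB:
        signs = np.where(rng.random(n) < _SIGN_PROB[scenario], 1.0, -1.0)
    elif scenario == 4:
        first = 1.0 if rng.random() < 0.5 else -1.0
        signs = first * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    else:
        raise ValueError(f"unknown coupling/repulsion scenario {scenario!r}")
    return mags * signs


def genetic_values(population: Population, arch: TraitArchitecture) -> np.ndarray:
    """g = sum_i a_i * dose_i for every individual."""
    return population.doses(arch.qtl_idx).astype(float) @ arch.effects


def standardize_variance(effects: np.ndarray, population: Population,
                         qtl_idx: np.ndarray) -> np.ndarray:
    """Divide effects by sqrt(varA) of the reference population (varA -> 1)."""
    g = population.doses(np.asarray(qtl_idx, dtype=int)).astype(float) @ np.asarray(effects, float)
    var_a = float(np.var(g))
    if var_a <= 1e-12:  # exactly fixed, or fixed up to rounding noise
        raise ValueError("no genetic variance to standardize")
    return np.asarray(effects, dtype=float) / math.sqrt(var_a)


def phenotype(population: Population, arch: TraitArchitecture,
              model: PhenotypeModel, rng: np.random.Generator) -> np.ndarray:
    """y = g + e with e ~ Normal(0, sigma2_e) i.i.d."""
    g = genetic_values(population, arch)
    if model.sigma2_e == 0:
        return g
    return g + rng.normal(0.0, math.sqrt(model.sigma2_e), size=population.n)
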