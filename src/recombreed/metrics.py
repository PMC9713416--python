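"""Per-cycle response variables.

All variances are population variances (divisor n): these are parameters
of the simulated population, not sample estimates.  Allele frequencies are
computed from genotype doses over individuals, so fully inbred populations
give line frequencies — matching the Hardy–Weinberg convention of the
genic-variance formula they feed.
"""

from __future__ import annotations

import numpy as np

from .populations import FounderSet, Population
from .traits import TraitArchitecture, genetic_values


def additive_variance(population: Population, arch: TraitArchitecture) -> float:
    """Variance (divisor n) of true genetic values."""
    return float(np.var(genetic_values(population, arch)))


def genic_variance(population: Population, arch: TraitArchitecture) -> float:
    """Expected additive variance under HWE and linkage equilibrium.

    sum_i 2 p_i (1-p_i) a_i^2, applied regardless of actual inbreeding; a
    fully inbred population at linkage equilibrium therefore has
    additive variance = 2 x genic variance.
    """
    p = population.allele_freq(arch.qtl_idx)
    return float(np.sum(2.0 * p * (1.0 - p) * arch.effects**2))


def bulmer_effect(var_a: float, genic_var_a: float) -> float:
    """varA / (2 genicVarA) for inbred populations; < 1 flags repulsion LD."""
    if genic_var_a <= 0:
        return float("nan")
    return var_a / (2.0 * genic_var_a)


def genetic_gain(mean_g: np.ndarray, cycles: np.ndarray) -> np.ndarray:
    """Gain per cycle: mean genetic value minus the cycle-1 mean (gain(1)=0)."""
    mean_g = np.asarray(mean_g, dtype=float)
    cycles = np.asarray(cycles)
    ref = np.where(cycles == 1)[0]
    if ref.size == 0:
        raise ValueError("cycle-1 record required to anchor genetic gain")
    return mean_g - mean_g[ref[0]]


def effect_terciles(effects: np.ndarray) -> list[np.ndarray]:
    """Indices of QTL split by |effect| into small/medium/large terciles.

    Remainders go to the lower terciles, so 200 QTL split 67/67/66.
    """
    n = effects.size
    if n < 3:
        raise ValueError("terciles need at least 3 QTL")
    order = np.argsort(np.abs(effects), kind="stable")
    q, r = divmod(n, 3)
    sizes = [q + (1 if r >= 1 else 0), q + (1 if r >= 2 else 0), q]
    edges = np.cumsum([0] + sizes)
    return [order[edges[i]: edges[i + 1]] for i in range(3)]


def qtl_fixation(population: Population, arch: TraitArchitecture) -> dict:
    """Fraction of QTL fixed (p in {0,1}) per |effect| tercile.

    Each tercile reports the total fixed fraction and its split by whether
    the fixed allele is the favorable one (allele 1 for a > 0, allele 0
    for a < 0).
    """
    p = population.allele_freq(arch.qtl_idx)
    a = arch.effects
    fixed = (p == 0.0) | (p == 1.0)
    fixed_fav = ((p == 1.0) & (a > 0)) | ((p == 0.0) & (a < 0))
    out = {}
    for name, idx in zip(("small", "medium", "large"), effect_terciles(a)):
        out[name] = {
            "fixed": float(fixed[idx].mean()),
            "fixed_favorable": float(fixed_fav[idx].mean()),
            "fixed_unfavorable": float((fixed[idx] & ~fixed_fav[idx]).mean()),
        }
    return out


def allele_frequency_change(pop_t: Population, pop_0: Population,
                            arch: TraitArchitecture) -> dict:
    """Mean change in favorable-allele frequency per |effect| tercile.

    Negative values mean the unfavorable allele gained frequency
    (hitchhiking on linked selected QTL).
    """
    if pop_t.n_loci != pop_0.n_loci:
        raise ValueError("populations must share loci")
    fav_sign = np.where(arch.effects >= 0, 1.0, -1.0)

    def fav_freq(pop):
        p = pop.allele_freq(arch.qtl_idx)
        return np.where(fav_sign > 0, p, 1.0 - p)

    dq = fav_freq(pop_t) - fav_freq(pop_0)
    return {name: float(dq[idx].mean())
            for name, idx in zip(("small", "medium", "large"), effect_terciles(arch.effects))}


def neighboring_repulsion_fraction(founders: FounderSet,
                                   qtl_idx: np.ndarray | None = None) -> float:
    """Fraction of adjacent within-chromosome locus pairs in repulsion.

    A pair is in repulsion when the founder-genotype correlation between
    the two loci's minor-allele indicators is negative; "minor" keeps the
    full-founder-set designation (carried through biparental derivation).
    Zero-variance columns and cross-chromosome pairs are excluded.
    """
    ind = founders.minor_indicator().astype(float)
    if qtl_idx is not None:
        mask = np.zeros(founders.n_loci, dtype=bool)
        mask[np.asarray(qtl_idx, dtype=int)] = True
    chrom = founders.map.chrom_of_locus()
    neg = tot = 0
    centered = ind - ind.mean(axis=0, keepdims=True)
    var = centered.var(axis=0)
    for ci in range(founders.map.n_chrom):
        sel = chrom == ci
        if qtl_idx is not None:
            sel &= mask
        cols = np.where(sel)[0]
        if cols.size < 2:
            continue
        a, b = cols[:-1], cols[1:]
        ok = (var[a] > 0) & (var[b] > 0)
        cov = (centered[:, a[ok]] * centered[:, b[ok]]).sum(axis=0)
        neg += int((cov < 0).sum())
        tot += int(ok.sum())
    if tot == 0:
        raise ValueError("no adjacent polymorphic locus pairs to evaluate")
    return neg / tot
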