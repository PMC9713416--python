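"""Meiosis: crossover placement with interference, gametes, crosses, DHs.

Crossovers are modelled as a stationary gamma renewal process on the
four-strand bundle with shape ``GAMMA_SHAPE`` = 2.63 and chiasma intensity
2 per Morgan, thinned by 1/2 per gamete.  This is the standard process-
level approximation to the Kosambi map function: it reproduces Kosambi
two-point recombination fractions (r = tanh(2d)/2) to within simulation
error at map distances up to ~0.5 M, while giving the expected one
crossover per Morgan per gamete.  No obligate crossover is enforced.
Chromosomes assort independently.
"""

from __future__ import annotations

import numpy as np

from .genmap import GeneticMap
from .populations import Population

#: Gamma shape of the chiasma renewal process (Kosambi-level interference).
GAMMA_SHAPE = 2.63

#: Morgans of renewal-process burn-in before the chromosome start, enough
#: for the process to reach stationarity at interarrival mean 0.5 M.
_STATIONARY_BURNIN = 4.0


def sample_crossovers(length: float, n_gametes: int, rng: np.random.Generator,
                      shape: float = GAMMA_SHAPE) -> list[np.ndarray]:
    """Crossover positions for ``n_gametes`` independent gametes.

    Chiasma interarrivals on the bundle are Gamma(shape, scale=0.5/shape)
    (mean 0.5 M); each chiasma is resolved into a given gamete with
    probability 1/2, so the gamete sees one crossover per Morgan in
    expectation.
    """
    if length <= 0:
        return [np.empty(0) for _ in range(n_gametes)]
    total = length + _STATIONARY_BURNIN
    n_exp = total / 0.5
    k = int(n_exp + 6.0 * np.sqrt(n_exp) + 12)
    iv = rng.gamma(shape, 0.5 / shape, size=(n_gametes, k))
    pos = np.cumsum(iv, axis=1) - _STATIONARY_BURNIN
    # extend the rare rows whose events do not yet cover the chromosome
    short = np.where(pos[:, -1] < length)[0]
    extras: dict[int, np.ndarray] = {}
    for i in short:
        tail = [pos[i, -1]]
        while tail[-1] < length:
            tail.append(tail[-1] + rng.gamma(shape, 0.5 / shape))
        extras[i] = np.asarray(tail[1:])
    keep = (pos > 0) & (pos < length) & (rng.random((n_gametes, k)) < 0.5)
    out = []
    for i in range(n_gametes):
        p = pos[i, keep[i]]
        if i in extras:
            e = extras[i]
            e = e[(e > 0) & (e < length)]
            e = e[rng.random(e.size) < 0.5]
            p = np.concatenate([p, e])
        out.append(p)
    return out


def simulate_gametes(parents: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent.

    ``parents`` is (k, 2, n_loci); returns (k, n_loci).  Each gamete starts
    from a fair-coin choice of haplotype and switches at every crossover.
    """
    parents = np.asarray(parents)
    k = parents.shape[0]
    gametes = np.empty((k, gmap.n_loci), dtype=np.uint8)
    for ci, chrom in enumerate(gmap.chromosomes):
        sl = gmap.chrom_slice(ci)
        pos = chrom.positions
        cos = sample_crossovers(chrom.length, k, rng)
        start = rng.integers(0, 2, size=k)
        col = np.arange(pos.size)
        for i in range(k):
            c = cos[i]
            if c.size:
                hap_idx = (start[i] + np.searchsorted(c, pos)) & 1
                gametes[i, sl] = parents[i, :, sl][hap_idx, col]
            else:
                gametes[i, sl] = parents[i, start[i], sl]
    return gametes


def simulate_gamete(parent: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Single gamete from one individual's two haplotypes (2, n_loci)."""
    return simulate_gametes(np.asarray(parent)[None], gmap, rng)[0]


def make_crosses(pop: Population, mothers: np.ndarray, fathers: np.ndarray,
                 gmap: GeneticMap, rng: np.random.Generator) -> Population:
    """F1 progeny of the given parent pairings, one per pairing."""
    egg = simulate_gametes(pop.haplotypes[mothers], gmap, rng)
    sperm = simulate_gametes(pop.haplotypes[fathers], gmap, rng)
    return Population(np.stack([egg, sperm], axis=1))


def make_cross(pop: Population, mother: int, father: int,
               gmap: GeneticMap, rng: np.random.Generator) -> Population:
    """A single F1 individual from one cross."""
    return make_crosses(pop, np.array([mother]), np.array([father]), gmap, rng)


def make_dhs(f1s: Population, gmap: GeneticMap, rng: np.random.Generator) -> Population:
    """Doubled haploids: one recombinant gamete per F1, duplicated."""
    gam = simulate_gametes(f1s.haplotypes, gmap, rng)
    return Population(np.repeat(gam[:, None, :], 2, axis=1))


def make_dh(f1: Population, gmap: GeneticMap, rng: np.random.Generator) -> Population:
    return make_dhs(f1, gmap, rng)


def random_pairings(n_parents: int, n_crosses: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random parent pairs with replacement across crosses, no selfing."""
    if n_parents < 2:
        raise ValueError("need at least 2 parents to cross")
    mothers = rng.integers(0, n_parents, size=n_crosses)
    shift = rng.integers(1, n_parents, size=n_crosses)
    fathers = (mothers + shift) % n_parents
    return mothers, fathers
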