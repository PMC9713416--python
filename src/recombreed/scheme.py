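"""Breeding scheme: phenotypic burn-in and the 10-cycle genomic-selection loop.

Full-founder programmes burn in with 10 cycles of phenotypic selection
(400 random crosses -> 400 DHs, advance the top 80 = 20% intensity; the
very first crosses are among the founders, and in the final burn-in cycle
all 400 DHs become the training population).  Biparental programmes burn
in for a single unselected cycle.  The trait is re-standardised to unit
additive variance on the TP, the recombination treatment is applied to
the map, and genomic selection proceeds: refit RRBLUP on the TP each
cycle, predict the 400 DH candidates, advance the top 20 (5%) as parents,
phenotype the top 160 (40%) into the TP and drop the 80 lowest-EBV TP
members — the TP grows by 80 per cycle, from 400 to 1200 at cycle 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import founders as founders_mod
from . import metrics
from .genmap import GeneticMap, MapTreatment, scale_map
from .meiosis import make_crosses, make_dhs, random_pairings
from .populations import FounderSet, Population
from .prediction import fit_rrblup, predict_ebv, prediction_accuracy
from .traits import (PhenotypeModel, TraitArchitecture, assign_effect_signs,
                     assign_qtl, genetic_values, phenotype, qtl_counts_per_chrom,
                     sample_dv_pool, sample_snpchip, standardize_variance)


@dataclass
class SimConfig:
    """One cell of the factorial design plus run sizes and seeds."""

    founder_mode: str = "full"          # "full" | "biparental"
    n_qtl_per_chrom: int = 200
    d_group_qtl: int | None = None      # e.g. 60 on the D subgenome
    h2: float = 0.8
    map_type: str = "WT"
    scale: float = 1.0
    scenario: int = 1
    qtl_type: str = "R"                 # "R" | "DV"
    predictor: str = "GW"               # "GW" | "CV"
    n_burnin: int | None = None         # default: 10 full / 1 biparental
    n_gs_cycles: int = 10
    n_crosses: int = 400
    n_burnin_parents: int = 80
    n_gs_parents: int = 20
    n_tp_add: int = 160
    tp_rule: str = "net80"              # "net80" | "literal20"
    marker_per_bin: int = 10
    seed: int = 0
    # synthetic founder parameters, used when no FounderSet is supplied
    n_founders: int = 26
    n_chrom: int = 21
    mean_length: float = 1.22
    snp_density: int = 2000
    coupling_target: float = 0.33

    def treatment(self) -> MapTreatment:
        scale = 1.0 if self.map_type == "WT" else float(self.scale)
        return MapTreatment(self.map_type, scale)


@dataclass
class CycleRecord:
    """Response variables for one GS cycle (cycle 0 = post-burn-in baseline)."""

    cycle: int
    mean_g: float
    var_a: float
    genic_var_a: float
    bulmer: float
    accuracy: float
    tp_size: int
    n_candidates: int
    fixation_small: float
    fixation_medium: float
    fixation_large: float
    daf_small: float
    daf_medium: float
    daf_large: float
    gain: float = float("nan")


@dataclass
class SchemeState:
    """Mutable state threaded through the GS loop."""

    cycle: int
    parents: Population
    candidates: Population
    tp: Population
    tp_phenotypes: np.ndarray
    records: list = field(default_factory=list)


def _select_top(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties broken by position (stable)."""
    return np.argsort(-values, kind="stable")[:k]


def burn_in(founders: FounderSet, arch: TraitArchitecture, model: PhenotypeModel,
            config: SimConfig, gmap: GeneticMap, rng: np.random.Generator) -> Population:
    """Phenotypic-selection burn-in; returns the 400-DH training population."""
    n_cycles = config.n_burnin
    if n_cycles is None:
        n_cycles = 10 if config.founder_mode == "full" else 1
    parents = founders.to_population()
    if parents.n < 2:
        raise ValueError("burn-in needs at least 2 parents")
    dhs = None
    for c in range(n_cycles):
        mothers, fathers = random_pairings(parents.n, config.n_crosses, rng)
        f1 = make_crosses(parents, mothers, fathers, gmap, rng)
        dhs = make_dhs(f1, gmap, rng)
        last = c == n_cycles - 1
        if config.founder_mode == "full" and not last:
            y = phenotype(dhs, arch, model, rng)
            parents = dhs.subset(_select_top(y, config.n_burnin_parents))
    return dhs


def gs_cycle(state: SchemeState, gs_map: GeneticMap, arch: TraitArchitecture,
             model: PhenotypeModel, predictor_idx: np.ndarray, pop0: Population,
             config: SimConfig, rng: np.random.Generator) -> SchemeState:
    """One cycle of genomic selection, updating candidates, parents and TP."""
    state.cycle += 1
    mothers, fathers = random_pairings(state.parents.n, config.n_crosses, rng)
    f1 = make_crosses(state.parents, mothers, fathers, gs_map, rng)
    cand = make_dhs(f1, gs_map, rng)

    fitted = fit_rrblup(state.tp.doses(predictor_idx), state.tp_phenotypes,
                        fallback_h2=config.h2)
    ebv = predict_ebv(fitted, cand.doses(predictor_idx))
    state.parents = cand.subset(_select_top(ebv, config.n_gs_parents))

    top = _select_top(ebv, config.n_tp_add)
    newly = cand.subset(top)
    state.tp = state.tp.concat(newly)
    state.tp_phenotypes = np.concatenate(
        [state.tp_phenotypes, phenotype(newly, arch, model, rng)])
    tp_ebv = predict_ebv(fitted, state.tp.doses(predictor_idx))
    n_drop = (80 if config.tp_rule == "net80"
              else int(np.floor(0.2 * state.tp.n)))
    drop = np.argsort(tp_ebv, kind="stable")[:n_drop]
    keep = np.setdiff1d(np.arange(state.tp.n), drop)
    state.tp = state.tp.subset(keep)
    state.tp_phenotypes = state.tp_phenotypes[keep]

    state.candidates = cand
    state.records.append(_record(state, cand, ebv, arch, pop0))
    return state


def _record(state: SchemeState, cand: Population, ebv: np.ndarray,
            arch: TraitArchitecture, pop0: Population) -> CycleRecord:
    g = genetic_values(cand, arch)
    var_a = float(np.var(g))
    genic = metrics.genic_variance(cand, arch)
    fix = metrics.qtl_fixation(cand, arch)
    daf = metrics.allele_frequency_change(cand, pop0, arch)
    return CycleRecord(
        cycle=state.cycle,
        mean_g=float(g.mean()),
        var_a=var_a,
        genic_var_a=genic,
        bulmer=metrics.bulmer_effect(var_a, genic),
        accuracy=prediction_accuracy(ebv, g),
        tp_size=state.tp.n,
        n_candidates=cand.n,
        fixation_small=fix["small"]["fixed"],
        fixation_medium=fix["medium"]["fixed"],
        fixation_large=fix["large"]["fixed"],
        daf_small=daf["small"],
        daf_medium=daf["medium"],
        daf_large=daf["large"],
    )


def run_replicate(config: SimConfig, founders: FounderSet | None = None) -> list[CycleRecord]:
    """Execute one complete simulation replicate.

    Founders -> marker panel and QTL -> scenario effects (standardised on
    the founders) -> burn-in -> re-standardisation on the TP -> map
    treatment -> GS cycles.  Returns one record per cycle including the
    cycle-0 post-burn-in baseline (n_gs_cycles + 1 records).  Identical
    config and seed give bit-identical records.
    """
    rng = np.random.default_rng(config.seed)
    try:
        if founders is None:
            founders = founders_mod.generate_founders(
                config.n_founders, config.n_chrom, config.mean_length,
                config.snp_density, config.coupling_target,
                seed=int(rng.integers(2**31)))
        if config.founder_mode == "biparental":
            if config.qtl_type == "DV":
                raise ValueError("deleterious-variant QTL are not evaluated in biparental mode")
            founders = founders_mod.derive_biparental(founders)
        elif config.founder_mode != "full":
            raise ValueError(f"unknown founder_mode {config.founder_mode!r}")
    except ValueError as err:
        raise ValueError(f"[founders] {err}") from err

    try:
        markers = sample_snpchip(founders, config.marker_per_bin, rng)
        dv_pool = (sample_dv_pool(founders.annotations, rng)
                   if config.qtl_type == "DV" else None)
        counts = qtl_counts_per_chrom(founders, config.n_qtl_per_chrom, config.d_group_qtl)
        qtl = assign_qtl(founders, config.qtl_type, counts, markers, rng, dv_pool)
        magnitudes = np.abs(rng.standard_normal(qtl.size))
        effects = assign_effect_signs(magnitudes, config.scenario, rng)
        effects = standardize_variance(effects, founders.to_population(), qtl)
        arch = TraitArchitecture(qtl, effects, config.qtl_type, config.scenario)
        model = PhenotypeModel.from_heritability(config.h2)
    except ValueError as err:
        raise ValueError(f"[trait] {err}") from err

    wt_map = founders.map
    try:
        tp = burn_in(founders, arch, model, config, wt_map, rng)
        arch = arch.with_effects(standardize_variance(arch.effects, tp, arch.qtl_idx))
        model = PhenotypeModel.from_heritability(config.h2)
        tp_y = phenotype(tp, arch, model, rng)
    except ValueError as err:
        raise ValueError(f"[burn-in] {err}") from err

    gs_map = scale_map(wt_map, config.treatment())
    predictor_idx = markers if config.predictor == "GW" else arch.qtl_idx
    pop0 = tp

    # cycle 0: the TP is also the first candidate population
    state = SchemeState(cycle=0, parents=tp, candidates=tp, tp=tp, tp_phenotypes=tp_y)
    try:
        fitted = fit_rrblup(tp.doses(predictor_idx), tp_y, fallback_h2=config.h2)
        ebv0 = predict_ebv(fitted, tp.doses(predictor_idx))
        state.parents = tp.subset(_select_top(ebv0, config.n_gs_parents))
        state.records.append(_record(state, tp, ebv0, arch, pop0))
        for _ in range(config.n_gs_cycles):
            state = gs_cycle(state, gs_map, arch, model, predictor_idx, pop0, config, rng)
    except ValueError as err:
        raise ValueError(f"[gs-cycle {state.cycle}] {err}") from err

    mean_g = np.array([r.mean_g for r in state.records])
    cycles = np.array([r.cycle for r in state.records])
    gains = metrics.genetic_gain(mean_g, cycles)
    for r, gain in zip(state.records, gains):
        r.gain = float(gain)
    return state.records


def records_to_frame(records: list[CycleRecord], **extra) -> pd.DataFrame:
    """Long-format table of cycle records, with optional constant columns."""
    df = pd.DataFrame([asdict(r) for r in records])
    for key, val in extra.items():
        df[key] = val
    return df
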