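"""Pre-configured reduced-scale studies of the recombination treatments.

These functions run the simulator at a desk scale (5 chromosomes, 40
QTL per chromosome, a few tens of replicates) chosen so the directional
effects of recombination treatments — variance retention under 20x map
scaling, loss of genome-wide prediction accuracy, faster fixation of
oligogenic traits — are measurable in minutes rather than the
full-factorial compute of a complete study.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .founders import generate_founders
from .metrics import bulmer_effect, genic_variance
from .populations import Population
from .scheme import SimConfig, burn_in, records_to_frame, run_replicate
from .traits import (PhenotypeModel, TraitArchitecture, assign_effect_signs,
                     assign_qtl, genetic_values, sample_snpchip,
                     standardize_variance)

#: Reduced-scale founder panel: 26 inbred lines, 5 chromosomes of ~1.22 M,
#: 600 SNPs per chromosome, wildtype coupling baseline.
FOUNDER_KW = dict(n_founders=26, n_chrom=5, mean_length=1.22,
                  snp_density=600, coupling_target=0.33)

#: Reduced-scale trait/scheme settings: 40 QTL per chromosome stands in
#: for the polygenic (200-QTL) architecture on the smaller genome.
SIM_KW = dict(n_qtl_per_chrom=40, h2=0.8, scenario=4, qtl_type="R",
              marker_per_bin=2, **FOUNDER_KW)


def _contrast_settings():
    return {
        "cv_wt": dict(predictor="CV", map_type="WT", scale=1),
        "cv_20x": dict(predictor="CV", map_type="Chromosome", scale=20),
        "gw_wt": dict(predictor="GW", map_type="WT", scale=1),
        "gw_20x": dict(predictor="GW", map_type="Chromosome", scale=20),
        "cv_wt_oligogenic": dict(predictor="CV", map_type="WT", scale=1,
                                 n_qtl_per_chrom=2),
    }


def recombination_contrast_study(n_replicates: int = 20, seed: int = 0,
                                 log=None) -> pd.DataFrame:
    """WT vs 20x-Chromosome maps under repulsion (scenario 4), H2 = 0.8.

    Runs five paired settings per replicate (CV and GW predictors under
    both maps, plus an oligogenic CV baseline), sharing the founder panel
    within a replicate.  Returns the per-cycle records of every run.
    """
    frames = []
    for rep in range(n_replicates):
        founders = generate_founders(seed=(seed * 1009 + rep) % (2**31), **FOUNDER_KW)
        for name, over in _contrast_settings().items():
            salt = zlib.crc32(name.encode()) % 997
            cfg = SimConfig(**{**SIM_KW, **over},
                            seed=(seed * 9176 + rep * 31 + salt) % (2**31))
            try:
                recs = run_replicate(cfg, founders=founders)
                frames.append(records_to_frame(recs, setting=name, replicate=rep,
                                               burnin_fixed=False))
            except ValueError as err:
                if "no genetic variance" not in str(err):
                    raise
                # every QTL fixed during burn-in (oligogenic architectures do
                # this): record the terminal state rather than losing the run
                frames.append(pd.DataFrame(dict(
                    cycle=range(cfg.n_gs_cycles + 1), mean_g=np.nan,
                    var_a=0.0, genic_var_a=0.0, bulmer=np.nan,
                    accuracy=np.nan, tp_size=400, n_candidates=400,
                    fixation_small=1.0, fixation_medium=1.0, fixation_large=1.0,
                    daf_small=np.nan, daf_medium=np.nan, daf_large=np.nan,
                    gain=np.nan, setting=name, replicate=rep, burnin_fixed=True)))
        if log:
            log(f"replicate {rep + 1}/{n_replicates} done")
    return pd.concat(frames, ignore_index=True)


def contrast_summary(results: pd.DataFrame) -> dict:
    """Replicate-mean summaries of the directional contrasts."""
    def mean_at(setting, cycle, col):
        sub = results[(results.setting == setting) & (results.cycle == cycle)]
        return float(np.nanmean(sub[col]))

    fix_cols = ["fixation_small", "fixation_medium", "fixation_large"]
    return {
        "cycle10_varA_wt_cv": mean_at("cv_wt", 10, "var_a"),
        "cycle10_varA_20x_cv": mean_at("cv_20x", 10, "var_a"),
        "cycle6_accuracy_wt_gw": mean_at("gw_wt", 6, "accuracy"),
        "cycle6_accuracy_20x_gw": mean_at("gw_20x", 6, "accuracy"),
        "cycle10_gain_wt_cv": mean_at("cv_wt", 10, "gain"),
        "cycle10_gain_20x_cv": mean_at("cv_20x", 10, "gain"),
        "cycle6_fixation_polygenic": float(np.mean(
            [mean_at("cv_wt", 6, c) for c in fix_cols])),
        "cycle6_fixation_oligogenic": float(np.mean(
            [mean_at("cv_wt_oligogenic", 6, c) for c in fix_cols])),
    }


def linkage_equilibrium_bulmer(n_individuals: int = 10000, n_qtl: int = 100,
                               seed: int = 0) -> float:
    """Bulmer ratio varA/(2 genicVarA) of a DH population simulated at
    linkage equilibrium (independent loci); its expectation is 1."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_qtl)
    geno = (rng.random((n_individuals, n_qtl)) < p).astype(np.uint8)
    pop = Population.from_inbred(geno)
    arch = TraitArchitecture(np.arange(n_qtl), rng.standard_normal(n_qtl))
    var_a = float(np.var(genetic_values(pop, arch)))
    return bulmer_effect(var_a, genic_variance(pop, arch))


def burnin_bulmer_by_scenario(scenarios=(1, 4), n_replicates: int = 20,
                              seed: int = 0, log=None) -> pd.DataFrame:
    """Bulmer ratio of post-burn-in training populations per sign scenario.

    Scenario 4 (strict alternation: adjacent QTL in repulsion) should show
    a stronger Bulmer effect (lower ratio) than scenario 1 (full coupling).
    The Bulmer ratio is invariant to effect rescaling, so it is computed
    before the post-burn-in re-standardisation.
    """
    rows = []
    for rep in range(n_replicates):
        founders = generate_founders(seed=(seed * 2003 + rep) % (2**31), **FOUNDER_KW)
        rng_shared = np.random.default_rng((seed * 517 + rep) % (2**31))
        markers = sample_snpchip(founders, 2, rng_shared)
        qtl = assign_qtl(founders, "R", 40, markers, rng_shared)
        mags = np.abs(rng_shared.standard_normal(qtl.size))
        for scen in scenarios:
            rng = np.random.default_rng((seed * 771 + rep * 13 + scen) % (2**31))
            effects = assign_effect_signs(mags, scen, rng)
            effects = standardize_variance(effects, founders.to_population(), qtl)
            arch = TraitArchitecture(qtl, effects, "R", scen)
            model = PhenotypeModel.from_heritability(0.8)
            cfg = SimConfig(**{**SIM_KW, "scenario": scen}, seed=0)
            tp = burn_in(founders, arch, model, cfg, founders.map, rng)
            var_a = float(np.var(genetic_values(tp, arch)))
            rows.append(dict(replicate=rep, scenario=scen,
                             bulmer=bulmer_effect(var_a, genic_variance(tp, arch))))
        if log:
            log(f"burn-in replicate {rep + 1}/{n_replicates} done")
    return pd.DataFrame(rows)


def crossover_calibration(lengths=(0.5, 1.22, 5.02, 24.4), n_gametes: int = 20000,
                          seed: int = 0) -> pd.DataFrame:
    """Mean crossover count per gamete against map length in Morgans."""
    from .meiosis import sample_crossovers

    rng = np.random.default_rng(seed)
    rows = []
    for length in lengths:
        cos = sample_crossovers(length, n_gametes, rng)
        rows.append(dict(length=length,
                         mean_crossovers=float(np.mean([c.size for c in cos]))))
    return pd.DataFrame(rows)
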