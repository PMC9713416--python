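"""Factorial simulation experiments and their statistical summary.

``run_grid`` executes every cell of a factorial design for a number of
replicates, with deterministic per-cell seeds, and returns a long-format
table (one row per setting x replicate x cycle).  ``variance_decomposition``
fits the all-main-effects + first-order-interaction linear model with a
replicate block term and reports each term's share of the total sum of
squares; under the balanced designs used here this coincides with the
random-intercept mixed model's decomposition.  ``marginal_means`` averages
cell means over the balanced grid of the other factors.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import founders as founders_mod
from .scheme import SimConfig, records_to_frame, run_replicate

#: Factor columns of the canonical design, in model order.
FACTORS = ("founder_mode", "n_qtl", "h2", "scale", "map_type", "qtl_type",
           "scenario", "predictor")


@dataclass
class FactorialDesign:
    """Factor levels of the simulation experiment.

    The canonical design crosses every factor fully, with biparental runs
    restricted to scenarios 3 and 4; the default levels give 672 cells.
    Biparental cells with deleterious-variant QTL are counted in the design
    but are not evaluable (the biparental panel loses most annotated
    polymorphic sites) — ``settings(evaluable_only=True)`` drops them, and
    the grid runner logs and skips them.
    """

    founder_mode: tuple = ("full", "biparental")
    n_qtl: tuple = (2, 200)
    h2: tuple = (0.2, 0.8)
    scale: tuple = (2, 20)
    map_type: tuple = ("WT", "Pericentromere", "Chromosome")
    qtl_type: tuple = ("R", "DV")
    scenario: tuple = (1, 2, 3, 4, 5)
    biparental_scenarios: tuple = (3, 4)
    predictor: tuple = ("GW", "CV")

    def settings(self, evaluable_only: bool = False) -> list[dict]:
        out = []
        for fm, nq, h2, sc, mt, qt, sn, pr in itertools.product(
                self.founder_mode, self.n_qtl, self.h2, self.scale,
                self.map_type, self.qtl_type, self.scenario, self.predictor):
            if fm == "biparental" and sn not in self.biparental_scenarios:
                continue
            if evaluable_only and fm == "biparental" and qt == "DV":
                continue
            out.append(dict(founder_mode=fm, n_qtl=nq, h2=h2, scale=sc,
                            map_type=mt, qtl_type=qt, scenario=sn, predictor=pr))
        return out

    @property
    def n_settings(self) -> int:
        return len(self.settings())


def full_founder_design() -> FactorialDesign:
    """The canonical 672-setting design."""
    return FactorialDesign()


def setting_seed(base_seed: int, setting: dict, replicate: int) -> int:
    """Deterministic sub-2^31 seed for one (setting, replicate) cell."""
    key = json.dumps({**setting, "replicate": replicate}, sort_keys=True)
    return (zlib.crc32(key.encode()) ^ (base_seed * 0x9E3779B1)) % (2**31)


def _cell_config(setting: dict, seed: int, sim_kwargs: dict) -> SimConfig:
    kw = dict(sim_kwargs)
    d_group_qtl = kw.pop("d_group_qtl_when_polygenic", None)
    cfg = SimConfig(
        founder_mode=setting["founder_mode"],
        n_qtl_per_chrom=setting["n_qtl"],
        d_group_qtl=d_group_qtl if setting["n_qtl"] > 2 else None,
        h2=setting["h2"],
        map_type=setting["map_type"],
        scale=setting["scale"],
        scenario=setting["scenario"],
        qtl_type=setting["qtl_type"],
        predictor=setting["predictor"],
        seed=seed,
        **kw,
    )
    return cfg


def run_cell(setting: dict, replicate: int, base_seed: int,
             sim_kwargs: dict | None = None, founders=None) -> pd.DataFrame:
    seed = setting_seed(base_seed, setting, replicate)
    cfg = _cell_config(setting, seed, sim_kwargs or {})
    records = run_replicate(cfg, founders=founders)
    return records_to_frame(records, replicate=replicate, **setting)


def run_grid(design: FactorialDesign, base_seed: int, n_replicates: int,
             sim_kwargs: dict | None = None, shared_founders: bool = True,
             founder_kwargs: dict | None = None, out_dir=None,
             resume: bool = True, log=None) -> pd.DataFrame:
    """Run every design cell for ``n_replicates`` replicates.

    Replicate seeds are derived from ``base_seed`` and the setting, so the
    table is identical however the cells are scheduled.  With
    ``shared_founders`` a synthetic founder set is generated once per
    replicate index and reused across settings (paired comparisons, as
    when all settings start from the same real founder panel).  If
    ``out_dir`` is given each cell is written to its own CSV and completed
    cells are skipped on resume.
    """
    sim_kwargs = dict(sim_kwargs or {})
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    founder_cache: dict[int, object] = {}
    fk = founder_kwargs or {}
    frames = []
    for si, setting in enumerate(design.settings()):
        for rep in range(n_replicates):
            part = (out_dir / f"cell_{si:04d}_rep{rep:03d}.csv") if out_dir else None
            if part is not None and resume and part.exists():
                frames.append(pd.read_csv(part))
                continue
            founders = None
            if shared_founders:
                if rep not in founder_cache:
                    founder_cache[rep] = founders_mod.generate_founders(
                        seed=(base_seed * 1000003 + rep) % (2**31), **fk)
                founders = founder_cache[rep]
            try:
                df = run_cell(setting, rep, base_seed, sim_kwargs, founders)
            except ValueError as err:
                if log:
                    log(f"WARNING: cell {si} replicate {rep} failed and is excluded: {err}")
                continue
            if part is not None:
                df.to_csv(part, index=False)
            frames.append(df)
        if log:
            log(f"setting {si + 1}/{design.n_settings} done")
    if not frames:
        raise ValueError("no cells completed")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# statistical summary


def variance_decomposition(results: pd.DataFrame, response: str, cycle: int,
                           factors=None, replicate_col: str = "replicate") -> pd.DataFrame:
    """Share of total sum of squares per model term, in percent.

    Fits ``response ~ (sum of factors)**2 + C(replicate)`` on the records
    of one cycle with Type-II sums of squares (orthogonal under balance).
    Factors with a single observed level are dropped from the model.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = results[results["cycle"] == cycle].copy()
    if df.empty:
        raise ValueError(f"no records at cycle {cycle}")
    factors = [f for f in (factors or FACTORS) if f in df.columns]
    factors = [f for f in factors if df[f].nunique() > 1]
    if not factors:
        raise ValueError("no factors with more than one level")
    df["_y"] = df[response].astype(float)
    terms = " + ".join(f"C({f})" for f in factors)
    formula = f"_y ~ ({terms})**2"
    if replicate_col in df.columns and df[replicate_col].nunique() > 1:
        formula += f" + C({replicate_col})"
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        dep = np.where(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())[0]
        aliased = sorted({model.exog_names[i].split("[")[0] for i in dep})
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    table = anova_lm(fit, typ=2)
    total = table["sum_sq"].sum()
    out = table.rename_axis("term").reset_index()
    out["share_pct"] = 100.0 * out["sum_sq"] / total
    out["term"] = (out["term"].str.replace(r"C\((\w+)\)", r"\1", regex=True)
                   .str.replace(":", " x "))
    return out[["term", "df", "sum_sq", "share_pct"]]


def marginal_means(results: pd.DataFrame, factor: str, response: str,
                   cycle: int | None = None, conditioning: dict | None = None,
                   factors=None) -> pd.Series:
    """Estimated marginal means of one factor: cell means averaged with
    equal weight over the balanced grid of the remaining factors."""
    df = results.copy()
    if cycle is not None:
        df = df[df["cycle"] == cycle]
    for key, val in (conditioning or {}).items():
        df = df[df[key].isin(val if isinstance(val, (list, tuple, set)) else [val])]
    if df.empty:
        raise ValueError("empty subset after conditioning")
    grid = [f for f in (factors or FACTORS) if f in df.columns]
    if factor not in grid:
        raise ValueError(f"unknown factor {factor!r}")
    cells = df.groupby(grid, observed=True)[response].mean().reset_index()
    return cells.groupby(factor, observed=True)[response].mean()


def percent_difference(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    return 100.0 * (value - reference) / reference
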