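"""Founder populations: synthetic generation and real-data reading.

The synthetic generator emulates the statistical structure of a diverse
inbred wheat founder panel: fully homozygous lines, 21 chromosomes
averaging 1.22 Morgans, a pericentromeric low-recombination window
enriched for putatively deleterious annotations, reduced annotation
density on the D subgenome, and an overall excess of coupling-phase
linkage among minor alleles.  Haplotypes are built from a first-order
autoregressive latent field per founder (block-wise local allele-sign
correlation); the AR coefficient is tuned by bisection until the realized
fraction of adjacent loci whose minor alleles are in repulsion matches a
requested target.
"""

from __future__ import annotations

import math
from io import StringIO

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import metrics
from .genmap import GeneticMap, make_chromosome
from .populations import FounderSet, VariantAnnotation, default_genome_groups

#: Default per-chromosome annotation fractions.  On a 2000-locus synthetic
#: chromosome these give a deleterious-variant candidate pool of
#: 0.9*0.33*2000 + 0.25*0.11*2000 ≈ 649 loci, the pool size typical of a
#: well-annotated wheat chromosome.
HIGH_IMPACT_FRACTION = 0.33
NONSYN_FRACTION = 0.11

#: D-subgenome annotation density multiplier (DV capacity ~60 vs ~200 QTL).
D_GENOME_FRACTION = 0.3

_UNKNOWN_CHROM = {"", "na", "nan", "un", "unknown", "none"}


def _simulate_panel(n_founders, lengths, n_raw, rho, seed):
    """Raw AR(1)-correlated inbred haplotypes; returns per-chrom (geno, pos)."""
    rng = np.random.default_rng(seed)
    out = []
    for L, m in zip(lengths, n_raw):
        pos = np.sort(rng.uniform(0.0, L, size=m))
        eps = rng.standard_normal((n_founders, m))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        c = math.sqrt(max(0.0, 1.0 - rho * rho))
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + c * eps[:, j]
        # per-locus target minor-allele frequency in (0.1, 0.5)
        thresh = norm.ppf(rng.uniform(0.1, 0.5, size=m))
        geno = (z >= thresh[None, :]).astype(np.uint8)  # 1 = common-side allele
        out.append((geno, pos))
    return out


def _assemble(panel, lengths, snp_density, rng):
    """Drop monomorphic loci, trim to the requested density, recode major=1."""
    genos, chroms = [], []
    for ci, ((geno, pos), L) in enumerate(zip(panel, lengths)):
        freq = geno.mean(axis=0)
        keep = np.where((freq > 0) & (freq < 1))[0]
        if keep.size > snp_density:
            keep = np.sort(rng.choice(keep, snp_density, replace=False))
        geno, pos = geno[:, keep], pos[keep]
        flip = geno.mean(axis=0) < 0.5
        geno = np.where(flip[None, :], 1 - geno, geno).astype(np.uint8)
        genos.append(geno)
        chroms.append(make_chromosome(pos, length=L, name=f"chr{ci + 1}"))
    return np.concatenate(genos, axis=1), GeneticMap(chroms)


def generate_founders(n_founders: int = 26, n_chrom: int = 21,
                      mean_length: float = 1.22, snp_density: int = 1200,
                      coupling_target: float = 0.33, seed: int = 0,
                      annotate: bool = True,
                      tolerance: float = 0.02, max_iter: int = 50) -> FounderSet:
    """Generate an inbred founder panel with tuned linkage phase.

    ``coupling_target`` is the desired fraction of adjacent locus pairs
    whose minor alleles are in repulsion (negative correlation across
    founders); it is matched empirically by bisection on the latent AR
    coefficient (at most ``max_iter`` panel draws).  The major allele is
    coded 1 at every locus and no locus is monomorphic.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if snp_density < 10:
        raise ValueError("need at least 10 SNPs per chromosome")
    if not 0.0 <= coupling_target <= 1.0:
        raise ValueError("coupling_target must be in [0, 1]")
    master = np.random.default_rng(seed)
    lengths = mean_length * master.uniform(0.85, 1.15, size=n_chrom)
    n_raw = [int(snp_density * 1.3) + 20] * n_chrom
    panel_seed = int(master.integers(2**31))
    trim_seed = int(master.integers(2**31))

    def realized(rho):
        panel = _simulate_panel(n_founders, lengths, n_raw, rho, panel_seed)
        geno, gmap = _assemble(panel, lengths, snp_density, np.random.default_rng(trim_seed))
        fs = FounderSet(geno, gmap, genome_group=default_genome_groups(n_chrom))
        return fs, metrics.neighboring_repulsion_fraction(fs)

    lo, hi = -0.999, 0.999  # repulsion fraction decreases in rho
    best, best_err = None, np.inf
    for _ in range(max_iter):
        rho = 0.5 * (lo + hi)
        fs, frac = realized(rho)
        err = abs(frac - coupling_target)
        if err < best_err:
            best, best_err = fs, err
        if err <= tolerance:
            break
        if frac > coupling_target:
            lo = rho  # too much repulsion -> increase coupling
        else:
            hi = rho
    founders = best
    if annotate:
        founders.annotations = annotate_deleterious(
            founders, seed=int(master.integers(2**31)))
    return founders


def annotate_deleterious(founders: FounderSet, pericentromere_enrichment: float = 3.0,
                         d_genome_fraction: float = D_GENOME_FRACTION, seed: int = 0,
                         high_fraction: float = HIGH_IMPACT_FRACTION,
                         nonsyn_fraction: float = NONSYN_FRACTION) -> VariantAnnotation:
    """Flag putatively deleterious loci, concentrated in the pericentromere.

    Per-Morgan flag density inside the centromere-spanning window exceeds
    the outside density by ~``pericentromere_enrichment``.  Chromosomes of
    the D subgenome carry ``d_genome_fraction`` times the flag counts, so
    deleterious-variant QTL capacity is correspondingly smaller there.
    Classes are mutually exclusive: high-impact flags are placed first,
    nonsynonymous flags only on unflagged loci.
    """
    if pericentromere_enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    gmap = founders.map
    high = np.zeros(gmap.n_loci, dtype=bool)
    nonsyn = np.zeros(gmap.n_loci, dtype=bool)
    for ci, chrom in enumerate(gmap.chromosomes):
        lo, hi = chrom.window
        if not (hi > lo):
            raise ValueError(f"low-recombination window undefined on chromosome {chrom.name!r}")
        base = gmap.offsets[ci]
        inside = (chrom.positions >= lo) & (chrom.positions <= hi)
        idx_in = base + np.where(inside)[0]
        idx_out = base + np.where(~inside)[0]
        scale = d_genome_fraction if founders.genome_group[ci] == "D" else 1.0
        n_high = round(high_fraction * scale * chrom.n_loci)
        n_nonsyn = round(nonsyn_fraction * scale * chrom.n_loci)
        total = n_high + n_nonsyn
        if total == 0:
            continue
        # allocate the whole flag budget inside/outside first, so the
        # realized per-Morgan density ratio tracks the requested enrichment
        # for both classes jointly, then split classes proportionally
        e = pericentromere_enrichment
        w_in = idx_in.size * e
        share = w_in / (w_in + idx_out.size) if (w_in + idx_out.size) else 0.0
        k_in = min(idx_in.size, round(total * share))
        k_out = min(idx_out.size, total - k_in)
        pick_in = rng.choice(idx_in, k_in, replace=False) if k_in else np.empty(0, int)
        pick_out = rng.choice(idx_out, k_out, replace=False) if k_out else np.empty(0, int)
        k_in_high = round(k_in * n_high / total)
        k_out_high = min(k_out, n_high - k_in_high)
        high[pick_in[:k_in_high]] = True
        nonsyn[pick_in[k_in_high:]] = True
        high[pick_out[:k_out_high]] = True
        nonsyn[pick_out[k_out_high:]] = True
    return VariantAnnotation(high, nonsyn)


def derive_biparental(founders: FounderSet) -> FounderSet:
    """Reduce to the two most divergent founders (maximum allele-sharing
    distance), dropping loci monomorphic between them.

    The first parent's allele is recoded as 1; the full-set minor-allele
    designation is carried through for linkage-phase statistics.
    """
    if founders.n_founders < 2:
        raise ValueError("need at least 2 founders")
    g = founders.genotypes.astype(np.int16)
    d = (g[:, None, :] != g[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, -1)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    p1, p2 = sorted((int(i), int(j)))
    pair = founders.subset_loci(founders.genotypes[p1] != founders.genotypes[p2])
    geno = pair.genotypes[[p1, p2]]
    new_geno = (geno == geno[0][None, :]).astype(np.uint8)  # parent 1 -> all 1s
    new_minor = (geno[0] == pair.minor_code).astype(np.uint8)
    return FounderSet(new_geno, pair.map, pair.annotations,
                      pair.labels[[p1, p2]], new_minor, list(pair.genome_group))


# ---------------------------------------------------------------------------
# real-data reader


def read_founders(genotype_table, map_path=None, annotation_path=None,
                  unit: str = "M", max_missing: float = 0.6,
                  drop_pc_outliers: bool = False, pc_threshold: float = 3.0,
                  centromeres: dict[str, float] | None = None,
                  log=None) -> FounderSet:
    """Read an inbred founder genotype table from delimited text.

    Expected layout: loci as rows with columns ``id``, ``chromosome``,
    ``position`` (embedded map) and one column per founder, calls in
    {0,1,NA} or {A,B,NA}.  Filters, in order: drop loci with more than
    ``max_missing`` missing calls or an unknown chromosome; drop
    monomorphic loci; recode the major allele as 1; fill remaining missing
    calls with the major allele (a documented simplification of the
    stochastic imputation used on the original data).

    ``drop_pc_outliers`` optionally removes founders whose first-PC score
    exceeds ``pc_threshold`` standard deviations (off by default).
    """
    df = pd.read_csv(genotype_table, sep=None, engine="python", dtype=str)
    df.columns = [c.lower() if c.lower() in ("id", "chromosome", "position") else c
                  for c in df.columns]
    if map_path is not None:
        ext = read_map_table(map_path, unit)
        df = df.merge(ext, on="id", how="left")
    for col in ("id", "chromosome", "position"):
        if col not in df.columns:
            raise ValueError(f"genotype table lacks required column {col!r}")
    if df["id"].duplicated().any():
        raise ValueError("duplicated locus identifiers")
    founder_cols = [c for c in df.columns if c not in ("id", "chromosome", "position")]
    calls = df[founder_cols].apply(lambda s: s.str.strip().str.upper() if s.dtype == object else s)
    coded = calls.replace({"A": "0", "B": "1", "NA": np.nan, "": np.nan, ".": np.nan})
    geno = coded.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    chrom_str = df["chromosome"].astype(str).str.strip().str.lower()
    known = ~chrom_str.isin(_UNKNOWN_CHROM) & df["chromosome"].notna()
    miss_frac = np.isnan(geno).mean(axis=1)
    keep = known.to_numpy() & (miss_frac <= max_missing)
    df, geno = df[keep], geno[keep]
    if log:
        log(f"kept {keep.sum()}/{keep.size} loci after missingness/chromosome filter")

    factor = 0.01 if unit.lower() == "cm" else 1.0
    pos = df["position"].astype(float).to_numpy() * factor
    # major-allele recode + imputation (flagged simplification);
    # geno rows are loci, columns are founders
    with np.errstate(invalid="ignore"):
        freq1 = np.nanmean(geno, axis=1)
    flip = freq1 < 0.5
    geno = np.where(flip[:, None], 1.0 - geno, geno)
    geno = np.where(np.isnan(geno), 1.0, geno)  # missing -> major allele
    if log:
        log("missing calls imputed with the major allele (simplified imputation)")
    # geno has shape (n_loci, n_founders) at this point
    poly = (geno.min(axis=1) < 1) & (geno.max(axis=1) > 0)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    df, geno, pos = df[poly], geno[poly], pos[poly]

    chroms, order = [], []
    for name, grp in df.groupby("chromosome", sort=False):
        rows = df.index.get_indexer(grp.index)
        p = pos[rows]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"map positions not sorted on chromosome {name!r}")
        cen = centromeres.get(str(name)) if centromeres else None
        chroms.append(make_chromosome(p, centromere=cen, name=str(name)))
        order.extend(rows.tolist())
    geno = geno[np.array(order)].T.astype(np.uint8)  # -> (n_founders, n_loci)
    fs = FounderSet(geno, GeneticMap(chroms), labels=np.array(founder_cols),
                    genome_group=default_genome_groups(len(chroms)))
    if annotation_path is not None:
        ids = df["id"].to_numpy()[np.array(order)]
        fs.annotations = read_annotations(annotation_path, ids)
    if drop_pc_outliers:
        fs = _drop_pc_outliers(fs, pc_threshold, log)
    return fs


def read_map_table(path, unit="M") -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    return df[["id", "chromosome", "position"]]


def read_annotations(path, locus_ids: np.ndarray) -> VariantAnnotation:
    """Delimited text (locus id, class in {high, nonsynonymous, none})."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    cls = df.set_index(df["id"].astype(str))["class"].astype(str).str.lower()
    aligned = cls.reindex(np.asarray(locus_ids, dtype=str)).fillna("none")
    return VariantAnnotation((aligned == "high").to_numpy(),
                             (aligned == "nonsynonymous").to_numpy())


def _drop_pc_outliers(fs: FounderSet, threshold: float, log=None) -> FounderSet:
    x = fs.genotypes.astype(float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    z = (pc1 - pc1.mean()) / pc1.std()
    keep = np.abs(z) <= threshold
    if log and (~keep).any():
        log(f"dropped first-PC outlier founders: {list(fs.labels[~keep])}")
    if keep.all():
        return fs
    sub = FounderSet(fs.genotypes[keep], fs.map, fs.annotations,
                     fs.labels[keep], fs.minor_code, list(fs.genome_group))
    # refilter monomorphic loci and re-evaluate major alleles in the subset
    poly = (sub.genotypes.min(axis=0) == 0) & (sub.genotypes.max(axis=0) == 1)
    sub = sub.subset_loci(poly)
    flip = sub.genotypes.mean(axis=0) < 0.5
    sub.genotypes = np.where(flip[None, :], 1 - sub.genotypes, sub.genotypes).astype(np.uint8)
    sub.minor_code = np.where(flip, 1 - sub.minor_code, sub.minor_code).astype(np.uint8)
    return sub


def founders_to_table(fs: FounderSet) -> str:
    """Serialize a FounderSet to the delimited layout ``read_founders`` accepts."""
    chrom = fs.map.chrom_of_locus()
    rows = {
        "id": [f"L{i:06d}" for i in range(fs.n_loci)],
        "chromosome": [fs.map.chromosomes[c].name or str(c) for c in chrom],
        "position": fs.map.all_positions(),
    }
    for k, lab in enumerate(fs.labels):
        rows[str(lab)] = fs.genotypes[k]
    buf = StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    return buf.getvalue()
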