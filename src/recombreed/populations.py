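"""In-memory containers: populations, founder sets, variant annotations."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genmap import ChromosomeMap, GeneticMap


@dataclass
class Population:
    """A set of individuals as a haplotype tensor.

    ``haplotypes`` has shape (n, 2, n_loci) with alleles coded 0/1.
    Founders, doubled haploids and training populations are all
    Populations; inbred individuals simply carry two identical haplotypes.
    """

    haplotypes: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.ids is None:
            self.ids = np.arange(self.n)
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def doses(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 dose per individual (0/1/2), optionally at a locus subset."""
        if loci is None:
            return self.haplotypes.sum(axis=1, dtype=np.int8)
        return self.haplotypes[:, :, loci].sum(axis=1, dtype=np.int8)

    def allele_freq(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Frequency of the allele coded 1, from genotype doses."""
        return self.doses(loci).mean(axis=0) / 2.0

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(self.haplotypes[idx], self.ids[idx])

    def concat(self, other: "Population") -> "Population":
        return Population(
            np.concatenate([self.haplotypes, other.haplotypes], axis=0),
            np.concatenate([self.ids, other.ids]),
        )

    @classmethod
    def from_inbred(cls, genotypes: np.ndarray, ids=None) -> "Population":
        """Build a fully inbred population from single haplotypes (n, n_loci)."""
        g = np.asarray(genotypes, dtype=np.uint8)
        return cls(np.repeat(g[:, None, :], 2, axis=1), ids)


@dataclass
class VariantAnnotation:
    """Per-locus putative-impact flags (mutually exclusive classes)."""

    high_impact: np.ndarray
    nonsynonymous: np.ndarray

    def __post_init__(self):
        self.high_impact = np.asarray(self.high_impact, dtype=bool)
        self.nonsynonymous = np.asarray(self.nonsynonymous, dtype=bool)
        if self.high_impact.shape != self.nonsynonymous.shape:
            raise ValueError("annotation flag arrays must align")

    @property
    def n_loci(self) -> int:
        return self.high_impact.size

    def subset(self, keep: np.ndarray) -> "VariantAnnotation":
        return VariantAnnotation(self.high_impact[keep], self.nonsynonymous[keep])


@dataclass
class FounderSet:
    """Inbred founder lines with their map, annotations and allele coding.

    ``genotypes`` is (n_founders, n_loci) with the major allele (in this
    founder set) coded 1.  ``minor_code`` records, per locus, which code
    (0/1) is the minor allele of the *original full* founder set so that
    linkage-phase statistics keep a consistent minor-allele definition
    after biparental derivation.  ``genome_group`` labels each chromosome
    'A'/'B'/'D' (wheat subgenomes); annotation density is reduced on D.
    """

    genotypes: np.ndarray
    map: GeneticMap
    annotations: VariantAnnotation | None = None
    labels: np.ndarray | None = None
    minor_code: np.ndarray | None = None
    genome_group: list[str] | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be (n_founders, n_loci)")
        if self.genotypes.shape[1] != self.map.n_loci:
            raise ValueError("genotype columns must match map loci")
        if self.labels is None:
            self.labels = np.array([f"F{i:03d}" for i in range(self.n_founders)])
        else:
            self.labels = np.asarray(self.labels)
        if self.minor_code is None:
            self.minor_code = np.zeros(self.n_loci, dtype=np.uint8)
        else:
            self.minor_code = np.asarray(self.minor_code, dtype=np.uint8)
        if self.genome_group is None:
            self.genome_group = default_genome_groups(self.map.n_chrom)

    @property
    def n_founders(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def to_population(self) -> Population:
        return Population.from_inbred(self.genotypes, self.labels)

    def allele_freq(self) -> np.ndarray:
        return self.genotypes.mean(axis=0)

    def minor_indicator(self) -> np.ndarray:
        """(n_founders, n_loci) indicator of carrying the full-set minor allele."""
        return (self.genotypes == self.minor_code[None, :]).astype(np.int8)

    def subset_loci(self, keep: np.ndarray) -> "FounderSet":
        keep = np.asarray(keep)
        if keep.dtype != bool:
            mask = np.zeros(self.n_loci, dtype=bool)
            mask[keep] = True
            keep = mask
        return FounderSet(
            self.genotypes[:, keep],
            self.map.subset(keep),
            self.annotations.subset(keep) if self.annotations is not None else None,
            self.labels,
            self.minor_code[keep],
            list(self.genome_group),
        )

    # -- serialization (single .npz archive) --------------------------------

    def save(self, path) -> None:
        meta = {
            "labels": [str(x) for x in self.labels],
            "genome_group": list(self.genome_group),
            "chrom_names": [c.name for c in self.map.chromosomes],
            "lengths": [c.length for c in self.map.chromosomes],
            "centromeres": [c.centromere for c in self.map.chromosomes],
            "windows": [list(c.window) for c in self.map.chromosomes],
        }
        np.savez_compressed(
            path,
            genotypes=self.genotypes,
            positions=self.map.all_positions(),
            offsets=self.map.offsets,
            high_impact=self.annotations.high_impact if self.annotations else np.zeros(self.n_loci, bool),
            nonsynonymous=self.annotations.nonsynonymous if self.annotations else np.zeros(self.n_loci, bool),
            minor_code=self.minor_code,
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path) -> "FounderSet":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        pos, off = z["positions"], z["offsets"]
        chroms = [
            ChromosomeMap(
                pos[off[i]: off[i + 1]],
                meta["lengths"][i],
                meta["centromeres"][i],
                tuple(meta["windows"][i]),
                meta["chrom_names"][i],
            )
            for i in range(len(off) - 1)
        ]
        return cls(
            z["genotypes"],
            GeneticMap(chroms),
            VariantAnnotation(z["high_impact"], z["nonsynonymous"]),
            np.array(meta["labels"]),
            z["minor_code"],
            list(meta["genome_group"]),
        )


def default_genome_groups(n_chrom: int) -> list[str]:
    """Subgenome labels: thirds of the chromosome list are A, B, D (wheat
    convention for 21 chromosomes: 1-7 A, 8-14 B, 15-21 D); leftovers to A/B."""
    per = n_chrom // 3
    rem = n_chrom - 3 * per
    groups = ["A"] * (per + (1 if rem >= 1 else 0)) + ["B"] * (per + (1 if rem >= 2 else 0)) + ["D"] * per
    return groups[:n_chrom]
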