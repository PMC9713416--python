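"""Genetic maps and recombination-treatment scaling.

A genetic map stores, per chromosome, ordered locus positions in Morgans,
the centromere position, and a low-recombination window spanning the
centromere (0.2 M wide on the wildtype map).  Recombination treatments
("Pericentromere" or "Chromosome" scaling by 2x or 20x) act on the map by
stretching inter-locus distances; the meiosis simulator then places
crossovers at unit intensity per Morgan, so expected crossover count per
gamete always equals map length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Minimum separation imposed on co-located loci, in Morgans.
JITTER = 0.00001

#: Width of the pericentromeric low-recombination window on the WT map (M).
WINDOW_WIDTH = 0.2

MAP_TYPES = ("WT", "Pericentromere", "Chromosome")


@dataclass(frozen=True)
class MapTreatment:
    """A recombination treatment: which region is scaled and by how much.

    ``WT`` leaves the map untouched and forces ``scale_factor == 1``.
    ``Chromosome`` multiplies every inter-locus distance by
    ``scale_factor``; ``Pericentromere`` scales only distance inside the
    wildtype low-recombination window.
    """

    map_type: str = "WT"
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.map_type not in MAP_TYPES:
            raise ValueError(f"unknown map_type {self.map_type!r}; expected one of {MAP_TYPES}")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.map_type == "WT" and self.scale_factor != 1:
            raise ValueError("WT map treatment forces scale_factor = 1")


@dataclass
class ChromosomeMap:
    """Ordered locus positions on one chromosome, in Morgans."""

    positions: np.ndarray
    length: float
    centromere: float
    window: tuple[float, float]
    name: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"locus positions on chromosome {self.name!r} must be strictly increasing")
        if self.positions.size and (self.positions[0] < 0 or self.positions[-1] > self.length + 1e-12):
            raise ValueError(f"positions outside [0, length] on chromosome {self.name!r}")

    @property
    def n_loci(self) -> int:
        return int(self.positions.size)


class GeneticMap:
    """A multi-chromosome genetic map with global locus indexing.

    Loci are concatenated across chromosomes; ``offsets`` gives the global
    index of the first locus of each chromosome (length ``n_chrom + 1``).
    """

    def __init__(self, chromosomes: Sequence[ChromosomeMap]):
        if not chromosomes:
            raise ValueError("map needs at least one chromosome")
        self.chromosomes = list(chromosomes)
        counts = [c.n_loci for c in self.chromosomes]
        self.offsets = np.concatenate([[0], np.cumsum(counts)]).astype(int)

    @property
    def n_chrom(self) -> int:
        return len(self.chromosomes)

    @property
    def n_loci(self) -> int:
        return int(self.offsets[-1])

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.chromosomes))

    def chrom_slice(self, i: int) -> slice:
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def chrom_of_locus(self) -> np.ndarray:
        """Chromosome index for every global locus."""
        out = np.empty(self.n_loci, dtype=int)
        for i in range(self.n_chrom):
            out[self.chrom_slice(i)] = i
        return out

    def all_positions(self) -> np.ndarray:
        return np.concatenate([c.positions for c in self.chromosomes])

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """New map retaining only the global loci in boolean/index mask ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype != bool:
            mask = np.zeros(self.n_loci, dtype=bool)
            mask[keep] = True
            keep = mask
        chroms = []
        for i, c in enumerate(self.chromosomes):
            m = keep[self.chrom_slice(i)]
            chroms.append(replace(c, positions=c.positions[m]))
        return GeneticMap(chroms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.n_chrom == other.n_chrom and all(
            np.array_equal(a.positions, b.positions)
            and a.length == b.length
            and a.centromere == b.centromere
            and a.window == b.window
            for a, b in zip(self.chromosomes, other.chromosomes)
        )


def jitter_positions(positions: np.ndarray, step: float = JITTER) -> np.ndarray:
    """Separate co-located (or out-of-order ties from rounding) positions.

    Any position not strictly greater than its predecessor is bumped to
    predecessor + ``step``.
    """
    out = np.array(positions, dtype=float)
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + step
    return out


def _overlap(lo: float, hi: float, window: tuple[float, float]) -> float:
    return max(0.0, min(hi, window[1]) - max(lo, window[0]))


def scale_map(gmap: GeneticMap, treatment: MapTreatment) -> GeneticMap:
    """Apply a recombination treatment to a wildtype map.

    ``Chromosome``: every coordinate x -> s*x.  ``Pericentromere``: distance
    inside the WT window is multiplied by s; intervals straddling a window
    boundary are split at the boundary and scaled piecewise, so
    x -> x + (s-1)*|[0,x] ∩ window|.  ``WT`` is the identity.
    """
    s = float(treatment.scale_factor)
    if treatment.map_type == "WT":
        return gmap
    chroms = []
    for c in gmap.chromosomes:
        if treatment.map_type == "Chromosome":
            new_pos = c.positions * s
            new_len = c.length * s
            new_cen = c.centromere * s
            new_win = (c.window[0] * s, c.window[1] * s)
        else:  # Pericentromere
            if not (0 <= c.window[0] < c.window[1] <= c.length + 1e-12):
                raise ValueError(f"low-recombination window undefined on chromosome {c.name!r}")
            add = s - 1.0
            new_pos = c.positions + add * np.array([_overlap(0.0, p, c.window) for p in c.positions])
            new_len = c.length + add * (c.window[1] - c.window[0])
            new_cen = c.centromere + add * _overlap(0.0, c.centromere, c.window)
            new_win = (c.window[0], c.window[0] + s * (c.window[1] - c.window[0]))
        chroms.append(ChromosomeMap(new_pos, new_len, new_cen, new_win, c.name))
    return GeneticMap(chroms)


def make_chromosome(positions, length=None, centromere=None, name="", window_width=WINDOW_WIDTH) -> ChromosomeMap:
    """Build a chromosome map with a centromere-spanning window, jittering ties."""
    positions = jitter_positions(np.sort(np.asarray(positions, dtype=float)))
    if length is None:
        length = float(positions[-1]) if positions.size else 0.0
    if centromere is None:
        centromere = length / 2.0
    half = window_width / 2.0
    window = (max(0.0, centromere - half), min(length, centromere + half))
    return ChromosomeMap(positions, float(length), float(centromere), window, name)


def read_map(path, unit: str = "M", centromeres: dict[str, float] | None = None) -> GeneticMap:
    """Read a genetic map from delimited text (chromosome, locus id, position).

    ``unit`` is ``"M"`` or ``"cM"``; positions are stored in Morgans.
    Centromere positions (Morgans, post-conversion) may be supplied per
    chromosome name; default is the chromosome midpoint.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    need = {"chromosome", "id", "position"}
    if not need.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(need)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
        raise ValueError(f"duplicated locus identifiers in map: {dups}")
    factor = 0.01 if unit.lower() == "cm" else 1.0
    chroms = []
    for name, grp in df.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy(dtype=float) * factor
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"map positions not sorted on chromosome {name!r}")
        cen = centromeres.get(str(name)) if centromeres else None
        chroms.append(make_chromosome(pos, centromere=cen, name=str(name)))
    return GeneticMap(chroms)
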