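"""Meiosis on a binned genetic map: crossovers, gametes, crosses, selfing.

The simulated genome is the 0.1-cM bin lattice of a :class:`BinnedGenome`.
Per chromosome, the crossover count is Poisson with rate equal to the
chromosome's genetic length in Morgans, and crossover positions are i.i.d.
uniform along the chromosome — no interference, no mutation, no sex
difference in recombination.  A crossover switches the source haplotype at
the nearest bin boundary.

A simulated haplotype is stored as an array of founder-haplotype indices
over bins (ancestry tracking): marker alleles are materialised by looking
up, for each marker, the founder haplotype recorded in the marker's bin.
Two markers in the same bin therefore co-segregate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import PhasedPopulation
from .map_tools import BinnedGenome

__all__ = [
    "Gamete",
    "SimIndividual",
    "draw_crossovers",
    "make_gamete",
    "cross",
    "self_fertilize",
    "derive_inbred",
    "materialize_genotypes",
    "founders_to_sim",
]


@dataclass
class Gamete:
    """Per-chromosome starting haplotype and sorted crossover positions (Morgans)."""

    start_haplotype: list[int]
    crossovers: list[np.ndarray]

    def __post_init__(self) -> None:
        for h in self.start_haplotype:
            if h not in (0, 1):
                raise ValueError("starting haplotype index must be 0 or 1")
        for pos in self.crossovers:
            if np.any(np.diff(pos) < 0):
                raise ValueError("crossover positions must be sorted")


@dataclass
class SimIndividual:
    """Two bin-resolution haplotypes of founder-haplotype ancestry indices."""

    id: str
    haplotypes: np.ndarray  # (2, total_bins) int32 founder-haplotype indices
    parents: tuple[str | None, str | None] = (None, None)
    generation: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int32)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, total_bins)")


def draw_crossovers(length_morgan: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(length) crossover count; positions i.i.d. Uniform(0, length), sorted."""
    if length_morgan < 0:
        raise ValueError("chromosome length must be non-negative")
    if length_morgan == 0:
        return np.empty(0)
    k = rng.poisson(length_morgan)
    return np.sort(rng.uniform(0.0, length_morgan, size=k))


def _gamete_chrom(
    hap0: np.ndarray,
    hap1: np.ndarray,
    n_bins: int,
    length_morgan: float,
    bin_size_cm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Recombine one chromosome; returns (child bins, start hap, positions)."""
    pos = draw_crossovers(length_morgan, rng)
    start = int(rng.integers(2))
    # crossover -> nearest bin boundary (boundary b sits at b*bin_size cM)
    bounds = np.rint(pos * 100.0 / bin_size_cm).astype(int)
    bounds = bounds[(bounds > 0) & (bounds < n_bins)]
    out = np.empty(n_bins, dtype=np.int32)
    src = (hap0, hap1)
    cur = start
    prev = 0
    for b in bounds:
        out[prev:b] = src[cur][prev:b]
        cur ^= 1
        prev = b
    out[prev:] = src[cur][prev:]
    return out, start, pos


def make_gamete(
    parent: SimIndividual,
    binned: BinnedGenome,
    rng: np.random.Generator,
    return_gamete: bool = False,
):
    """Sample one gamete from a parent as a mosaic of its two haplotypes."""
    offsets = binned.offsets
    child = np.empty(binned.total_bins, dtype=np.int32)
    starts: list[int] = []
    xovers: list[np.ndarray] = []
    for ci in range(len(binned.chrom_names)):
        lo = offsets[ci]
        hi = lo + int(binned.n_bins[ci])
        seg, start, pos = _gamete_chrom(
            parent.haplotypes[0, lo:hi],
            parent.haplotypes[1, lo:hi],
            hi - lo,
            float(binned.lengths_morgan[ci]),
            binned.bin_size_cm,
            rng,
        )
        child[lo:hi] = seg
        starts.append(start)
        xovers.append(pos)
    if return_gamete:
        return child, Gamete(start_haplotype=starts, crossovers=xovers)
    return child


def cross(
    p1: SimIndividual,
    p2: SimIndividual,
    n_progeny: int,
    binned: BinnedGenome,
    rng: np.random.Generator,
    generation: int | None = None,
    id_prefix: str = "prog",
) -> list[SimIndividual]:
    """Cross two parents: each progeny receives one gamete from each."""
    if n_progeny <= 0:
        raise ValueError("n_progeny must be positive")
    if p1.haplotypes.shape != p2.haplotypes.shape:
        raise ValueError("parents must share the same binned genome")
    gen = generation if generation is not None else max(p1.generation, p2.generation) + 1
    out = []
    for i in range(n_progeny):
        h1 = make_gamete(p1, binned, rng)
        h2 = make_gamete(p2, binned, rng)
        out.append(
            SimIndividual(
                id=f"{id_prefix}_{i}",
                haplotypes=np.stack([h1, h2]),
                parents=(p1.id, p2.id),
                generation=gen,
            )
        )
    return out


def self_fertilize(
    ind: SimIndividual,
    binned: BinnedGenome,
    rng: np.random.Generator,
    child_id: str | None = None,
) -> SimIndividual:
    h1 = make_gamete(ind, binned, rng)
    h2 = make_gamete(ind, binned, rng)
    return SimIndividual(
        id=child_id or f"{ind.id}_self",
        haplotypes=np.stack([h1, h2]),
        parents=(ind.id, ind.id),
        generation=ind.generation + 1,
    )


def derive_inbred(
    ind: SimIndividual,
    binned: BinnedGenome,
    rng: np.random.Generator,
    generations: int = 6,
) -> SimIndividual:
    """Single-seed-descent inbred line: ``generations`` rounds of selfing,
    carrying one offspring forward each round."""
    if generations < 1:
        raise ValueError("at least one selfing generation is required")
    cur = ind
    for g in range(generations):
        cur = self_fertilize(cur, binned, rng, child_id=f"{ind.id}_ssd{g + 1}")
    return cur


def materialize_genotypes(
    individuals: list[SimIndividual],
    binned: BinnedGenome,
    founders: PhasedPopulation,
) -> PhasedPopulation:
    """Marker genotypes from bin ancestry via the nearest-bin rule.

    For each marker, both alleles are copied from the founder haplotype
    recorded in the marker's bin.  ``founders`` supplies the allele content
    of each founder haplotype (index 2*i + k for individual i, haplotype k).
    """
    m = founders.n_markers
    if binned.marker_bins.size != m:
        raise ValueError("bin assignment does not cover the founder marker set")
    if binned.marker_bins.size and binned.marker_bins.max() >= binned.total_bins:
        raise ValueError("marker mapped to no bin")
    # founder haplotype alleles, flattened to (2n, m)
    fh = founders.haplotypes.reshape(-1, m)
    src = np.stack([ind.haplotypes for ind in individuals])  # (n, 2, bins)
    anc = src[:, :, binned.marker_bins]  # (n, 2, m)
    if anc.size and (anc.min() < 0 or anc.max() >= fh.shape[0]):
        raise ValueError("ancestry index outside the founder haplotype pool")
    alleles = fh[anc, np.arange(m)]
    return PhasedPopulation(
        individual_ids=[ind.id for ind in individuals],
        haplotypes=alleles.astype(np.int8),
        marker_ids=list(founders.marker_ids),
    )


def founders_to_sim(
    founders: PhasedPopulation, binned: BinnedGenome
) -> list[SimIndividual]:
    """Wrap founder individuals as bin-resolution ancestry constants."""
    out = []
    for i, ind_id in enumerate(founders.individual_ids):
        hap = np.stack(
            [
                np.full(binned.total_bins, 2 * i, dtype=np.int32),
                np.full(binned.total_bins, 2 * i + 1, dtype=np.int32),
            ]
        )
        out.append(SimIndividual(id=str(ind_id), haplotypes=hap, generation=0))
    return out
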