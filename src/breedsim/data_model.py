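"""Core genotype/phenotype containers and population-genetic summaries.

Genotypes are biallelic SNPs.  Phased data are stored as an ``(n, 2, m)``
array of allele codes (0 = reference, 1 = alternate, ``MISSING`` before
imputation); unphased dosages are the alternate-allele count 0/1/2.
This module also provides the marker QC filters (missingness and minor
allele frequency), the VanRaden additive kinship matrix, pairwise LD as
the squared allelic correlation r², and broad-sense heritability from a
replicated one-way ANOVA, h² = sigma²_G / (sigma²_G + sigma²_E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing allele or dosage
MISSING: int = -1

__all__ = [
    "MISSING",
    "PhasedPopulation",
    "GenotypeMatrix",
    "PhenotypeTable",
    "HeritabilityEstimate",
    "LDResult",
    "encode_genotypes",
    "filter_markers",
    "compute_kinship",
    "compute_ld_r2",
    "estimate_heritability",
]


@dataclass
class PhasedPopulation:
    """n diploid individuals x 2 haplotypes x m biallelic markers."""

    individual_ids: list[str]
    haplotypes: np.ndarray  # (n, 2, m) int8; 0/1 alleles, MISSING allowed
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n, p, m = self.haplotypes.shape
        if p != 2:
            raise ValueError("haplotypes must have shape (n, 2, m)")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match haplotypes")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length does not match haplotypes")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        valid = np.isin(self.haplotypes, (0, 1, MISSING))
        if not valid.all():
            raise ValueError("allele codes must be 0, 1 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Alternate-allele dosage matrix (n, m); MISSING where any allele is missing."""
        h = self.haplotypes
        d = h[:, 0, :].astype(np.int16) + h[:, 1, :].astype(np.int16)
        d[(h == MISSING).any(axis=1)] = MISSING
        return d.astype(np.int8)

    def to_genotype_matrix(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages(),
            individual_ids=list(self.individual_ids),
            marker_ids=list(self.marker_ids),
        )

    def subset_markers(self, index: np.ndarray) -> "PhasedPopulation":
        index = np.asarray(index)
        return PhasedPopulation(
            individual_ids=list(self.individual_ids),
            haplotypes=self.haplotypes[:, :, index],
            marker_ids=[self.marker_ids[i] for i in index],
        )


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n individuals x m markers) with per-marker QC summaries."""

    dosages: np.ndarray  # (n, m) int8 in {0,1,2} or MISSING
    individual_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        if not np.isin(self.dosages, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be 0/1/2 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over observed calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        p = d.mean(axis=0) / 2.0
        return np.asarray(p.filled(np.nan), dtype=float)

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Float dosages with per-marker mean imputation of missing entries."""
        x = self.dosages.astype(float)
        x[x == MISSING] = np.nan
        col_means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        idx = np.where(np.isnan(x))
        x[idx] = col_means[idx[1]]
        return x

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[i] for i in index],
        )


@dataclass
class PhenotypeTable:
    """Trait values per individual, optionally with per-year replicates.

    ``values`` holds the across-year averages used by the prediction models;
    ``replicates`` (n x t x y) keeps the per-year observations for the ANOVA
    heritability decomposition.
    """

    values: pd.DataFrame  # index = individual ids, columns = traits
    replicates: np.ndarray | None = None  # (n, t, y), NaN = missing
    trait_meta: pd.DataFrame | None = None  # columns: name, category

    def __post_init__(self) -> None:
        if self.replicates is not None:
            reps = np.asarray(self.replicates, dtype=float)
            if reps.shape[:2] != self.values.shape:
                raise ValueError("replicates shape incompatible with values")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                avg = np.nanmean(reps, axis=2)
            if not np.allclose(
                np.nan_to_num(avg), np.nan_to_num(self.values.to_numpy()), atol=1e-8
            ):
                raise ValueError(
                    "values must equal the mean over non-missing replicate years"
                )
            self.replicates = reps

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)

    def trait_replicates(self, name: str) -> np.ndarray:
        if self.replicates is None:
            raise ValueError("no replicate observations available")
        j = self.traits.index(name)
        return self.replicates[:, j, :]

    @classmethod
    def from_replicates(
        cls,
        replicates: np.ndarray,
        individual_ids: Sequence[str],
        trait_names: Sequence[str],
        trait_meta: pd.DataFrame | None = None,
    ) -> "PhenotypeTable":
        reps = np.asarray(replicates, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            avg = np.nanmean(reps, axis=2)
        values = pd.DataFrame(avg, index=list(individual_ids), columns=list(trait_names))
        return cls(values=values, replicates=reps, trait_meta=trait_meta)


@dataclass
class HeritabilityEstimate:
    sigma2_G: float
    sigma2_E: float
    h2: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


@dataclass
class LDResult:
    pairs: list[tuple[str, str]]
    r2: np.ndarray
    dist_cm: np.ndarray | None = None
    dist_bp: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_a": [a for a, _ in self.pairs],
                "marker_b": [b for _, b in self.pairs],
                "r2": self.r2,
            }
        )
        if self.dist_cm is not None:
            df["dist_cm"] = self.dist_cm
        if self.dist_bp is not None:
            df["dist_bp"] = self.dist_bp
        return df


# ---------------------------------------------------------------------------
# operations


_MISSING_CALLS = {"NN", "--", "..", "./.", ".|.", ""}


def encode_genotypes(
    calls: Sequence[Sequence[str]],
    marker_ids: Sequence[str] | None = None,
    individual_ids: Sequence[str] | None = None,
    alt_alleles: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Encode biallelic genotype calls ("GG", "GA", ...) as 0/1/2 dosages.

    Dosage counts copies of the alternate allele: the reference homozygote is
    0, the heterozygote 1, the alternate homozygote 2.  When ``alt_alleles``
    is not given the alleles at each marker are sorted and the
    lexicographically later one is taken as alternate, which makes the
    encoding deterministic.

    Parameters
    ----------
    calls : (n, m) nested sequence of two-letter genotype strings.
    alt_alleles : optional per-marker alternate allele.
    """
    arr = np.asarray(calls, dtype=object)
    if arr.ndim != 2:
        raise ValueError("calls must be 2-D (individuals x markers)")
    n, m = arr.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(n)]
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        col = arr[:, j]
        observed = [str(c).upper() for c in col]
        alleles: set[str] = set()
        for c in observed:
            if c in _MISSING_CALLS:
                continue
            if len(c) != 2 or not c.isalpha():
                raise ValueError(
                    f"marker {marker_ids[j]}: unknown genotype symbol {c!r}"
                )
            alleles.update(c)
        if len(alleles) > 2:
            raise ValueError(
                f"marker {marker_ids[j]}: more than two alleles {sorted(alleles)}"
            )
        if not alleles:
            continue
        if alt_alleles is not None:
            alt = str(alt_alleles[j]).upper()
            if alt not in alleles and len(alleles) == 2:
                raise ValueError(
                    f"marker {marker_ids[j]}: alternate allele {alt!r} not observed"
                )
        elif len(alleles) == 1:
            alt = ""  # monomorphic without a declared alternate: reference only
        else:
            alt = sorted(alleles)[-1]
        for i, c in enumerate(observed):
            if c in _MISSING_CALLS:
                continue
            dosages[i, j] = (c[0] == alt) + (c[1] == alt)
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=list(individual_ids),
        marker_ids=list(marker_ids),
    )


def filter_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Marker QC: keep markers with missing_rate <= max_missing and maf > min_maf.

    The MAF comparison is strict (a marker at exactly ``min_maf`` is removed).
    Returns the filtered matrix and a per-marker report with the retention flag.
    """
    for name, thr in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    miss = g.missing_rate
    maf = g.maf
    keep = (miss <= max_missing) & (np.nan_to_num(maf, nan=0.0) > min_maf)
    report = pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "missing_rate": miss,
            "maf": maf,
            "retained": keep,
        }
    )
    if not keep.any():
        warnings.warn("no markers passed the QC filters", stacklevel=2)
    return g.subset_markers(np.flatnonzero(keep)), report


def compute_kinship(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden additive relationship matrix.

    G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the allele-frequency-centred
    dosage matrix.  Symmetric and positive semidefinite by construction;
    invariant to marker order and (because centring uses 2p) to which allele
    is labelled alternate.
    """
    if isinstance(g, GenotypeMatrix):
        x = g.imputed()
    else:
        x = np.asarray(g, dtype=float)
    p = x.mean(axis=0) / 2.0
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    z = x - 2.0 * p
    k = z @ z.T / het
    return (k + k.T) / 2.0


def compute_ld_r2(
    pop: PhasedPopulation,
    pairs: Iterable[tuple[int, int]] | Iterable[tuple[str, str]] | None = None,
    linkage_map=None,
) -> LDResult:
    """Pairwise LD as squared Pearson correlation of haplotype allele indicators.

    Computed across the 2n phased haplotypes.  Monomorphic markers give NaN.
    If a :class:`~breedsim.map_tools.LinkageMap` is supplied, genetic and
    physical distances for intra-chromosome pairs are attached.
    """
    h = pop.haplotypes.astype(float)
    h[h == MISSING] = np.nan
    # stack haplotypes: (2n, m)
    hstack = np.concatenate([h[:, 0, :], h[:, 1, :]], axis=0)
    id_to_idx = {mid: j for j, mid in enumerate(pop.marker_ids)}
    if pairs is None:
        m = pop.n_markers
        pair_idx = [(a, b) for a in range(m) for b in range(a, m)]
    else:
        pair_idx = []
        for a, b in pairs:
            ia = id_to_idx[a] if isinstance(a, str) else int(a)
            ib = id_to_idx[b] if isinstance(b, str) else int(b)
            pair_idx.append((ia, ib))
    r2 = np.empty(len(pair_idx))
    for k, (ia, ib) in enumerate(pair_idx):
        xa, xb = hstack[:, ia], hstack[:, ib]
        ok = ~(np.isnan(xa) | np.isnan(xb))
        xa, xb = xa[ok], xb[ok]
        if xa.std() == 0 or xb.std() == 0:
            r2[k] = np.nan
        elif ia == ib:
            r2[k] = 1.0
        else:
            r2[k] = np.corrcoef(xa, xb)[0, 1] ** 2
    dist_cm = dist_bp = None
    if linkage_map is not None:
        pos_cm, pos_bp, chrom = linkage_map.marker_positions()
        dist_cm = np.array(
            [
                abs(pos_cm[a] - pos_cm[b]) if chrom[a] == chrom[b] else np.nan
                for a, b in pair_idx
            ]
        )
        if pos_bp is not None:
            dist_bp = np.array(
                [
                    abs(pos_bp[a] - pos_bp[b]) if chrom[a] == chrom[b] else np.nan
                    for a, b in pair_idx
                ]
            )
    names = [(pop.marker_ids[a], pop.marker_ids[b]) for a, b in pair_idx]
    return LDResult(pairs=names, r2=r2, dist_cm=dist_cm, dist_bp=dist_bp)


def estimate_heritability(replicates: np.ndarray) -> HeritabilityEstimate:
    """Broad-sense heritability from a replicated one-way ANOVA.

    ``replicates`` is an (n individuals x y years) array with one observation
    per individual per year (NaN = missing).  Using the expected mean squares
    of the one-way classification with individual as the factor:

        sigma²_E = MS_within
        sigma²_G = (MS_between - MS_within) / n0

    where n0 is the effective replicate number (equal to y when balanced).
    Negative sigma²_G estimates are truncated to zero, and h² = sigma²_G /
    (sigma²_G + sigma²_E), with the 0/0 case defined as 0.
    """
    x = np.asarray(replicates, dtype=float)
    if x.ndim != 2:
        raise ValueError("replicates must be 2-D (individuals x years)")
    counts = np.sum(~np.isnan(x), axis=1)
    keep = counts >= 1
    x = x[keep]
    counts = counts[keep]
    n_groups = x.shape[0]
    if x.shape[1] < 2 or np.max(counts) < 2:
        raise ValueError("at least two replicate years are required")
    total_n = counts.sum()
    grand = np.nansum(x) / total_n
    means = np.nanmean(x, axis=1)
    ss_between = np.sum(counts * (means - grand) ** 2)
    ss_within = np.nansum((x - means[:, None]) ** 2)
    df_between = n_groups - 1
    df_within = total_n - n_groups
    if df_between <= 0 or df_within <= 0:
        raise ValueError("insufficient degrees of freedom for the ANOVA")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    # effective replicate number for unbalanced one-way EMS
    n0 = (total_n - np.sum(counts**2) / total_n) / df_between
    sigma2_e = ms_within
    sigma2_g = max(0.0, (ms_between - ms_within) / n0)
    denom = sigma2_g + sigma2_e
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityEstimate(
        sigma2_G=float(sigma2_g),
        sigma2_E=float(sigma2_e),
        h2=float(h2),
        n_replicates=int(round(n0)),
    )
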