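"""Synthetic founder panels, trait architectures and phenotypes.

Emulates the statistical structure the analyses assume, without any
download: ~96 phased F1 individuals over 12 chromosomes, ~10^4 mapped SNPs,
LD extending tens of cM, and 20 correlated traits with broad-sense
heritabilities spanning 0.1–1.0 observed over 4 replicate years.

LD is induced by an ancestral-mosaic (haplotype-copying) model: each founder
haplotype is a mosaic of a small pool of ancestral haplotypes with
exponentially distributed segment lengths at the LD scale.  This is an
emulation of long-range LD in an elite panel, not a model of tomato
history.  The two default target traits ("TFW", total fruit weight, and
"SSC", soluble solids content) share pleiotropic QTLs with negatively
correlated effects, reproducing the yield/flavour antagonism that makes
their simultaneous improvement hard.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import PhasedPopulation, PhenotypeTable
from .map_tools import BinnedGenome, ChromosomeMap, LinkageMap, build_bins

__all__ = [
    "FounderConfig",
    "TraitArchitecture",
    "simulate_founders",
    "simulate_phenotypes",
    "make_fixture",
    "default_trait_architecture",
    "DEFAULT_CHROM_LENGTHS_CM",
]

#: default per-chromosome genetic lengths (cM); 12 chromosomes, ~1300 cM total
DEFAULT_CHROM_LENGTHS_CM: tuple[float, ...] = (
    158.0, 136.0, 127.0, 128.0, 115.0, 105.0, 103.0, 99.0, 105.0, 92.0, 99.0, 110.0,
)


@dataclass
class FounderConfig:
    n_individuals: int = 96
    n_chromosomes: int = 12
    chrom_lengths_cm: tuple[float, ...] = DEFAULT_CHROM_LENGTHS_CM
    n_markers: int = 10_000
    ld_scale_cm: float = 20.0
    n_ancestors: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_chromosomes, self.n_markers, self.n_ancestors) <= 0:
            raise ValueError("all counts must be positive")
        if self.ld_scale_cm <= 0:
            raise ValueError("LD scale must be positive")
        if len(self.chrom_lengths_cm) != self.n_chromosomes:
            raise ValueError("chrom_lengths_cm length must equal n_chromosomes")


@dataclass
class TraitArchitecture:
    trait_names: list[str]
    h2_targets: np.ndarray  # per trait, in [0, 1]
    genetic_corr: np.ndarray  # symmetric PSD, unit diagonal
    n_qtl: int = 50
    n_years: int = 4
    trait_categories: list[str] | None = None

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        self.h2_targets = np.asarray(self.h2_targets, dtype=float)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        if self.h2_targets.shape != (t,):
            raise ValueError("one h2 target per trait is required")
        if np.any((self.h2_targets < 0) | (self.h2_targets > 1)):
            raise ValueError("h2 targets must lie in [0, 1]")
        C = self.genetic_corr
        if C.shape != (t, t) or not np.allclose(C, C.T):
            raise ValueError("genetic correlation matrix must be symmetric (t x t)")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic correlation matrix needs a unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("genetic correlation matrix is not PSD")


def default_trait_architecture(n_years: int = 4) -> TraitArchitecture:
    """20 traits spanning h² 0.1–1.0, with a -0.5 TFW/SSC genetic correlation."""
    names = [
        "TFW", "SSC", "PF", "AFW", "PMF", "TMFW", "AMFW", "PCol", "SS", "PBF",
        "PIF", "PCF", "PSF", "LL", "LW", "SW", "H1T", "NFlo", "DTF", "NL1T",
    ]
    h2 = np.array(
        [0.51, 0.60, 0.30, 0.54, 0.40, 0.45, 0.47, 1.00, 0.49, 0.39,
         0.48, 0.34, 0.37, 0.49, 0.46, 0.38, 0.37, 0.38, 0.10, 0.39]
    )
    C = np.eye(len(names))
    C[0, 1] = C[1, 0] = -0.5
    cats = ["yield", "quality"] + ["yield"] * 5 + ["quality"] * 2 + \
        ["disorder"] * 4 + ["other"] * 7
    cats = cats[: len(names)]
    return TraitArchitecture(
        trait_names=names, h2_targets=h2, genetic_corr=C, n_years=n_years,
        trait_categories=cats,
    )


def _bp_from_cm(pos_cm: np.ndarray, length_cm: float, bp_per_cm: float = 750_000.0) -> np.ndarray:
    """Monotone nonlinear cM -> bp relation (mimics pericentromeric compression)."""
    x = pos_cm / max(length_cm, 1e-9)
    warp = x + 0.12 * np.sin(2.0 * np.pi * x) / (2.0 * np.pi) * 4.0
    # derivative 1 + 0.48 cos(2 pi x) > 0.5, hence strictly monotone
    bp = warp * length_cm * bp_per_cm
    return np.maximum(1, np.round(bp)).astype(np.int64)


def simulate_founders(
    cfg: FounderConfig,
) -> tuple[PhasedPopulation, LinkageMap, pd.DataFrame]:
    """Simulate a phased founder panel, its linkage map and an anchor table.

    Ancestral alleles are drawn so the minor allele has 2–6 copies among the
    ancestral pool, keeping the founder MAF spectrum clear of the QC
    thresholds for most markers.  Founder haplotypes copy ancestral segments
    with Exp(ld_scale_cm) lengths, which gives LD decaying on the tens-of-cM
    scale.  The anchor table samples the true bp<->cM relation for the
    projection tooling.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = np.asarray(cfg.chrom_lengths_cm, dtype=float)
    weights = lengths / lengths.sum()
    per_chrom = np.floor(weights * cfg.n_markers).astype(int)
    per_chrom[: cfg.n_markers - per_chrom.sum()] += 1
    n_anc = cfg.n_ancestors
    hap_rows = []
    chrom_frames = []
    anchor_rows = []
    marker_counter = 0
    n_haps = 2 * cfg.n_individuals
    for ci in range(cfg.n_chromosomes):
        L = lengths[ci]
        m_c = int(per_chrom[ci])
        pos_cm = np.sort(rng.uniform(0.0, L, size=m_c))
        pos_bp = _bp_from_cm(pos_cm, L)
        # strictly increasing bp despite rounding
        pos_bp = np.maximum.accumulate(pos_bp + np.arange(m_c))
        # ancestral pool: minor allele on 2..6 of the ancestors
        if n_anc == 1:
            anc = np.zeros((1, m_c), dtype=np.int8)
        else:
            lo = min(2, n_anc - 1)
            hi = min(6, n_anc - 1)
            minor_counts = rng.integers(lo, hi + 1, size=m_c)
            anc = np.zeros((n_anc, m_c), dtype=np.int8)
            for j in range(m_c):
                carriers = rng.choice(n_anc, size=minor_counts[j], replace=False)
                anc[carriers, j] = 1
        # founder haplotypes as ancestral mosaics
        for h in range(n_haps):
            src = np.empty(m_c, dtype=np.int16)
            pos0 = 0.0
            cur = rng.integers(n_anc)
            j = 0
            while j < m_c:
                seg_end = pos0 + rng.exponential(cfg.ld_scale_cm)
                j_end = int(np.searchsorted(pos_cm, seg_end, side="right"))
                src[j:j_end] = cur
                j = j_end
                pos0 = seg_end
                cur = rng.integers(n_anc)
            if h == 0:
                hap_block = np.empty((n_haps, m_c), dtype=np.int8)
            hap_block[h] = anc[src, np.arange(m_c)]
        hap_rows.append(hap_block)
        ids = [f"c{ci + 1}_m{j}" for j in range(m_c)]
        marker_counter += m_c
        chrom_frames.append(
            ChromosomeMap(
                name=f"chr{ci + 1:02d}",
                length_morgan=L / 100.0,
                markers=pd.DataFrame(
                    {"marker_id": ids, "pos_cm": pos_cm, "pos_bp": pos_bp}
                ),
            )
        )
        n_anchor = max(12, m_c // 25)
        a_cm = np.linspace(0.0, L, n_anchor)
        a_bp = _bp_from_cm(a_cm, L)
        anchor_rows.append(
            pd.DataFrame({"chrom": f"chr{ci + 1:02d}", "pos_bp": a_bp, "pos_cm": a_cm})
        )
    haplotypes = np.concatenate(hap_rows, axis=1)  # (2n, m_total)
    haplotypes = haplotypes.reshape(cfg.n_individuals, 2, -1)
    pop = PhasedPopulation(
        individual_ids=[f"V{i + 1:03d}" for i in range(cfg.n_individuals)],
        haplotypes=haplotypes,
        marker_ids=[mid for c in chrom_frames for mid in c.markers["marker_id"]],
    )
    lmap = LinkageMap(chromosomes=chrom_frames)
    anchors = pd.concat(anchor_rows, ignore_index=True)
    return pop, lmap, anchors


def simulate_phenotypes(
    pop: PhasedPopulation,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    return_qtl: bool = False,
):
    """Additive phenotypes with target genetic correlations and heritabilities.

    A single pleiotropic QTL set is drawn; per-QTL effect vectors across
    traits come from N(0, C) with C the target genetic correlation, so the
    true breeding values realise approximately that correlation.  Per-year
    phenotype = genetic value + N(0, sigma2_E) with sigma2_E chosen so the
    broad-sense heritability on the per-year scale matches the target
    (h²=0 zeroes the genetic signal; h²=1 has no year noise).

    Returns (PhenotypeTable with replicates, true breeding values DataFrame),
    plus the QTL marker indices when ``return_qtl``.
    """
    n, _, m = pop.haplotypes.shape
    t = len(arch.trait_names)
    if arch.n_qtl > m:
        raise ValueError("more QTLs requested than markers available")
    qtl = np.sort(rng.choice(m, size=arch.n_qtl, replace=False))
    X = pop.dosages().astype(float)[:, qtl]
    chol = np.linalg.cholesky(arch.genetic_corr + 1e-10 * np.eye(t))
    raw = rng.standard_normal((arch.n_qtl, t))
    if arch.n_qtl > t:
        # decorrelate the draw so the effect sample correlation is exactly C
        raw = raw - raw.mean(axis=0)
        emp = np.linalg.cholesky(np.cov(raw.T) + 1e-10 * np.eye(t))
        raw = np.linalg.solve(emp, raw.T).T
    effects = raw @ chol.T
    G = X @ effects  # (n, t) raw genetic values
    G = G - G.mean(axis=0)
    reps = np.empty((n, t, arch.n_years))
    tbv = np.empty((n, t))
    for j in range(t):
        h2 = arch.h2_targets[j]
        g = G[:, j]
        var_g = g.var()
        if var_g <= 0 or h2 <= 0:
            g = np.zeros(n)
            sigma_e = 1.0
        elif h2 >= 1:
            sigma_e = 0.0
        else:
            sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
        tbv[:, j] = g
        noise = rng.standard_normal((n, arch.n_years)) * sigma_e
        reps[:, j, :] = g[:, None] + noise
    table = PhenotypeTable.from_replicates(
        reps,
        individual_ids=pop.individual_ids,
        trait_names=arch.trait_names,
        trait_meta=pd.DataFrame(
            {
                "name": arch.trait_names,
                "category": arch.trait_categories or ["unknown"] * t,
                "h2_target": arch.h2_targets,
            }
        ),
    )
    tbv_df = pd.DataFrame(tbv, index=pop.individual_ids, columns=arch.trait_names)
    if return_qtl:
        return table, tbv_df, qtl
    return table, tbv_df


_PRESETS = {
    "tiny": dict(
        founder=dict(
            n_individuals=12,
            n_chromosomes=2,
            chrom_lengths_cm=(60.0, 40.0),
            n_markers=80,
            ld_scale_cm=15.0,
            n_ancestors=4,
        ),
        traits=dict(n_traits=3, n_qtl=10, n_years=4),
    ),
    "panel96": dict(founder=dict(), traits=dict()),
}


def make_fixture(
    preset: str,
    out_dir: str | Path,
    seed: int = 0,
    force: bool = False,
) -> dict:
    """Write a self-contained dataset bundle (genotypes, map, phenotypes).

    ``tiny`` is a seconds-scale unit-test bundle; ``panel96`` emulates the
    study scale (96 individuals x ~10^4 markers x 20 traits x 4 years).
    Returns the manifest dict.  Refuses to overwrite unless ``force``.
    """
    from . import io as bio  # local import to avoid a cycle

    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)
    spec = _PRESETS[preset]
    cfg = FounderConfig(seed=seed, **spec["founder"])
    pop, lmap, anchors = simulate_founders(cfg)
    rng = np.random.default_rng(seed + 1)
    topt = spec["traits"]
    arch = default_trait_architecture()
    if "n_traits" in topt:
        k = topt["n_traits"]
        arch = TraitArchitecture(
            trait_names=arch.trait_names[:k],
            h2_targets=arch.h2_targets[:k],
            genetic_corr=arch.genetic_corr[:k, :k],
            n_qtl=topt.get("n_qtl", arch.n_qtl),
            n_years=topt.get("n_years", arch.n_years),
            trait_categories=(arch.trait_categories or [])[:k] or None,
        )
    pheno, tbv = simulate_phenotypes(pop, arch, rng)
    bio.write_haplotypes_tsv(out / "haplotypes.tsv", pop)
    bio.write_vcf(out / "genotypes.vcf", pop, lmap)
    bio.write_map_tsv(out / "map.tsv", lmap)
    anchors.to_csv(out / "anchors.tsv", sep="\t", index=False)
    bio.write_phenotypes_csv(out / "phenotypes.csv", pheno)
    bio.write_phenotypes_long_csv(out / "phenotypes_long.csv", pheno)
    tbv.to_csv(out / "true_breeding_values.csv")
    manifest = {
        "preset": preset,
        "seed": seed,
        "n_individuals": pop.n_individuals,
        "n_markers": pop.n_markers,
        "n_traits": len(arch.trait_names),
        "n_years": arch.n_years,
        "files": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
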