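"""Readers and writers for the on-disk formats.

Genotypes: phased VCF (GT ``0|1``; read with cyvcf2, written as minimal
VCF 4.2 text) or a TSV haplotype matrix with markers as rows and two
columns per individual (``<id>_hap1``, ``<id>_hap2``).  Maps and anchors
are TSV; phenotypes are CSV, wide (individual x trait averages) or long
(with a ``year`` column for the replicate observations).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import MISSING, PhasedPopulation, PhenotypeTable
from .map_tools import LinkageMap

__all__ = [
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "read_vcf",
    "write_vcf",
    "read_map_tsv",
    "write_map_tsv",
    "read_anchors_tsv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_phenotypes_long_csv",
    "write_phenotypes_long_csv",
    "write_pedigree_tsv",
]


def write_haplotypes_tsv(path: str | Path, pop: PhasedPopulation) -> None:
    cols: dict[str, np.ndarray] = {}
    for i, ind in enumerate(pop.individual_ids):
        cols[f"{ind}_hap1"] = pop.haplotypes[i, 0, :]
        cols[f"{ind}_hap2"] = pop.haplotypes[i, 1, :]
    df = pd.DataFrame(cols, index=pd.Index(pop.marker_ids, name="marker_id"))
    df.to_csv(path, sep="\t")


def read_haplotypes_tsv(path: str | Path) -> PhasedPopulation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids: list[str] = []
    for c in df.columns[::2]:
        if not c.endswith("_hap1"):
            raise ValueError(f"unexpected haplotype column {c!r}")
        ids.append(c[: -len("_hap1")])
    n, m = len(ids), df.shape[0]
    hap = np.empty((n, 2, m), dtype=np.int8)
    for i, ind in enumerate(ids):
        hap[i, 0, :] = df[f"{ind}_hap1"].to_numpy()
        hap[i, 1, :] = df[f"{ind}_hap2"].to_numpy()
    return PhasedPopulation(
        individual_ids=ids, haplotypes=hap, marker_ids=df.index.astype(str).tolist()
    )


def write_vcf(
    path: str | Path,
    pop: PhasedPopulation,
    lmap: LinkageMap | None = None,
    ref: str = "A",
    alt: str = "G",
) -> None:
    """Minimal phased VCF 4.2; positions taken from the map when given."""
    chrom = ["1"] * pop.n_markers
    pos = list(range(1, pop.n_markers + 1))
    if lmap is not None:
        df = lmap.to_frame()
        order = {mid: k for k, mid in enumerate(df["marker_id"])}
        if set(pop.marker_ids) <= set(order):
            sub = df.set_index("marker_id").loc[pop.marker_ids]
            chrom = sub["chrom"].astype(str).tolist()
            if "pos_bp" in sub.columns:
                pos = sub["pos_bp"].astype(int).tolist()
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(pop.individual_ids),
    ]
    h = pop.haplotypes
    for j, mid in enumerate(pop.marker_ids):
        gts = []
        for i in range(pop.n_individuals):
            a, b = h[i, 0, j], h[i, 1, j]
            sa = "." if a == MISSING else str(int(a))
            sb = "." if b == MISSING else str(int(b))
            gts.append(f"{sa}|{sb}")
        lines.append(
            f"{chrom[j]}\t{pos[j]}\t{mid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> PhasedPopulation:
    """Read a phased VCF via cyvcf2 (unphased calls are accepted as-is)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.genotype.array())[:, :2]
        gt = np.where(gt < 0, MISSING, gt)
        rows.append(gt.astype(np.int8))
    hap = np.stack(rows, axis=2) if rows else np.empty((len(ids), 2, 0), dtype=np.int8)
    return PhasedPopulation(individual_ids=ids, haplotypes=hap, marker_ids=marker_ids)


def write_map_tsv(path: str | Path, lmap: LinkageMap) -> None:
    df = lmap.to_frame()
    cols = ["marker_id", "chrom"] + [c for c in ("pos_bp", "pos_cm") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path, length_morgan: dict[str, float] | None = None) -> LinkageMap:
    df = pd.read_csv(path, sep="\t")
    req = {"marker_id", "chrom"}
    if not req <= set(df.columns):
        raise ValueError("map file needs marker_id and chrom columns")
    if "pos_cm" not in df.columns:
        raise ValueError("map file lacks pos_cm (project from anchors first)")
    return LinkageMap.from_frame(df, length_morgan=length_morgan)


def read_anchors_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos_bp", "pos_cm"} <= set(df.columns):
        raise ValueError("anchor file needs chrom, pos_bp and pos_cm columns")
    return df


def write_phenotypes_csv(path: str | Path, pheno: PhenotypeTable) -> None:
    out = pheno.values.copy()
    out.index.name = "individual"
    out.to_csv(path)


def read_phenotypes_csv(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(values=df)


def write_phenotypes_long_csv(path: str | Path, pheno: PhenotypeTable) -> None:
    if pheno.replicates is None:
        raise ValueError("no replicate observations to write")
    n, t, y = pheno.replicates.shape
    rows = []
    for yi in range(y):
        sub = pd.DataFrame(
            pheno.replicates[:, :, yi],
            index=pheno.values.index,
            columns=pheno.values.columns,
        )
        sub = sub.reset_index(names="individual")
        sub.insert(1, "year", yi + 1)
        rows.append(sub)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_phenotypes_long_csv(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    if "year" not in df.columns or "individual" not in df.columns:
        raise ValueError("long phenotype file needs individual and year columns")
    df["individual"] = df["individual"].astype(str)
    traits = [c for c in df.columns if c not in ("individual", "year")]
    years = sorted(df["year"].unique())
    inds = df["individual"].drop_duplicates().tolist()
    reps = np.full((len(inds), len(traits), len(years)), np.nan)
    ind_idx = {v: i for i, v in enumerate(inds)}
    year_idx = {v: i for i, v in enumerate(years)}
    for _, row in df.iterrows():
        i = ind_idx[row["individual"]]
        yi = year_idx[row["year"]]
        for tj, trait in enumerate(traits):
            reps[i, tj, yi] = row[trait]
    return PhenotypeTable.from_replicates(reps, individual_ids=inds, trait_names=traits)


def write_pedigree_tsv(path: str | Path, individuals) -> None:
    rows = [
        {
            "id": ind.id,
            "parent1": ind.parents[0] or ".",
            "parent2": ind.parents[1] or ".",
            "generation": ind.generation,
        }
        for ind in individuals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
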