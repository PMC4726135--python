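"""End-to-end analysis pipeline mirroring the breeding-design workflow.

filter -> (optional bp->cM projection) -> LOOCV over prediction methods ->
best-method-per-trait table -> GWAS on the target traits -> recurrent
genomic-selection simulation.  Every output table lands in the artifact
directory together with a JSON run record (seed, parameters, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .breeding import run_recurrent_gs
from .data_model import (
    PhasedPopulation,
    PhenotypeTable,
    compute_kinship,
    estimate_heritability,
    filter_markers,
)
from .gwas import mlm_scan
from .map_tools import LinkageMap
from .wgp import ShrinkageConfig, best_method_per_trait, fit_model, loocv

log = logging.getLogger("breedsim")


@dataclass
class RunConfig:
    """Workflow parameters; defaults follow the study design throughout."""

    geno: str = ""
    map: str = ""
    pheno: str = ""
    out: str = "breedsim_out"
    max_missing: float = 0.05
    min_maf: float = 0.05
    n_pcs: int = 6
    fdr_level: float = 0.05
    theta: float = 1e-4
    bin_size_cm: float = 0.1
    population_size: int = 96
    generations: int = 5
    replicates: int = 5
    inbreeding_generations: int = 6
    methods: tuple[str, ...] = ("rr", "bl", "ebl", "bayesc", "rkhs")
    target_traits: tuple[str, ...] = ("TFW", "SSC")
    seed: int = 0
    gibbs_iters: int = 1000
    gibbs_burnin: int = 300

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_inputs(cfg: RunConfig) -> tuple[PhasedPopulation, LinkageMap, PhenotypeTable]:
    geno = Path(cfg.geno)
    if geno.suffix == ".vcf":
        pop = bio.read_vcf(geno)
    else:
        pop = bio.read_haplotypes_tsv(geno)
    lmap = bio.read_map_tsv(cfg.map)
    if lmap.marker_ids != pop.marker_ids:
        a, b = set(lmap.marker_ids), set(pop.marker_ids)
        first = next(iter(sorted(a ^ b)), "<order>")
        raise ValueError(f"genotype and map marker sets differ (first: {first})")
    pheno_path = Path(cfg.pheno)
    try:
        pheno = bio.read_phenotypes_long_csv(pheno_path)
    except ValueError:
        pheno = bio.read_phenotypes_csv(pheno_path)
    missing = set(pheno.values.index) ^ set(pop.individual_ids)
    if missing:
        raise ValueError(f"phenotype/genotype individual mismatch: {sorted(missing)[0]}")
    pheno.values = pheno.values.loc[pop.individual_ids]
    return pop, lmap, pheno


def run_workflow(cfg: RunConfig) -> Path:
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    log.info("run %s seed=%d", cfg.digest(), cfg.seed)
    pop, lmap, pheno = load_inputs(cfg)

    gm = pop.to_genotype_matrix()
    gm_f, report = filter_markers(gm, cfg.max_missing, cfg.min_maf)
    report.to_csv(out / "marker_qc.tsv", sep="\t", index=False)
    keep = set(gm_f.marker_ids)
    keep_idx = [j for j, mid in enumerate(pop.marker_ids) if mid in keep]
    pop_f = pop.subset_markers(np.asarray(keep_idx))
    map_df = lmap.to_frame()
    lmap_f = LinkageMap.from_frame(
        map_df[map_df["marker_id"].isin(keep)],
        length_morgan={c.name: c.length_morgan for c in lmap.chromosomes},
    )
    log.info("QC: %d of %d markers retained", len(keep_idx), pop.n_markers)

    # heritability table
    h2_rows = []
    if pheno.replicates is not None:
        for t in pheno.traits:
            est = estimate_heritability(pheno.trait_replicates(t))
            h2_rows.append(
                {"trait": t, "sigma2_G": est.sigma2_G, "sigma2_E": est.sigma2_E, "h2": est.h2}
            )
        pd.DataFrame(h2_rows).to_csv(out / "heritability.tsv", sep="\t", index=False)

    # LOOCV model comparison
    scfg = ShrinkageConfig(
        niter=cfg.gibbs_iters, burnin=cfg.gibbs_burnin, seed=cfg.seed, theta=cfg.theta
    )
    reports = []
    for t in pheno.traits:
        y = pheno.trait(t)
        for method in cfg.methods:
            rep = loocv(gm_f, y, method, config=scfg, trait=t)
            reports.append(rep)
            log.info("LOOCV %s/%s accuracy=%.3f", t, method, rep.accuracy)
    cv_table = pd.DataFrame(
        [(r.trait, r.method, r.accuracy) for r in reports],
        columns=["trait", "method", "accuracy"],
    )
    cv_table.to_csv(out / "loocv_accuracy.tsv", sep="\t", index=False)
    best = best_method_per_trait(reports)
    best.to_csv(out / "best_method_per_trait.tsv", sep="\t", index=False)

    # GWAS on target traits
    kin = compute_kinship(gm_f)
    for t in cfg.target_traits:
        if t not in pheno.traits:
            continue
        res = mlm_scan(gm_f, pheno.trait(t), kin, n_pcs=min(cfg.n_pcs, gm_f.n_individuals - 2), fdr_level=cfg.fdr_level)
        res.table.to_csv(out / f"gwas_mlm_{t}.tsv", sep="\t", index=False)

    # recurrent GS with the best model per target trait
    models = {}
    best_by_trait = dict(zip(best["trait"], best["method"]))
    for t in pheno.traits:
        method = best_by_trait.get(t, "rr")
        models[t] = fit_model(gm_f, pheno.trait(t), method, config=scfg)
    targets = [t for t in cfg.target_traits if t in models]
    if len(targets) >= 2:
        sim = run_recurrent_gs(
            pop_f,
            lmap_f,
            models,
            target_traits=targets,
            generations=cfg.generations,
            replicates=cfg.replicates,
            population_size=cfg.population_size,
            seed=cfg.seed,
        )
        sim.gebvs.to_csv(out / "simulation_gebvs.tsv", sep="\t", index=False)
        sim.selected_parents.to_csv(out / "selected_parents.tsv", sep="\t", index=False)

    record = {"config": asdict(cfg), "config_hash": cfg.digest(), "seed": cfg.seed}
    (out / "run_record.json").write_text(json.dumps(record, indent=2, default=str) + "\n")
    return out
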