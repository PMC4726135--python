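"""Recurrent genomic selection: GEBV-based parent choice, round-robin crossing.

The scheme: score every candidate with fixed, founder-trained prediction
models; take the top-k individuals per target trait (2 + 2 for the first
cycle, 4 + 4 afterwards); arrange the selected parents in a ring that
alternates the two trait groups so every cross pairs a high scorer of one
target with a high scorer of the other; cross ring neighbours; keep the
population size constant (96 by default, so 4 crosses x 24 progeny, then
8 crosses x 12).  The models are never retrained on simulated progeny.
GEBVs of all supplied traits — target and non-target — are tracked every
generation, and inbred lines (single-seed descent) can be derived from any
generation with the same fixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PhasedPopulation
from .map_tools import BinnedGenome, LinkageMap, build_bins
from .meiosis import (
    SimIndividual,
    cross,
    derive_inbred,
    founders_to_sim,
    materialize_genotypes,
)
from .wgp import MarkerEffectModel, predict_gebv

__all__ = [
    "SelectionRule",
    "CrossingPlan",
    "SimulationResult",
    "select_parents",
    "round_robin_plan",
    "run_recurrent_gs",
    "derive_inbred_population",
]


@dataclass
class SelectionRule:
    """Per-trait parent counts with next-ranked replacement on overlap."""

    n_parents_first: int = 2
    n_parents_later: int = 4

    def k_for_generation(self, generation: int) -> int:
        return self.n_parents_first if generation == 1 else self.n_parents_later


@dataclass
class CrossingPlan:
    ring: list[int]  # candidate indices in ring order
    crosses: list[tuple[int, int]]
    progeny_per_cross: int

    def __post_init__(self) -> None:
        if len(self.crosses) not in (len(self.ring), 1):
            raise ValueError("a round-robin plan has one cross per ring member")


@dataclass
class SimulationResult:
    """Long-format GEBV trajectories plus per-generation bookkeeping."""

    gebvs: pd.DataFrame  # replicate, generation, individual, trait, gebv
    selected_parents: pd.DataFrame  # replicate, generation, trait_group, individual
    inbred_gebvs: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def generation_means(self) -> pd.DataFrame:
        return (
            self.gebvs.groupby(["replicate", "generation", "trait"])["gebv"]
            .mean()
            .reset_index()
        )

    def population_sizes(self) -> pd.DataFrame:
        return (
            self.gebvs.groupby(["replicate", "generation", "trait"])["individual"]
            .nunique()
            .reset_index(name="n")
        )


def _ranked(values: np.ndarray) -> np.ndarray:
    """Candidate indices by descending value; ties broken by lower index."""
    order = np.lexsort((np.arange(len(values)), -np.asarray(values, float)))
    return order


def select_parents(
    gebvs_by_trait: dict[str, np.ndarray],
    k_per_trait: int,
) -> dict[str, list[int]]:
    """Top-k candidates per trait, de-duplicated across traits.

    If an individual makes the top list for both traits it is kept for the
    trait where it ranks better (ties to the first trait) and the other
    trait takes its next-ranked candidate; the process repeats until the
    per-trait lists are disjoint.  Deterministic: within-trait ties break by
    candidate index, cross-trait rank ties by trait order.
    """
    traits = list(gebvs_by_trait)
    n_cand = len(next(iter(gebvs_by_trait.values())))
    if n_cand < k_per_trait * len(traits):
        raise ValueError(
            f"{n_cand} candidates cannot supply {k_per_trait} parents "
            f"for each of {len(traits)} traits"
        )
    ranked = {t: list(_ranked(np.asarray(gebvs_by_trait[t]))) for t in traits}
    rank_of = {t: {ind: r for r, ind in enumerate(ranked[t])} for t in traits}
    top = {t: ranked[t][:k_per_trait] for t in traits}
    while True:
        overlap = None
        for i, ta in enumerate(traits):
            for tb in traits[i + 1 :]:
                common = [x for x in top[ta] if x in top[tb]]
                if common:
                    overlap = (ta, tb, common[0])
                    break
            if overlap:
                break
        if overlap is None:
            break
        ta, tb, ind = overlap
        # keep where it ranks better; tie -> earlier trait
        loser = tb if rank_of[ta][ind] <= rank_of[tb][ind] else ta
        others = set().union(*(top[t] for t in traits))
        top[loser] = [x for x in top[loser] if x != ind]
        for cand in ranked[loser]:
            if cand not in others:
                top[loser].append(cand)
                break
        else:
            raise ValueError("not enough distinct candidates to de-duplicate")
    return top


def round_robin_plan(
    parents_by_trait: dict[str, list[int]],
    population_size: int = 96,
) -> CrossingPlan:
    """Ring crossing plan interleaving the trait groups.

    The ring alternates members of the two (or more) trait groups so every
    adjacent pair — hence every cross — combines different selection
    targets.  k parents give k crosses of N/k progeny each; N must be
    divisible by k.  k = 2 degenerates to a single cross carrying all N
    progeny.
    """
    groups = [list(v) for v in parents_by_trait.values()]
    k = sum(len(g) for g in groups)
    if k < 2:
        raise ValueError("at least two parents are required")
    width = max(len(g) for g in groups)
    ring: list[int] = []
    for i in range(width):
        for g in groups:
            if i < len(g):
                ring.append(g[i])
    if k == 2:
        if population_size <= 0:
            raise ValueError("population size must be positive")
        return CrossingPlan(
            ring=ring, crosses=[(ring[0], ring[1])], progeny_per_cross=population_size
        )
    if population_size % k != 0:
        raise ValueError(
            f"population size {population_size} is not divisible by {k} crosses"
        )
    crosses = [(ring[i], ring[(i + 1) % k]) for i in range(k)]
    return CrossingPlan(ring=ring, crosses=crosses, progeny_per_cross=population_size // k)


def _gebv_table(
    pop: PhasedPopulation, models: dict[str, MarkerEffectModel]
) -> pd.DataFrame:
    gm = pop.to_genotype_matrix()
    return pd.DataFrame(
        {t: predict_gebv(m, gm) for t, m in models.items()},
        index=pop.individual_ids,
    )


def run_recurrent_gs(
    founders: PhasedPopulation,
    linkage_map: LinkageMap | BinnedGenome,
    models: dict[str, MarkerEffectModel],
    target_traits: list[str],
    generations: int = 5,
    replicates: int = 5,
    population_size: int = 96,
    seed: int = 0,
    rule: SelectionRule | None = None,
    random_selection: bool = False,
    derive_inbreds: bool = False,
    inbreeding_generations: int = 6,
) -> SimulationResult:
    """Simulate the recurrent genomic-selection scheme.

    G1 is produced from founder selection with the first-cycle parent count;
    later generations select among the previous generation's progeny only.
    ``random_selection=True`` replaces GEBV ranking with uniformly random
    parent choice — the negative control that separates selection response
    from simulator drift.  Each replicate runs on an independent,
    deterministic substream of the master seed.
    """
    rule = rule or SelectionRule()
    binned = (
        linkage_map
        if isinstance(linkage_map, BinnedGenome)
        else build_bins(linkage_map)
    )
    for t in target_traits:
        if t not in models:
            raise ValueError(f"no model supplied for target trait {t!r}")
    founder_sims = founders_to_sim(founders, binned)
    founder_gebvs = _gebv_table(founders, models)
    rows: list[pd.DataFrame] = []
    parent_rows: list[dict] = []
    inbred_rows: list[pd.DataFrame] = []
    streams = np.random.SeedSequence(seed).spawn(replicates)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        candidates = founder_sims
        cand_gebvs = founder_gebvs
        for gen in range(1, generations + 1):
            k = rule.k_for_generation(gen)
            if random_selection:
                picked = rng.choice(
                    len(candidates), size=k * len(target_traits), replace=False
                )
                per_trait = {
                    t: list(picked[i * k : (i + 1) * k])
                    for i, t in enumerate(target_traits)
                }
            else:
                per_trait = select_parents(
                    {t: cand_gebvs[t].to_numpy() for t in target_traits}, k
                )
            for t, idxs in per_trait.items():
                for idx in idxs:
                    parent_rows.append(
                        {
                            "replicate": rep,
                            "generation": gen,
                            "trait_group": t,
                            "individual": candidates[idx].id,
                        }
                    )
            plan = round_robin_plan(per_trait, population_size)
            progeny: list[SimIndividual] = []
            for ci, (a, b) in enumerate(plan.crosses):
                progeny.extend(
                    cross(
                        candidates[a],
                        candidates[b],
                        plan.progeny_per_cross,
                        binned,
                        rng,
                        generation=gen,
                        id_prefix=f"r{rep}_g{gen}_c{ci}",
                    )
                )
            pop = materialize_genotypes(progeny, binned, founders)
            gebvs = _gebv_table(pop, models)
            long = gebvs.reset_index(names="individual").melt(
                id_vars="individual", var_name="trait", value_name="gebv"
            )
            long.insert(0, "generation", gen)
            long.insert(0, "replicate", rep)
            rows.append(long)
            if derive_inbreds:
                inb = derive_inbred_population(
                    progeny,
                    binned,
                    founders,
                    models,
                    rng,
                    generations=inbreeding_generations,
                )
                il = inb.reset_index(names="individual").melt(
                    id_vars="individual", var_name="trait", value_name="gebv"
                )
                il.insert(0, "generation", gen)
                il.insert(0, "replicate", rep)
                inbred_rows.append(il)
            candidates = progeny
            cand_gebvs = gebvs
    return SimulationResult(
        gebvs=pd.concat(rows, ignore_index=True),
        selected_parents=pd.DataFrame(parent_rows),
        inbred_gebvs=pd.concat(inbred_rows, ignore_index=True) if inbred_rows else None,
        config={
            "generations": generations,
            "replicates": replicates,
            "population_size": population_size,
            "seed": seed,
            "target_traits": list(target_traits),
            "random_selection": random_selection,
        },
    )


def derive_inbred_population(
    individuals: list[SimIndividual],
    binned: BinnedGenome,
    founders: PhasedPopulation,
    models: dict[str, MarkerEffectModel],
    rng: np.random.Generator,
    generations: int = 6,
) -> pd.DataFrame:
    """One single-seed-descent inbred per individual, scored with the fixed models."""
    inbreds = [derive_inbred(ind, binned, rng, generations=generations) for ind in individuals]
    pop = materialize_genotypes(inbreds, binned, founders)
    return _gebv_table(pop, models)
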