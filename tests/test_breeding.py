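"""Parent selection, round-robin crossing and recurrent genomic selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from breedsim.breeding import (
    SelectionRule,
    derive_inbred_population,
    round_robin_plan,
    run_recurrent_gs,
    select_parents,
)
from breedsim.data_model import PhasedPopulation
from breedsim.map_tools import build_bins
from breedsim.meiosis import founders_to_sim
from breedsim.synthetic import (
    FounderConfig,
    TraitArchitecture,
    simulate_founders,
    simulate_phenotypes,
)
from breedsim.wgp import fit_rr


def _brute_force_dedup(gebv_a, gebv_b, k):
    """Exhaustive enumeration of the next-ranked replacement rule."""
    rank_a = list(np.lexsort((np.arange(len(gebv_a)), -np.asarray(gebv_a))))
    rank_b = list(np.lexsort((np.arange(len(gebv_b)), -np.asarray(gebv_b))))
    top_a, top_b = rank_a[:k], rank_b[:k]
    while set(top_a) & set(top_b):
        ind = next(x for x in top_a if x in top_b)
        if rank_a.index(ind) <= rank_b.index(ind):
            top_b.remove(ind)
            pool = [x for x in rank_b if x not in top_a and x not in top_b]
            top_b.append(pool[0])
        else:
            top_a.remove(ind)
            pool = [x for x in rank_a if x not in top_a and x not in top_b]
            top_a.append(pool[0])
    return top_a, top_b


class TestSelectParents:
    def test_disjoint_top_lists_returned_directly(self):
        sel = select_parents({"A": np.array([5.0, 1, 2, 0]), "B": np.array([0.0, 4, 1, 3])}, 2)
        assert sel["A"] == [0, 2]
        assert sel["B"] == [1, 3]

    def test_overlap_resolved_by_next_ranked_replacement(self):
        # individual 0 tops both traits; it ranks equally (rank 0) in both,
        # so it stays with the first trait and trait B takes its next pick
        sel = select_parents({"A": np.array([9.0, 5, 1, 0]), "B": np.array([9.0, 0, 4, 2])}, 2)
        assert sel["A"] == [0, 1]
        assert sel["B"] == [2, 3]
        all_parents = sel["A"] + sel["B"]
        assert len(set(all_parents)) == 4

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(8, 16)
            a = rng.normal(size=n)
            b = 0.7 * a + rng.normal(size=n)  # correlated -> frequent overlap
            sel = select_parents({"A": a, "B": b}, 4)
            ea, eb = _brute_force_dedup(a, b, 4)
            assert sel["A"] == ea and sel["B"] == eb

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_parents({"A": np.ones(3), "B": np.ones(3)}, 2)

    def test_ties_break_by_index(self):
        sel = select_parents({"A": np.zeros(6), "B": np.zeros(6)}, 2)
        assert sel["A"] == [0, 1] and sel["B"] == [2, 3]


class TestRoundRobinPlan:
    def test_four_parents_96(self):
        plan = round_robin_plan({"A": [0, 1], "B": [2, 3]}, 96)
        assert len(plan.crosses) == 4
        assert plan.progeny_per_cross == 24
        assert plan.ring == [0, 2, 1, 3]  # interleaved trait groups

    def test_eight_parents_96(self):
        plan = round_robin_plan({"A": [0, 1, 2, 3], "B": [4, 5, 6, 7]}, 96)
        assert len(plan.crosses) == 8
        assert plan.progeny_per_cross == 12

    def test_every_cross_pairs_the_two_groups(self):
        plan = round_robin_plan({"A": [0, 1, 2, 3], "B": [4, 5, 6, 7]}, 96)
        for a, b in plan.crosses:
            assert (a < 4) != (b < 4)

    def test_three_parent_ring(self):
        plan = round_robin_plan({"A": [7, 8, 9]}, 9)
        assert plan.crosses == [(7, 8), (8, 9), (9, 7)]

    def test_two_parents_degenerate_single_cross(self):
        plan = round_robin_plan({"A": [0], "B": [1]}, 96)
        assert plan.crosses == [(0, 1)]
        assert plan.progeny_per_cross == 96

    def test_indivisible_population_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            round_robin_plan({"A": [0, 1], "B": [2, 3]}, 50)


@pytest.fixture(scope="module")
def small_gs_setup():
    cfg = FounderConfig(
        n_individuals=32,
        n_chromosomes=2,
        chrom_lengths_cm=(80.0, 60.0),
        n_markers=300,
        ld_scale_cm=15.0,
        n_ancestors=6,
        seed=21,
    )
    pop, lmap, _ = simulate_founders(cfg)
    binned = build_bins(lmap)
    arch = TraitArchitecture(
        trait_names=["up", "down", "other"],
        h2_targets=np.array([0.6, 0.6, 0.4]),
        genetic_corr=np.array([[1.0, -0.5, 0.0], [-0.5, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        n_qtl=30,
        n_years=4,
    )
    pheno, tbv = simulate_phenotypes(pop, arch, np.random.default_rng(22))
    gm = pop.to_genotype_matrix()
    models = {t: fit_rr(gm, pheno.trait(t)) for t in arch.trait_names}
    return pop, binned, models


class TestRecurrentGS:
    def test_population_size_constant(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        sim = run_recurrent_gs(
            pop, binned, models, ["up", "down"],
            generations=3, replicates=2, population_size=32, seed=5,
        )
        assert (sim.population_sizes()["n"] == 32).all()

    def test_all_traits_tracked(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        sim = run_recurrent_gs(
            pop, binned, models, ["up", "down"],
            generations=2, replicates=1, population_size=32, seed=5,
        )
        assert set(sim.gebvs["trait"]) == {"up", "down", "other"}

    def test_parents_are_population_members(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        sim = run_recurrent_gs(
            pop, binned, models, ["up", "down"],
            generations=3, replicates=1, population_size=32, seed=6,
        )
        g1_parents = sim.selected_parents.query("generation == 1")["individual"]
        assert set(g1_parents) <= set(pop.individual_ids)
        g2_parents = set(sim.selected_parents.query("generation == 2")["individual"])
        g1_members = set(sim.gebvs.query("generation == 1")["individual"])
        assert g2_parents <= g1_members  # progeny-only selection after G1

    def test_identical_founders_show_no_response(self, tiny_binned, tiny_panel):
        pop0, _, _ = tiny_panel
        hap = np.tile(pop0.haplotypes[:1], (8, 1, 1))
        pop = PhasedPopulation([f"c{i}" for i in range(8)], hap, pop0.marker_ids)
        gm = pop.to_genotype_matrix()
        rng = np.random.default_rng(7)
        models = {t: fit_rr(gm, rng.normal(size=8)) for t in ("x", "y")}
        sim = run_recurrent_gs(
            pop, tiny_binned, models, ["x", "y"],
            generations=3, replicates=1, population_size=8, seed=8,
        )
        means = sim.generation_means()
        for t in ("x", "y"):
            vals = means.query("trait == @t")["gebv"].to_numpy()
            np.testing.assert_allclose(vals, vals[0], atol=1e-9)

    def test_selection_improves_both_antagonistic_targets(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        sim = run_recurrent_gs(
            pop, binned, models, ["up", "down"],
            generations=4, replicates=3, population_size=32, seed=9,
        )
        means = sim.generation_means()
        for t in ("up", "down"):
            piv = means.query("trait == @t").pivot(
                index="replicate", columns="generation", values="gebv"
            )
            improved = (piv[4] >= piv[1]).sum()
            assert improved >= 2

    def test_reproducible_given_seed(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        kw = dict(
            generations=2, replicates=2, population_size=32, seed=10
        )
        a = run_recurrent_gs(pop, binned, models, ["up", "down"], **kw)
        b = run_recurrent_gs(pop, binned, models, ["up", "down"], **kw)
        pd.testing.assert_frame_equal(a.gebvs, b.gebvs)

    def test_missing_model_rejected(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        with pytest.raises(ValueError, match="no model"):
            run_recurrent_gs(pop, binned, models, ["up", "absent"], population_size=32)


class TestInbredDerivation:
    def test_homozygous_population_unchanged(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        hom = PhasedPopulation(
            pop.individual_ids,
            np.repeat(pop.haplotypes[:, :1, :], 2, axis=1),
            pop.marker_ids,
        )
        sims = founders_to_sim(hom, binned)
        rng = np.random.default_rng(11)
        gebvs = derive_inbred_population(sims, binned, hom, models, rng)
        from breedsim.wgp import predict_gebv

        gm = hom.to_genotype_matrix()
        for t, m in models.items():
            np.testing.assert_allclose(gebvs[t].to_numpy(), predict_gebv(m, gm))

    def test_inbreeding_exposes_additive_variance(self, small_gs_setup):
        pop, binned, models = small_gs_setup
        sims = founders_to_sim(pop, binned)
        t = "up"
        gm = pop.to_genotype_matrix()
        from breedsim.wgp import predict_gebv

        parental = predict_gebv(models[t], gm)
        var_ratio, mean_shift = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            inb = derive_inbred_population(sims, binned, pop, models, rng)
            var_ratio.append(inb[t].var() / parental.var())
            mean_shift.append(inb[t].mean() - parental.mean())
        assert np.mean(var_ratio) > 1.0  # selfing exposes additive variance
        assert abs(np.mean(mean_shift)) < 0.5 * parental.std()  # no directional shift
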