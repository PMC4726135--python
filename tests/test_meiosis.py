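"""Crossover sampling, gamete construction, crossing and selfing."""

import math

import numpy as np
import pandas as pd
import pytest

from breedsim.data_model import PhasedPopulation
from breedsim.map_tools import ChromosomeMap, LinkageMap, build_bins
from breedsim.meiosis import (
    SimIndividual,
    cross,
    derive_inbred,
    draw_crossovers,
    founders_to_sim,
    make_gamete,
    materialize_genotypes,
    self_fertilize,
)


def _two_marker_genome(d_cm: float = 10.0, length_morgan: float = 0.5):
    lm = LinkageMap(
        [
            ChromosomeMap(
                "c1",
                length_morgan,
                pd.DataFrame({"marker_id": ["l", "r"], "pos_cm": [10.0, 10.0 + d_cm]}),
            )
        ]
    )
    return build_bins(lm)


def _het_founder(binned, n_markers=2):
    hap = np.zeros((1, 2, n_markers), dtype=np.int8)
    hap[0, 1, :] = 1  # haplotype 1 carries the alternate allele everywhere
    pop = PhasedPopulation(["f1"], hap, [f"m{j}" for j in range(n_markers)][:n_markers])
    return pop, founders_to_sim(pop, binned)[0]


class TestDrawCrossovers:
    def test_zero_length_never_recombines(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert draw_crossovers(0.0, rng).size == 0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            draw_crossovers(-1.0, np.random.default_rng(0))

    def test_poisson_mean_and_variance(self):
        rng = np.random.default_rng(1)
        lam = 1.2
        counts = np.array([draw_crossovers(lam, rng).size for _ in range(10_000)])
        se_mean = math.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 3 * se_mean
        se_var = math.sqrt((lam + 2 * lam**2) / len(counts))
        assert abs(counts.var() - lam) < 3 * se_var

    def test_positions_inside_and_sorted(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            pos = draw_crossovers(2.0, rng)
            assert np.all((pos >= 0) & (pos <= 2.0))
            assert np.all(np.diff(pos) >= 0)


class TestMakeGamete:
    def test_identical_haplotypes_pass_through(self):
        binned = _two_marker_genome()
        hap = np.ones((1, 2, 2), dtype=np.int8)
        pop = PhasedPopulation(["f"], hap, ["m0", "m1"])
        sim = founders_to_sim(pop, binned)[0]
        rng = np.random.default_rng(3)
        mb = binned.marker_bins
        fh = pop.haplotypes.reshape(-1, 2)
        for _ in range(20):
            g = make_gamete(sim, binned, rng)
            np.testing.assert_array_equal(fh[g[mb], np.arange(2)], [1, 1])

    def test_haldane_recombination_fraction(self):
        d = 0.1  # Morgans
        binned = _two_marker_genome(d_cm=10.0)
        _, sim = _het_founder(binned)
        rng = np.random.default_rng(4)
        mb = binned.marker_bins
        n = 20_000
        rec = 0
        for _ in range(n):
            g = make_gamete(sim, binned, rng)
            rec += (g[mb[0]] & 1) != (g[mb[1]] & 1)
        r_hat = rec / n
        r_exp = (1 - math.exp(-2 * d)) / 2
        se = math.sqrt(r_exp * (1 - r_exp) / n)
        assert abs(r_hat - r_exp) < 3 * se

    def test_unlinked_chromosomes_assort_independently(self):
        lm = LinkageMap(
            [
                ChromosomeMap("c1", 0.3, pd.DataFrame({"marker_id": ["a"], "pos_cm": [15.0]})),
                ChromosomeMap("c2", 0.3, pd.DataFrame({"marker_id": ["b"], "pos_cm": [15.0]})),
            ]
        )
        binned = build_bins(lm)
        _, sim = _het_founder(binned)
        rng = np.random.default_rng(5)
        mb = binned.marker_bins
        n = 20_000
        same = 0
        for _ in range(n):
            g = make_gamete(sim, binned, rng)
            same += (g[mb[0]] & 1) == (g[mb[1]] & 1)
        assert abs(same / n - 0.5) < 3 * math.sqrt(0.25 / n)


class TestCrossAndSelfing:
    def test_inbred_identical_parents_give_identical_progeny(self):
        binned = _two_marker_genome()
        hap = np.zeros((2, 2, 2), dtype=np.int8)  # two founders, all-reference
        pop = PhasedPopulation(["p1", "p2"], hap, ["m0", "m1"])
        sims = founders_to_sim(pop, binned)
        rng = np.random.default_rng(6)
        prog = cross(sims[0], sims[1], 10, binned, rng)
        mat = materialize_genotypes(prog, binned, pop)
        assert np.all(mat.haplotypes == 0)

    def test_nonpositive_progeny_rejected(self):
        binned = _two_marker_genome()
        pop, sim = _het_founder(binned)
        with pytest.raises(ValueError):
            cross(sim, sim, 0, binned, np.random.default_rng(0))

    def test_mendelian_segregation_from_f1_self(self):
        # selfing an Aa F1: progeny dosage at a marker ~ {0: 1/4, 1: 1/2, 2: 1/4}
        binned = _two_marker_genome()
        pop, sim = _het_founder(binned)
        rng = np.random.default_rng(7)
        prog = cross(sim, sim, 10_000, binned, rng)
        mat = materialize_genotypes(prog, binned, pop)
        d = mat.dosages()[:, 0]
        frac_het = np.mean(d == 1)
        assert abs(frac_het - 0.5) < 3 * math.sqrt(0.25 / len(d))
        assert abs(np.mean(d) - 1.0) < 3 * math.sqrt(0.5 / len(d))

    def test_allele_conservation(self):
        binned = _two_marker_genome()
        pop, sim = _het_founder(binned)
        rng = np.random.default_rng(8)
        prog = cross(sim, sim, 200, binned, rng)
        anc = np.stack([p.haplotypes for p in prog])
        assert set(np.unique(anc)) <= {0, 1}  # only the parent's haplotypes

    def test_homozygous_input_fixed_under_selfing(self):
        binned = _two_marker_genome()
        hap = np.ones((1, 2, 2), dtype=np.int8)
        pop = PhasedPopulation(["f"], hap, ["m0", "m1"])
        sim = founders_to_sim(pop, binned)[0]
        rng = np.random.default_rng(9)
        inbred = derive_inbred(sim, binned, rng, generations=6)
        mat = materialize_genotypes([inbred], binned, pop)
        assert np.all(mat.haplotypes == 1)

    def test_selfing_heterozygosity_decay(self):
        # fraction of initially heterozygous bins still het after g selfings = (1/2)^g
        lm = LinkageMap(
            [ChromosomeMap("c1", 1.0, pd.DataFrame({"marker_id": ["x"], "pos_cm": [50.0]}))]
        )
        binned = build_bins(lm)
        pop, sim = _het_founder(binned, n_markers=1)
        g = 6
        reps = 2000
        rng = np.random.default_rng(10)
        het = np.empty(reps)
        for r in range(reps):
            ind = derive_inbred(sim, binned, rng, generations=g)
            a = ind.haplotypes
            het[r] = np.mean((a[0] & 1) != (a[1] & 1))
        expect = 0.5**g
        se = het.std(ddof=1) / math.sqrt(reps)
        assert abs(het.mean() - expect) < 3 * se + 1e-12

    def test_pedigree_recorded(self):
        binned = _two_marker_genome()
        pop, sim = _het_founder(binned)
        child = self_fertilize(sim, binned, np.random.default_rng(11))
        assert child.parents == (sim.id, sim.id)
        assert child.generation == sim.generation + 1


class TestMaterialize:
    def test_shared_bin_markers_in_perfect_ld(self):
        lm = LinkageMap(
            [
                ChromosomeMap(
                    "c1",
                    0.5,
                    pd.DataFrame(
                        {"marker_id": ["a", "b", "c"], "pos_cm": [10.01, 10.02, 40.0]}
                    ),
                )
            ]
        )
        binned = build_bins(lm)
        assert binned.marker_bins[0] == binned.marker_bins[1]
        hap = np.zeros((1, 2, 3), dtype=np.int8)
        hap[0, 1, :] = 1
        pop = PhasedPopulation(["f"], hap, ["a", "b", "c"])
        sim = founders_to_sim(pop, binned)[0]
        rng = np.random.default_rng(12)
        prog = cross(sim, sim, 500, binned, rng)
        mat = materialize_genotypes(prog, binned, pop)
        np.testing.assert_array_equal(mat.haplotypes[:, :, 0], mat.haplotypes[:, :, 1])

    def test_founder_round_trip(self, tiny_panel, tiny_binned):
        pop, _, _ = tiny_panel
        sims = founders_to_sim(pop, tiny_binned)
        mat = materialize_genotypes(sims, tiny_binned, pop)
        np.testing.assert_array_equal(mat.haplotypes, pop.haplotypes)

    def test_reproducible_with_fixed_seed(self, tiny_panel, tiny_binned):
        pop, _, _ = tiny_panel
        sims = founders_to_sim(pop, tiny_binned)

        def run(seed):
            rng = np.random.default_rng(seed)
            prog = cross(sims[0], sims[1], 20, tiny_binned, rng)
            return materialize_genotypes(prog, tiny_binned, pop).haplotypes

        np.testing.assert_array_equal(run(123), run(123))
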