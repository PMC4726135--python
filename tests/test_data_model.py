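"""Containers, encoding, QC filters, kinship, LD and heritability."""

import numpy as np
import pandas as pd
import pytest

from breedsim.data_model import (
    MISSING,
    GenotypeMatrix,
    PhasedPopulation,
    compute_kinship,
    compute_ld_r2,
    encode_genotypes,
    estimate_heritability,
    filter_markers,
)


class TestEncodeGenotypes:
    def test_alt_allele_dosage(self):
        g = encode_genotypes([["GG"], ["GA"], ["AA"]], alt_alleles=["A"])
        assert g.dosages[:, 0].tolist() == [0, 1, 2]

    def test_monomorphic_column(self):
        g = encode_genotypes([["GG"], ["GG"], ["GG"]])
        assert g.dosages[:, 0].tolist() == [0, 0, 0]
        assert g.maf[0] == 0.0

    def test_half_and_half(self):
        g = encode_genotypes([["GG"], ["GG"], ["AA"], ["AA"]], alt_alleles=["A"])
        assert sorted(g.dosages[:, 0].tolist()) == [0, 0, 2, 2]
        assert g.maf[0] == pytest.approx(0.5)

    def test_triallelic_rejected_with_marker_id(self):
        with pytest.raises(ValueError, match="snp7"):
            encode_genotypes([["GG"], ["GT"], ["GC"]], marker_ids=["snp7"])

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype symbol"):
            encode_genotypes([["G?"], ["GG"]])

    def test_missing_sentinel(self):
        g = encode_genotypes([["NN"], ["GA"], ["AA"]], alt_alleles=["A"])
        assert g.dosages[0, 0] == MISSING
        assert g.missing_rate[0] == pytest.approx(1 / 3)


class TestFilterMarkers:
    def _toy(self):
        # 10 individuals x 10 markers; markers 2, 5, 8 violate the filters
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        d[:, 2] = 0                      # monomorphic -> maf 0
        d[:, 5] = [1] + [0] * 9          # maf exactly 0.05 -> removed (strict >)
        d[:, 8] = [MISSING] * 2 + [1] * 8  # 20% missing
        for j in (0, 1, 3, 4, 6, 7, 9):
            d[0, j] = 1  # guarantee polymorphism elsewhere
        return GenotypeMatrix(d, [f"i{i}" for i in range(10)], [f"m{j}" for j in range(10)])

    def test_boundary_maf_removed(self):
        g = self._toy()
        filtered, report = filter_markers(g)
        assert "m5" not in filtered.marker_ids
        assert report.set_index("marker_id").loc["m5", "maf"] == pytest.approx(0.05)

    def test_enumerated_violations(self):
        filtered, report = filter_markers(self._toy())
        assert not report.set_index("marker_id").loc[["m2", "m5", "m8"], "retained"].any()
        assert filtered.n_markers == 7

    def test_clean_marker_retained(self):
        d = np.array([[0], [0], [2], [2]], dtype=np.int8)
        g = GenotypeMatrix(d, list("abcd"), ["m"])
        filtered, _ = filter_markers(g)
        assert filtered.marker_ids == ["m"]

    def test_idempotent(self):
        once, _ = filter_markers(self._toy())
        twice, _ = filter_markers(once)
        assert twice.marker_ids == once.marker_ids
        np.testing.assert_array_equal(twice.dosages, once.dosages)

    def test_empty_result_warns(self):
        d = np.zeros((4, 2), dtype=np.int8)
        g = GenotypeMatrix(d, list("abcd"), ["x", "y"])
        with pytest.warns(UserWarning, match="no markers"):
            filtered, _ = filter_markers(g)
        assert filtered.n_markers == 0


class TestKinship:
    def test_identical_individuals_maximal_offdiag(self):
        d = np.array([[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 1, 2]], dtype=np.int8)
        g = GenotypeMatrix(d, list("abc"), list("wxyz"))
        k = compute_kinship(g)
        assert k[0, 1] == pytest.approx(max(k[0, 1], k[0, 2], k[1, 2]))
        assert k[0, 1] == pytest.approx(k[0, 0])  # duplicates are self-similar

    def test_duplicating_markers_invariant(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
        g1 = GenotypeMatrix(d, [f"i{i}" for i in range(6)], [f"m{j}" for j in range(5)])
        g2 = GenotypeMatrix(
            np.hstack([d, d]), g1.individual_ids, g1.marker_ids + [f"d{j}" for j in range(5)]
        )
        np.testing.assert_allclose(compute_kinship(g1), compute_kinship(g2), atol=1e-12)

    def test_hand_computed_3x2(self):
        d = np.array([[0, 2], [1, 1], [2, 0]], dtype=float)
        p = d.mean(axis=0) / 2.0  # (0.5, 0.5)
        z = d - 2 * p
        expect = z @ z.T / (2 * np.sum(p * (1 - p)))
        g = GenotypeMatrix(d.astype(np.int8), list("abc"), ["u", "v"])
        np.testing.assert_allclose(compute_kinship(g), expect)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
        g1 = GenotypeMatrix(d, [f"i{i}" for i in range(8)], [f"m{j}" for j in range(6)])
        flipped = d.copy()
        flipped[:, 3] = 2 - flipped[:, 3]
        g2 = GenotypeMatrix(flipped, g1.individual_ids, g1.marker_ids)
        np.testing.assert_allclose(compute_kinship(g1), compute_kinship(g2), atol=1e-12)

    def test_psd_and_symmetric(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        k = compute_kinship(GenotypeMatrix(d, [f"i{i}" for i in range(10)], [f"m{j}" for j in range(30)]))
        np.testing.assert_allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-9

    def test_monomorphic_only_rejected(self):
        g = GenotypeMatrix(np.zeros((4, 3), dtype=np.int8), list("abcd"), list("xyz"))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_kinship(g)


class TestLD:
    def test_self_r2_is_one(self):
        hap = np.array([[[0, 0], [1, 1]], [[0, 1], [1, 0]]], dtype=np.int8)
        pop = PhasedPopulation(["a", "b"], hap, ["m1", "m2"])
        res = compute_ld_r2(pop, [(0, 0)])
        assert res.r2[0] == 1.0

    def test_two_locus_textbook_value(self):
        # 2n=100 haplotypes: AB=40, Ab=10, aB=10, ab=40
        # D = 0.40 - 0.5*0.5 = 0.15; r2 = D^2/(pA qA pB qB) = 0.36
        blocks = [(1, 1, 40), (1, 0, 10), (0, 1, 10), (0, 0, 40)]
        h1, h2 = [], []
        for a, b, count in blocks:
            h1.extend([a] * count)
            h2.extend([b] * count)
        hap = np.stack([np.array(h1), np.array(h2)], axis=1)  # (100, 2 markers)
        hap = hap.reshape(50, 2, 2).astype(np.int8)
        pop = PhasedPopulation([f"i{i}" for i in range(50)], hap, ["A", "B"])
        res = compute_ld_r2(pop, [(0, 1)])
        assert res.r2[0] == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_pair_missing(self):
        hap = np.zeros((3, 2, 2), dtype=np.int8)
        hap[:, :, 1] = [[0, 1], [1, 0], [0, 0]]
        pop = PhasedPopulation(list("abc"), hap, ["mono", "poly"])
        res = compute_ld_r2(pop, [(0, 1)])
        assert np.isnan(res.r2[0])

    def test_independent_markers_sampling_bias(self):
        # E[r2] for independent markers ~ 1/(2n)
        rng = np.random.default_rng(42)
        n2 = 200
        reps = 1000
        vals = np.empty(reps)
        for r in range(reps):
            a = rng.integers(0, 2, n2)
            b = rng.integers(0, 2, n2)
            if a.std() == 0 or b.std() == 0:
                vals[r] = np.nan
                continue
            vals[r] = np.corrcoef(a, b)[0, 1] ** 2
        assert np.nanmean(vals) == pytest.approx(1.0 / n2, abs=1.5e-3)

    def test_distances_attached(self, tiny_panel):
        pop, lmap, _ = tiny_panel
        res = compute_ld_r2(pop, [(0, 1)], linkage_map=lmap)
        assert res.dist_cm is not None and np.isfinite(res.dist_cm[0])


class TestHeritability:
    def test_pure_genetic_trait(self):
        x = np.tile(np.arange(10, dtype=float)[:, None], (1, 4))
        est = estimate_heritability(x)
        assert est.h2 == 1.0 and est.sigma2_E == 0.0

    def test_degenerate_all_equal(self):
        est = estimate_heritability(np.full((6, 4), 3.0))
        assert est.h2 == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            estimate_heritability(np.ones((5, 1)))

    @pytest.mark.parametrize("h2_true", [0.1, 0.5, 0.9])
    def test_parameter_recovery(self, h2_true):
        n, y = 200, 4
        s2g = 1.0
        s2e = s2g * (1 - h2_true) / h2_true if h2_true > 0 else 1e6
        ests = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            g = rng.normal(0, np.sqrt(s2g), n)
            x = g[:, None] + rng.normal(0, np.sqrt(s2e), (n, y))
            ests.append(estimate_heritability(x).h2)
        assert np.mean(ests) == pytest.approx(h2_true, abs=0.05)

    def test_negative_variance_truncated(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (8, 4))  # no genetic signal, tiny n
        est = estimate_heritability(x)
        assert est.sigma2_G >= 0.0 and 0.0 <= est.h2 <= 1.0


class TestPhasedConsistency:
    def test_maf_identical_by_either_route(self, tiny_panel):
        pop, _, _ = tiny_panel
        gm = pop.to_genotype_matrix()
        hap_freq = pop.haplotypes.reshape(-1, pop.n_markers).mean(axis=0)
        maf_hap = np.minimum(hap_freq, 1 - hap_freq)
        np.testing.assert_allclose(gm.maf, maf_hap, atol=1e-12)

    def test_dosage_range(self, tiny_panel):
        pop, _, _ = tiny_panel
        d = pop.dosages()
        assert set(np.unique(d)) <= {0, 1, 2}
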