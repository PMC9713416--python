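"""Marker panels, QTL assignment, effect-sign scenarios, standardization."""

import numpy as np
import pytest

from recombreed.genmap import GeneticMap, make_chromosome
from recombreed.populations import FounderSet, Population, VariantAnnotation
from recombreed.traits import (PhenotypeModel, TraitArchitecture,
                               assign_effect_signs, assign_qtl, genetic_values,
                               phenotype, round_half_up, sample_dv_pool,
                               sample_snpchip, standardize_variance)


class TestSnpChip:
    def test_occupied_bins_yield_expected_panel(self, rng):
        # 122 occupied 1-cM bins x 10 per bin -> ~1200 markers
        pos = np.sort(np.concatenate([np.random.default_rng(0).uniform(0, 1.22, 2440)]))
        from recombreed.genmap import jitter_positions
        gmap = GeneticMap([make_chromosome(jitter_positions(pos), length=1.22)])
        fs = FounderSet(np.ones((2, 2440), np.uint8), gmap)
        markers = sample_snpchip(fs, per_bin=10, rng=rng)
        assert 1100 <= markers.size <= 1220

    def test_sparse_bins_contribute_all_their_snps(self, rng):
        gmap = GeneticMap([make_chromosome([0.001, 0.002, 0.5], length=1.0)])
        fs = FounderSet(np.ones((2, 3), np.uint8), gmap)
        markers = sample_snpchip(fs, per_bin=10, rng=rng)
        assert markers.size == 3  # empty bins skipped, small bins taken whole


class TestDvPool:
    def test_pool_composition_fractions(self, rng):
        ann = VariantAnnotation(np.arange(1400) < 1000,
                                (np.arange(1400) >= 1000))
        pool = sample_dv_pool(ann, rng)
        assert pool.size == 900 + 100  # 90% of 1000 high + 25% of 400 nonsyn
        assert np.sum(ann.high_impact[pool]) == 900
        assert np.sum(ann.nonsynonymous[pool]) == 100

    def test_rounding_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(2.25 * 2) == 5  # 4.5 -> 5

    def test_expected_pool_arithmetic(self, rng):
        ann = VariantAnnotation(np.arange(900) < 500,
                                (np.arange(900) >= 500))
        pool = sample_dv_pool(ann, rng)
        assert pool.size == round_half_up(0.9 * 500) + round_half_up(0.25 * 400)

    def test_no_annotations_rejected(self, rng):
        ann = VariantAnnotation(np.zeros(10, bool), np.zeros(10, bool))
        with pytest.raises(ValueError, match="no annotated"):
            sample_dv_pool(ann, rng)


class TestAssignQtl:
    def test_counts_and_disjointness(self, founders_small, rng):
        markers = sample_snpchip(founders_small, per_bin=2, rng=rng)
        qtl = assign_qtl(founders_small, "R", 2, markers, rng)
        assert qtl.size == 2 * founders_small.map.n_chrom
        assert np.intersect1d(qtl, markers).size == 0

    def test_dv_subset_of_pool(self, founders_small, rng):
        markers = sample_snpchip(founders_small, per_bin=2, rng=rng)
        pool = sample_dv_pool(founders_small.annotations, rng)
        counts = [40, 40, 40, 40, 12]  # D-subgenome reduction
        qtl = assign_qtl(founders_small, "DV", counts, markers, rng, pool)
        assert qtl.size == sum(counts)
        assert np.all(np.isin(qtl, pool))
        assert np.intersect1d(qtl, markers).size == 0

    def test_dv_qtl_nearer_centromere_than_random(self, founders_small, rng):
        # pericentromeric annotation enrichment pulls DV QTL toward centromeres
        markers = sample_snpchip(founders_small, per_bin=2, rng=rng)
        pos = founders_small.map.all_positions()
        chrom = founders_small.map.chrom_of_locus()
        cen = np.array([c.centromere for c in founders_small.map.chromosomes])
        dist = np.abs(pos - cen[chrom])
        d_dv, d_r = [], []
        for _ in range(60):
            pool = sample_dv_pool(founders_small.annotations, rng)
            dv = assign_qtl(founders_small, "DV", [40, 40, 40, 40, 12], markers, rng, pool)
            r = assign_qtl(founders_small, "R", [40, 40, 40, 40, 12], markers, rng)
            d_dv.append(dist[dv].mean())
            d_r.append(dist[r].mean())
        assert np.mean(d_dv) < np.mean(d_r)

    def test_insufficient_loci_names_chromosome(self, founders_tiny, rng):
        all_loci = np.arange(founders_tiny.n_loci)
        with pytest.raises(ValueError, match="chr"):
            assign_qtl(founders_tiny, "R", 10, all_loci[:-1], rng)


class TestEffectSigns:
    def test_scenario1_all_positive(self, rng):
        eff = assign_effect_signs(rng.standard_normal(500), 1, rng)
        assert np.all(eff > 0)

    def test_scenario4_exact_alternation(self, rng):
        eff = assign_effect_signs(np.ones(200), 4, rng)
        assert np.sum(eff > 0) == 100
        assert np.all(eff[:-1] * eff[1:] < 0)  # adjacent signs alternate

    @pytest.mark.parametrize("scenario,expect", [(2, 2 / 3), (3, 0.5), (5, 1 / 3)])
    def test_random_scenarios_sign_fractions(self, scenario, expect):
        rng = np.random.default_rng(77)
        eff = assign_effect_signs(np.ones(10000), scenario, rng)
        assert np.mean(eff > 0) == pytest.approx(expect, abs=0.02)

    def test_unknown_scenario_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_effect_signs(np.ones(5), 6, rng)

    def test_magnitudes_preserved(self, rng):
        mags = np.abs(rng.standard_normal(100))
        eff = assign_effect_signs(mags, 3, rng)
        np.testing.assert_allclose(np.abs(eff), mags)


class TestStandardization:
    def test_single_inbred_locus_closed_form(self):
        # inbred line frequencies p=q=1/2, a=3: varA = 4pq a^2 = 9 -> a/3 = 1
        pop = Population.from_inbred(np.array([[0], [1]], np.uint8))
        out = standardize_variance(np.array([3.0]), pop, np.array([0]))
        assert out[0] == pytest.approx(1.0)

    def test_resulting_variance_is_one(self, founders_small, rng):
        qtl = np.sort(rng.choice(founders_small.n_loci, 50, replace=False))
        eff = rng.standard_normal(50)
        pop = founders_small.to_population()
        out = standardize_variance(eff, pop, qtl)
        g = pop.doses(qtl).astype(float) @ out
        assert np.var(g) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_and_idempotence(self, founders_small, rng):
        qtl = np.sort(rng.choice(founders_small.n_loci, 30, replace=False))
        eff = rng.standard_normal(30)
        pop = founders_small.to_population()
        once = standardize_variance(eff, pop, qtl)
        np.testing.assert_allclose(standardize_variance(2 * eff, pop, qtl), once)
        np.testing.assert_allclose(standardize_variance(once, pop, qtl), once)

    def test_monomorphic_rejected(self):
        pop = Population.from_inbred(np.ones((4, 3), np.uint8))
        with pytest.raises(ValueError, match="no genetic variance"):
            standardize_variance(np.ones(3), pop, np.arange(3))


class TestGeneticValueAndPhenotype:
    def test_matches_bruteforce_on_toy(self, rng):
        haps = rng.integers(0, 2, size=(6, 2, 5)).astype(np.uint8)
        pop = Population(haps)
        arch = TraitArchitecture(np.arange(5), rng.standard_normal(5))
        g = genetic_values(pop, arch)
        for i in range(6):
            expected = sum(arch.effects[j] * (int(haps[i, 0, j]) + int(haps[i, 1, j]))
                           for j in range(5))
            assert g[i] == pytest.approx(expected)

    def test_zero_error_variance_returns_genetic_value(self, rng):
        pop = Population(rng.integers(0, 2, (10, 2, 4)).astype(np.uint8))
        arch = TraitArchitecture(np.arange(4), np.ones(4))
        model = PhenotypeModel(h2=1.0, sigma2_e=0.0)
        np.testing.assert_array_equal(phenotype(pop, arch, model, rng),
                                      genetic_values(pop, arch))

    def test_error_variance_from_heritability(self):
        assert PhenotypeModel.from_heritability(0.8).sigma2_e == pytest.approx(0.25)
        assert PhenotypeModel.from_heritability(0.2).sigma2_e == pytest.approx(4.0)

    def test_realized_heritability_at_standardization(self, founders_small, rng):
        qtl = np.sort(rng.choice(founders_small.n_loci, 50, replace=False))
        pop = founders_small.to_population()
        eff = standardize_variance(rng.standard_normal(50), pop, qtl)
        arch = TraitArchitecture(qtl, eff)
        big = Population(pop.haplotypes[rng.integers(0, pop.n, 10000)])
        model = PhenotypeModel.from_heritability(0.8, var_a=1.0)
        y = phenotype(big, arch, model, rng)
        g = genetic_values(big, arch)
        slope = np.cov(g, y)[0, 1] / np.var(y)
        assert slope == pytest.approx(0.8, abs=0.05)
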