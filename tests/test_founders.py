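"""Synthetic founder generation, annotation, biparental derivation, reading."""

import io

import numpy as np
import pytest

from recombreed.founders import (annotate_deleterious, derive_biparental,
                                 founders_to_table, generate_founders,
                                 read_founders)
from recombreed.metrics import neighboring_repulsion_fraction


class TestGenerateFounders:
    def test_dimensions_and_structure(self, founders_small):
        fs = founders_small
        assert fs.n_founders == 26
        assert fs.map.n_chrom == 5
        freq = fs.allele_freq()
        assert np.all(freq >= 0.5)  # major allele coded 1
        assert np.all(freq < 1.0)   # no monomorphic loci
        for c in fs.map.chromosomes:
            assert np.all(np.diff(c.positions) > 0)

    def test_coupling_target_reached(self, founders_small):
        frac = neighboring_repulsion_fraction(founders_small)
        assert 0.28 <= frac <= 0.38

    def test_two_founders_frequency_half(self):
        fs = generate_founders(n_founders=2, n_chrom=2, mean_length=1.0,
                               snp_density=100, coupling_target=0.4, seed=5)
        np.testing.assert_allclose(fs.allele_freq(), 0.5)

    def test_determinism(self):
        a = generate_founders(n_chrom=2, snp_density=100, seed=42)
        b = generate_founders(n_chrom=2, snp_density=100, seed=42)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.map == b.map
        assert np.array_equal(a.annotations.high_impact, b.annotations.high_impact)

    def test_repulsion_monotone_in_target(self):
        # averaged over seeds, realized repulsion follows the request
        means = []
        for target in (0.1, 0.3, 0.5):
            fracs = [neighboring_repulsion_fraction(
                generate_founders(n_founders=20, n_chrom=2, snp_density=150,
                                  coupling_target=target, seed=s, annotate=False))
                for s in range(20)]
            means.append(np.mean(fracs))
        assert means[0] < means[1] < means[2]

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_founders(coupling_target=1.5)
        with pytest.raises(ValueError):
            generate_founders(n_founders=1)
        with pytest.raises(ValueError):
            generate_founders(snp_density=5)


class TestAnnotateDeleterious:
    def test_enrichment_ratio(self, founders_small):
        # moderate flag fractions so the window cannot saturate
        ann = annotate_deleterious(founders_small, pericentromere_enrichment=3,
                                   seed=7, high_fraction=0.12, nonsyn_fraction=0.05)
        ratios = []
        for ci, c in enumerate(founders_small.map.chromosomes):
            if founders_small.genome_group[ci] == "D":
                continue
            sl = founders_small.map.chrom_slice(ci)
            fl = (ann.high_impact | ann.nonsynonymous)[sl]
            inside = (c.positions >= c.window[0]) & (c.positions <= c.window[1])
            w = c.window[1] - c.window[0]
            ratios.append((fl[inside].sum() / w) / (fl[~inside].sum() / (c.length - w)))
        assert 2.4 <= np.mean(ratios) <= 3.6

    def test_no_enrichment_gives_uniform_density(self, founders_small):
        ann = annotate_deleterious(founders_small, pericentromere_enrichment=1,
                                   seed=7, high_fraction=0.2, nonsyn_fraction=0.1)
        c = founders_small.map.chromosomes[0]
        sl = founders_small.map.chrom_slice(0)
        fl = (ann.high_impact | ann.nonsynonymous)[sl]
        inside = (c.positions >= c.window[0]) & (c.positions <= c.window[1])
        w = c.window[1] - c.window[0]
        ratio = (fl[inside].sum() / w) / (fl[~inside].sum() / (c.length - w))
        assert 0.7 <= ratio <= 1.4

    def test_classes_mutually_exclusive(self, founders_small):
        ann = founders_small.annotations
        assert not np.any(ann.high_impact & ann.nonsynonymous)

    def test_d_genome_reduced_density(self, founders_small):
        ann = founders_small.annotations
        chrom = founders_small.map.chrom_of_locus()
        groups = np.array(founders_small.genome_group)
        flags = ann.high_impact | ann.nonsynonymous
        per = np.array([flags[chrom == i].mean() for i in range(5)])
        d_mean = per[groups == "D"].mean()
        ab_mean = per[groups != "D"].mean()
        assert d_mean == pytest.approx(0.3 * ab_mean, rel=0.2)

    def test_enrichment_below_one_rejected(self, founders_small):
        with pytest.raises(ValueError):
            annotate_deleterious(founders_small, pericentromere_enrichment=0.5)


class TestDeriveBiparental:
    def test_pair_matches_brute_force(self, founders_tiny):
        fs = founders_tiny
        g = fs.genotypes.astype(int)
        best, pair = -1, None
        for i in range(fs.n_founders):
            for j in range(i + 1, fs.n_founders):
                d = int((g[i] != g[j]).sum())
                if d > best:
                    best, pair = d, (i, j)
        bp = derive_biparental(fs)
        assert set(bp.labels) == {fs.labels[pair[0]], fs.labels[pair[1]]}
        assert bp.n_loci == best  # exactly the differing loci retained
        assert bp.n_loci < fs.n_loci

    def test_duplicates_never_chosen(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(1, 60)).astype(np.uint8)
        div = 1 - base
        from recombreed.genmap import GeneticMap, make_chromosome
        from recombreed.populations import FounderSet
        geno = np.concatenate([base, base, div], axis=0)  # founders 0,1 identical
        fs = FounderSet(geno, GeneticMap([make_chromosome(
            np.linspace(0.01, 0.99, 60), length=1.0)]))
        bp = derive_biparental(fs)
        assert sorted(bp.labels) != sorted(fs.labels[[0, 1]])

    def test_first_parent_codes_one(self, founders_tiny):
        bp = derive_biparental(founders_tiny)
        assert np.all(bp.genotypes[0] == 1)
        assert np.all(bp.genotypes[1] == 0)


class TestReadFounders:
    def header(self, names=("f1", "f2", "f3", "f4")):
        return "id,chromosome,position," + ",".join(names)

    def test_filters_applied_in_order(self, tmp_path):
        # 10 loci: 3 with 75% missing, 1 monomorphic -> 6 retained
        rows = [self.header()]
        for i in range(6):
            rows.append(f"L{i},1,0.{i + 1},0,1,0,1")
        for i in range(6, 9):
            rows.append(f"L{i},2,0.{i - 5},NA,NA,NA,0")
        rows.append("L9,2,0.9,1,1,1,1")
        p = tmp_path / "geno.csv"
        p.write_text("\n".join(rows) + "\n")
        fs = read_founders(p)
        assert fs.n_loci == 6

    def test_majority_recode(self, tmp_path):
        # allele B carried by 3 of 4 founders -> coded 1
        p = tmp_path / "geno.csv"
        p.write_text(self.header() + "\nL0,1,0.1,A,B,B,B\nL1,1,0.2,B,A,A,A\n")
        fs = read_founders(p)
        np.testing.assert_array_equal(fs.genotypes[:, 0], [0, 1, 1, 1])
        np.testing.assert_array_equal(fs.genotypes[:, 1], [0, 1, 1, 1])

    def test_all_monomorphic_rejected(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(self.header() + "\nL0,1,0.1,1,1,1,1\n")
        with pytest.raises(ValueError, match="no polymorphic"):
            read_founders(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(self.header() + "\nL0,1,0.1,0,1,0,1\nL0,1,0.2,0,1,0,1\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_founders(p)

    def test_unsorted_positions_rejected(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(self.header() + "\nL0,1,0.5,0,1,0,1\nL1,1,0.1,1,0,1,0\n")
        with pytest.raises(ValueError, match="not sorted"):
            read_founders(p)

    def test_reader_idempotent_on_own_output(self, founders_tiny):
        fs1 = read_founders(io.StringIO(founders_to_table(founders_tiny)))
        fs2 = read_founders(io.StringIO(founders_to_table(fs1)))
        assert np.array_equal(fs1.genotypes, fs2.genotypes)
        assert fs1.map == fs2.map


class TestSerialization:
    def test_archive_roundtrip(self, founders_tiny, tmp_path):
        path = tmp_path / "founders.npz"
        founders_tiny.save(path)
        from recombreed.populations import FounderSet
        back = FounderSet.load(path)
        assert np.array_equal(back.genotypes, founders_tiny.genotypes)
        assert back.map == founders_tiny.map
        assert np.array_equal(back.annotations.high_impact,
                              founders_tiny.annotations.high_impact)
        assert back.genome_group == founders_tiny.genome_group
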