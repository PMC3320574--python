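"""Virtual genome and structured population generator."""

import numpy as np
import pytest

from cgpgwas.popgen import (
    ConfigurationError,
    GenomeLayout,
    HaplotypePanel,
    PopulationConfig,
    balding_nichols_freqs,
    build_layout,
    encode_genotypes,
    evolve_population,
    generate_population,
    sample_founders,
)


class TestLayout:
    def test_default_grid_has_40000_loci(self):
        layout = build_layout(20, 2000, 5000, 1.0)
        assert layout.n_loci == 40_000
        assert layout.n_chromosomes == 20

    def test_single_locus_genetic_position(self):
        layout = build_layout(1, 1, 5000, 1.0)
        assert layout.n_loci == 1
        # one locus at position 0; a hypothetical neighbour at 5000 bp would
        # sit at 0.005 cM under 1 cM/Mb
        assert layout.genetic_map_cm[0] == 0.0
        assert build_layout(1, 2, 5000, 1.0).genetic_map_cm[1] == pytest.approx(0.005)

    def test_per_chromosome_grid(self):
        layout = build_layout(2, 3, 5000, 1.0)
        for sl in layout.chrom_slices():
            assert list(layout.positions_bp[sl]) == [0, 5000, 10000]

    @pytest.mark.parametrize("args", [(0, 10, 5000, 1.0), (2, 10, -1, 1.0), (2, 0, 5000, 1.0)])
    def test_nonpositive_arguments_rejected(self, args):
        with pytest.raises(ConfigurationError):
            build_layout(*args)

    def test_positions_strictly_increasing_within_chromosome(self):
        layout = build_layout(3, 50, 1000, 0.5)
        for sl in layout.chrom_slices():
            assert np.all(np.diff(layout.positions_bp[sl]) > 0)
            assert np.all(np.diff(layout.genetic_map_cm[sl]) >= 0)


class TestFounders:
    def test_fst_zero_keeps_ancestral_frequencies(self, rng):
        p = rng.uniform(0.05, 0.95, 200)
        sub = balding_nichols_freqs(p, 0.0, 5, rng)
        assert np.array_equal(sub, np.broadcast_to(p, (5, 200)))

    def test_balding_nichols_variance_matches_moment_formula(self, rng):
        # Var over subpopulation draws should be fst * p * (1-p)
        p = np.full(2000, 0.5)
        sub = balding_nichols_freqs(p, 0.1, 1, rng)  # 2000 independent draws
        var = np.var(sub)
        assert var == pytest.approx(0.1 * 0.25, rel=0.10)

    def test_ld_corr_zero_gives_independent_loci(self, small_layout):
        cfg = PopulationConfig(n_final=600, n_subpops=1, fst=0.0, seed=5)
        panel = sample_founders(small_layout, 600, cfg, ld_corr=0.0)
        h = panel.haplotypes[:, :100].astype(float)
        hc = (h - h.mean(0)) / h.std(0)
        r = (hc[:, :-1] * hc[:, 1:]).mean(0)
        assert np.mean(r**2) < 5.0 / h.shape[0]

    def test_ld_decays_with_distance(self, small_layout):
        # mean squared haplotype correlation non-increasing in lag
        cfg = PopulationConfig(n_final=800, n_subpops=1, fst=0.0, seed=6)
        panel = sample_founders(small_layout, 800, cfg, ld_corr=0.7)
        h = panel.haplotypes[:, :300].astype(float)  # one chromosome, 300 loci
        hc = (h - h.mean(0)) / h.std(0)
        mean_r2 = []
        for k in range(1, 6):
            r = (hc[:, :-k] * hc[:, k:]).mean(0)
            mean_r2.append(np.mean(r**2))
        assert all(a >= b - 1e-3 for a, b in zip(mean_r2, mean_r2[1:]))
        assert mean_r2[0] > 10 * mean_r2[-1]

    def test_ld_corr_out_of_range_rejected(self, small_layout):
        cfg = PopulationConfig(n_final=100, n_subpops=2, seed=0)
        with pytest.raises(ConfigurationError):
            sample_founders(small_layout, 100, cfg, ld_corr=1.0)

    def test_maf_floor_respected_in_ancestral_pool(self, small_layout):
        cfg = PopulationConfig(n_final=100, n_subpops=2, maf_floor=0.2, seed=3)
        panel = sample_founders(small_layout, 100, cfg)
        assert panel.ancestral_freqs.min() >= 0.2
        assert panel.ancestral_freqs.max() <= 0.8

    def test_every_subpopulation_nonempty(self, small_layout):
        cfg = PopulationConfig(n_final=23, n_subpops=5, seed=1)
        panel = sample_founders(small_layout, 23, cfg)
        assert len(np.unique(panel.subpop_assignment)) == 5


class TestEvolve:
    def test_zero_generations_is_identity(self, small_layout):
        cfg = PopulationConfig(n_final=60, n_subpops=2, generations=0, seed=9)
        panel = sample_founders(small_layout, 60, cfg)
        out = evolve_population(panel, small_layout, cfg)
        assert out is panel

    def test_final_census_matches_config(self, small_layout):
        cfg = PopulationConfig(n_final=50, n_subpops=2, generations=4,
                               mutation_rate=0.0, seed=9)
        panel = sample_founders(small_layout, 20, cfg)
        out = evolve_population(panel, small_layout, cfg)
        assert out.n_individuals == 50
        assert out.haplotypes.shape == (100, small_layout.n_loci)

    def test_drift_stays_within_wright_fisher_bound(self, small_layout):
        # closed single population, no mutation: frequency change over G
        # generations bounded by the accumulated binomial sampling variance
        n, gens = 200, 10
        cfg = PopulationConfig(n_final=n, n_subpops=1, generations=gens,
                               mutation_rate=0.0, migration_rate=0.0,
                               fst=0.0, seed=77)
        panel = sample_founders(small_layout, n, cfg)
        f0 = panel.haplotypes.mean(0)
        out = evolve_population(panel, small_layout, cfg)
        f1 = out.haplotypes.mean(0)
        # per-locus accumulated sd ~ sqrt(G * p q / 2N); 5-sigma bound on the
        # RMS change over 600 loci
        sd = np.sqrt(gens * f0 * (1 - f0) / (2 * n))
        assert np.sqrt(np.mean((f1 - f0) ** 2)) < 5 * np.sqrt(np.mean(sd**2))

    def test_migration_homogenizes_subpopulations(self):
        # with fst>0 founders, migration and no mutation, the between-subpop
        # frequency spread shrinks in expectation
        layout = build_layout(1, 60, 5000, 1.0)
        spreads0, spreads1 = [], []
        for rep in range(3):
            cfg = PopulationConfig(n_final=120, n_subpops=3, generations=12,
                                   mutation_rate=0.0, migration_rate=0.2,
                                   fst=0.3, seed=100 + rep)
            panel = sample_founders(layout, 120, cfg)
            out = evolve_population(panel, layout, cfg)
            for p, take in ((panel, spreads0), (out, spreads1)):
                freqs = np.stack([
                    p.haplotypes[np.repeat(p.subpop_assignment == s, 2)].mean(0)
                    for s in range(3)
                ])
                take.append(np.mean(np.var(freqs, axis=0)))
        assert np.mean(spreads1) < np.mean(spreads0)


class TestEncoding:
    def _panel(self, haps, labels=None):
        haps = np.asarray(haps, dtype=np.uint8)
        n = haps.shape[0] // 2
        return HaplotypePanel(
            haplotypes=haps,
            subpop_assignment=np.zeros(n, dtype=int) if labels is None else labels,
            ancestral_freqs=haps.mean(0),
        )

    def test_coding_against_major_allele(self):
        # allele 1 at frequency 0.7 -> 1/1 coded +1, 0/1 -> 0, 0/0 -> -1
        col = [1, 1, 0, 0, 0, 1, 1, 1, 1, 1]  # pairs: 1/1, 0/0, 0/1, 1/1, 1/1
        panel = self._panel(np.array([col]).T)
        gm = encode_genotypes(panel)
        assert list(gm.codes[:, 0]) == [1, -1, 0, 1, 1]
        assert gm.allele_freqs[0] == pytest.approx(0.7)
        assert gm.major_is_allele1[0]

    def test_tie_designates_allele0_major(self):
        panel = self._panel(np.array([[1, 0, 1, 0]]).T)  # f1 = 0.5
        gm = encode_genotypes(panel)
        assert not gm.major_is_allele1[0]
        assert gm.allele_freqs[0] == 0.5

    def test_monomorphic_locus_flagged_untestable(self):
        panel = self._panel(np.array([[1, 1, 1, 1]]).T)
        gm = encode_genotypes(panel)
        assert np.all(gm.codes[:, 0] == 1)
        assert gm.untestable[0]

    def test_odd_haplotype_count_rejected(self):
        panel = self._panel(np.zeros((3, 4), dtype=np.uint8)[:3])
        panel.subpop_assignment = np.zeros(1, dtype=int)
        with pytest.raises(ValueError):
            encode_genotypes(panel)

    def test_coding_round_trip(self, small_population):
        # decode codes to major-allele copy counts, rebuild haplotypes,
        # re-encode: identity on codes and frequencies
        gm = small_population
        counts = gm.codes.astype(int) + 1   # copies of the major allele
        raw_copies = np.where(gm.major_is_allele1, counts, 2 - counts)
        h0 = (raw_copies >= 1).astype(np.uint8)
        h1 = (raw_copies == 2).astype(np.uint8)
        haps = np.empty((2 * gm.n_individuals, gm.n_loci), dtype=np.uint8)
        haps[0::2], haps[1::2] = h0, h1
        gm2 = encode_genotypes(
            HaplotypePanel(haps, gm.subpop_labels, gm.allele_freqs)
        )
        assert np.array_equal(gm2.codes, gm.codes)
        assert np.allclose(gm2.allele_freqs, gm.allele_freqs)

    def test_allele_frequency_consistency(self, small_population):
        # freq(+1) + freq(0)/2 equals the stored major-allele frequency
        gm = small_population
        n = gm.n_individuals
        f_hom = (gm.codes == 1).sum(0) / n
        f_het = (gm.codes == 0).sum(0) / n
        assert np.allclose(f_hom + 0.5 * f_het, gm.allele_freqs)


class TestGeneratePopulation:
    def test_fast_mode_census_and_coding(self, small_population):
        gm = small_population
        assert gm.n_individuals == 400
        assert set(np.unique(gm.codes)) <= {-1, 0, 1}
        assert gm.allele_freqs.min() >= 0.5

    def test_evolved_mode_runs_on_tiny_scale(self):
        layout = build_layout(1, 40, 5000, 1.0)
        cfg = PopulationConfig(n_final=30, n_subpops=2, generations=3,
                               mutation_rate=1e-4, seed=8)
        gm = generate_population(layout, cfg, fast=False)
        assert gm.n_individuals == 30
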