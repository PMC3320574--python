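"""Build a structured virtual population and inspect its genetic structure.

Generates a small version of the default genome (2 chromosomes x 1,000 SNPs)
for 1,000 individuals in 5 subpopulations, then prints the allele-frequency
spectrum and the decay of linkage disequilibrium with distance, and writes
PLINK ped/map files.
"""

import numpy as np

from cgpgwas import PopulationConfig, build_layout, generate_population
from cgpgwas.plinkio import write_ped_map

layout = build_layout(n_chrom=2, loci_per_chrom=1000, spacing_bp=5000)
config = PopulationConfig(n_final=1000, n_subpops=5, seed=42)
G = generate_population(layout, config, ld_corr=0.7, fast=True)

print(f"population: {G.n_individuals} individuals x {G.n_loci} SNPs, "
      f"{len(np.unique(G.subpop_labels))} subpopulations")
print(f"major-allele frequency: median {np.median(G.allele_freqs):.3f}, "
      f"range [{G.allele_freqs.min():.3f}, {G.allele_freqs.max():.3f}]")

# LD decay: mean squared genotype correlation at increasing locus lag
codes = G.codes[:, :400].astype(float)
z = (codes - codes.mean(0)) / codes.std(0)
for lag in (1, 2, 5, 10):
    r = (z[:, :-lag] * z[:, lag:]).mean(0)
    print(f"mean r^2 at lag {lag} (~{5 * lag} kb): {np.mean(r ** 2):.4f}")

write_ped_map("scratch_population", G, layout)
print("wrote scratch_population.ped / .map (PLINK text format)")
print("\nAdjacent SNPs are strongly correlated and the correlation decays to"
      "\nthe noise floor within a few loci, as in an ascertained common-SNP"
      "\npanel; the frequency spectrum is bounded away from 0.5 only by the"
      "\nascertainment floor.")
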