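"""Synthetic structured population with common-SNP allele frequencies and LD.

The virtual genome is a grid of evenly spaced biallelic SNPs on 20
autosome-like chromosomes.  Founder haplotypes come from a generative model
chosen to emulate an ascertained common-SNP panel drawn from several human
subpopulations:

* ancestral allele frequencies are uniform on [maf_floor, 1 - maf_floor]
  (common-SNP ascertainment);
* per-subpopulation frequencies diverge from the ancestral ones under a
  Balding-Nichols (beta) model with a given FST;
* within a subpopulation, haplotype alleles form a first-order Markov chain
  along each chromosome so adjacent loci have correlation ~ ld_corr, decaying
  multiplicatively with distance (classic exponential LD decay).

The founder panel can optionally be expanded forward in time (random mating
within subpopulations, island-model migration, Poisson recombination on the
genetic map, symmetric diallelic mutation) before genotypes are encoded as
{-1, 0, +1} relative to the most frequent allele at each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomeLayout",
    "PopulationConfig",
    "HaplotypePanel",
    "GenotypeMatrix",
    "build_layout",
    "sample_founders",
    "evolve_population",
    "encode_genotypes",
    "generate_population",
]


class ConfigurationError(ValueError):
    """Invalid genome / population configuration."""


@dataclass(frozen=True)
class GenomeLayout:
    """Positions of the SNP grid.

    Attributes
    ----------
    n_chromosomes, loci_per_chromosome : int
        Grid shape; total loci = product of the two.
    chrom : ndarray of int
        Chromosome index (0-based) per locus.
    positions_bp : ndarray of int
        Physical position per locus, strictly increasing within a chromosome.
    genetic_map_cm : ndarray of float
        Genetic position (cM) per locus, monotone within a chromosome.
    """

    n_chromosomes: int
    loci_per_chromosome: int
    chrom: np.ndarray
    positions_bp: np.ndarray
    genetic_map_cm: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    def chrom_slices(self) -> list[slice]:
        """Contiguous locus slice per chromosome."""
        L = self.loci_per_chromosome
        return [slice(c * L, (c + 1) * L) for c in range(self.n_chromosomes)]


@dataclass(frozen=True)
class PopulationConfig:
    """Demography and rates for the virtual population.

    Defaults describe the study population: 11 subpopulations diverged at
    FST 0.1 from a common ancestral pool, expanded to 5,000 individuals over
    500 generations with mutation rate 1e-8 and island-model migration 0.001.
    """

    n_final: int = 5000
    n_subpops: int = 11
    generations: int = 500
    mutation_rate: float = 1e-8
    migration_rate: float = 0.001
    fst: float = 0.1
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("mutation_rate", "migration_rate", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.generations < 0:
            raise ConfigurationError("generations must be >= 0")
        if not 0.0 < self.maf_floor < 0.5:
            raise ConfigurationError("maf_floor must lie in (0, 0.5)")
        if self.n_subpops < 1 or self.n_final < self.n_subpops:
            raise ConfigurationError("need n_final >= n_subpops >= 1")


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, two per individual.

    haplotypes[2*i] and haplotypes[2*i + 1] belong to individual i.
    """

    haplotypes: np.ndarray            # (2N, L) uint8 in {0, 1}
    subpop_assignment: np.ndarray     # (N,) int
    ancestral_freqs: np.ndarray       # (L,) allele-1 frequency in the ancestral pool
    subpop_freqs: np.ndarray | None = None  # (n_subpops, L), generator bookkeeping

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class GenotypeMatrix:
    """Genotypes coded relative to the most frequent allele per locus.

    codes[i, j] is +1 when individual i is homozygous for the major allele at
    locus j, 0 when heterozygous, -1 when homozygous for the minor allele.
    """

    codes: np.ndarray                 # (N, L) int8 in {-1, 0, 1}
    allele_freqs: np.ndarray          # (L,) major-allele frequency, >= 0.5
    subpop_labels: np.ndarray         # (N,) int
    major_is_allele1: np.ndarray      # (L,) bool, which raw allele is major
    untestable: np.ndarray            # (L,) bool, monomorphic loci

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]


def build_layout(
    n_chrom: int = 20,
    loci_per_chrom: int = 2000,
    spacing_bp: float = 5000,
    cm_per_mb: float = 1.0,
) -> GenomeLayout:
    """Evenly spaced SNP grid with a uniform genetic map.

    Genetic positions are physical positions times ``cm_per_mb`` (default
    1 cM/Mb), restarting from zero on each chromosome.
    """
    if min(n_chrom, loci_per_chrom) < 1 or spacing_bp <= 0 or cm_per_mb <= 0:
        raise ConfigurationError("all layout arguments must be positive")
    per_chrom_bp = np.arange(loci_per_chrom, dtype=np.int64) * int(spacing_bp)
    positions = np.tile(per_chrom_bp, n_chrom)
    chrom = np.repeat(np.arange(n_chrom), loci_per_chrom)
    gmap = positions * (cm_per_mb / 1e6)
    return GenomeLayout(n_chrom, loci_per_chrom, chrom, positions, gmap.astype(float))


def balding_nichols_freqs(
    ancestral: np.ndarray, fst: float, n_subpops: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-subpopulation allele frequencies diverged from ancestral ones.

    Draws Beta(p(1-F)/F, (1-p)(1-F)/F) per locus and subpopulation, which has
    mean p and variance F p (1-p).  fst=0 returns the ancestral frequencies.
    """
    if fst == 0.0:
        return np.broadcast_to(ancestral, (n_subpops, ancestral.size)).copy()
    c = (1.0 - fst) / fst
    return rng.beta(ancestral * c, (1.0 - ancestral) * c, size=(n_subpops, ancestral.size))


def _markov_haplotypes(
    freqs: np.ndarray,
    n_hap: int,
    layout: GenomeLayout,
    ld_corr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov haplotypes with adjacent-locus correlation ld_corr.

    Conditional mean E[x_{j+1} | x_j] = p_{j+1} + rho * sqrt(p'q'/pq) (x_j - p_j)
    yields correlation rho between adjacent allele indicators; chaining makes
    the correlation decay as rho**k over k steps.  Probabilities are clipped
    to [0, 1] where marginal heterogeneity makes the pair infeasible.
    """
    L = layout.n_loci
    out = np.empty((n_hap, L), dtype=np.uint8)
    base_gap = float(np.median(np.diff(layout.positions_bp[: layout.loci_per_chromosome]))) \
        if layout.loci_per_chromosome > 1 else 1.0
    for sl in layout.chrom_slices():
        p = freqs[sl]
        n_loc = p.size
        u = rng.random((n_hap, n_loc))
        x = np.empty((n_hap, n_loc), dtype=np.uint8)
        x[:, 0] = u[:, 0] < p[0]
        gaps = np.diff(layout.positions_bp[sl]).astype(float)
        if ld_corr > 0.0:
            rhos = ld_corr ** (gaps / base_gap)
        else:
            rhos = np.zeros_like(gaps)
        sd = np.sqrt(p * (1.0 - p))
        for j in range(1, n_loc):
            rho = rhos[j - 1]
            if rho == 0.0 or sd[j - 1] == 0.0:
                prob = p[j]
                x[:, j] = u[:, j] < prob
                continue
            slope = rho * sd[j] / sd[j - 1]
            prob = np.clip(p[j] + slope * (x[:, j - 1] - p[j - 1]), 0.0, 1.0)
            x[:, j] = u[:, j] < prob
        out[:, sl] = x
    return out


def _equal_subpop_sizes(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    return sizes


def sample_founders(
    layout: GenomeLayout,
    n_founders: int,
    config: PopulationConfig,
    ld_corr: float = 0.7,
    rng: np.random.Generator | None = None,
) -> HaplotypePanel:
    """Founder panel: Balding-Nichols subpopulation frequencies + Markov LD.

    Subpopulation sizes are equal (within rounding).  ``ld_corr`` is the
    target correlation between allele indicators at adjacent loci.
    """
    if not 0.0 <= ld_corr < 1.0:
        raise ConfigurationError(f"ld_corr={ld_corr} outside [0, 1)")
    if n_founders < 2 * config.n_subpops:
        raise ConfigurationError("need at least 2 founders per subpopulation")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = layout.n_loci
    ancestral = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=L)
    sub_freqs = balding_nichols_freqs(ancestral, config.fst, config.n_subpops, rng)
    sizes = _equal_subpop_sizes(n_founders, config.n_subpops)
    haps = np.empty((2 * n_founders, L), dtype=np.uint8)
    labels = np.repeat(np.arange(config.n_subpops), sizes)
    row = 0
    for s, n_s in enumerate(sizes):
        haps[row : row + 2 * n_s] = _markov_haplotypes(sub_freqs[s], 2 * n_s, layout, ld_corr, rng)
        row += 2 * n_s
    return HaplotypePanel(haps, labels, ancestral, sub_freqs)


def _meiosis(
    h0: np.ndarray,
    h1: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: Poisson crossovers on the genetic map, no interference."""
    gamete = np.empty_like(h0)
    for sl in layout.chrom_slices():
        cm = layout.genetic_map_cm[sl]
        length_morgan = (cm[-1] - cm[0]) / 100.0 if cm.size > 1 else 0.0
        n_x = rng.poisson(length_morgan)
        current = rng.integers(0, 2)
        if n_x == 0:
            gamete[sl] = h0[sl] if current == 0 else h1[sl]
            continue
        cuts = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
        # phase index per locus: parity of crossovers to the left
        phase = (current + np.searchsorted(cuts, cm, side="right")) % 2
        seg = np.where(phase == 0, h0[sl], h1[sl])
        gamete[sl] = seg
    return gamete


def _census_schedule(n0: int, n_final: int, generations: int) -> np.ndarray:
    """Geometric interpolation of the census from n0 to n_final."""
    if generations == 0:
        return np.array([], dtype=int)
    g = np.arange(1, generations + 1)
    sizes = np.round(n0 * (n_final / n0) ** (g / generations)).astype(int)
    sizes[-1] = n_final
    return sizes


def evolve_population(
    panel: HaplotypePanel,
    layout: GenomeLayout,
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> HaplotypePanel:
    """Forward-in-time expansion of the founder panel.

    Each generation: the census follows a geometric schedule towards
    ``n_final``; offspring counts per subpopulation keep the subpopulation
    proportions (so no subpopulation can empty); each parent is drawn from the
    offspring's own subpopulation, except with probability ``migration_rate``
    from a uniformly random other subpopulation (island model); gametes
    recombine as a Poisson crossover process on the genetic map; symmetric
    diallelic mutation flips alleles at ``mutation_rate`` per site per gamete.

    With ``generations=0`` the founder panel is returned unchanged.
    """
    if panel.n_individuals == 0:
        raise ConfigurationError("empty founder panel")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.generations == 0:
        return panel

    haps = panel.haplotypes
    labels = panel.subpop_assignment
    k = config.n_subpops
    schedule = _census_schedule(panel.n_individuals, config.n_final, config.generations)
    for n_next in schedule:
        sizes = _equal_subpop_sizes(n_next, k)
        members = [np.flatnonzero(labels == s) for s in range(k)]
        new_haps = np.empty((2 * n_next, haps.shape[1]), dtype=np.uint8)
        new_labels = np.repeat(np.arange(k), sizes)
        child = 0
        for s, n_s in enumerate(sizes):
            for _ in range(n_s):
                for h_slot in range(2):
                    src = s
                    if k > 1 and rng.random() < config.migration_rate:
                        src = (s + 1 + rng.integers(0, k - 1)) % k
                    parent = members[src][rng.integers(0, members[src].size)]
                    gam = _meiosis(haps[2 * parent], haps[2 * parent + 1], layout, rng)
                    new_haps[2 * child + h_slot] = gam
                child += 1
        if config.mutation_rate > 0.0:
            n_mut = rng.poisson(config.mutation_rate * new_haps.size)
            if n_mut:
                ii = rng.integers(0, new_haps.shape[0], size=n_mut)
                jj = rng.integers(0, new_haps.shape[1], size=n_mut)
                new_haps[ii, jj] ^= 1
        haps, labels = new_haps, new_labels
    return HaplotypePanel(haps, labels, panel.ancestral_freqs, panel.subpop_freqs)


def encode_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Code genotypes as {-1, 0, +1} relative to the most frequent allele.

    The major allele is determined in the final population; a tie at
    frequency 0.5 designates allele 0 as major.  Monomorphic loci are coded
    +1 for everyone and flagged untestable.
    """
    haps = panel.haplotypes
    if haps.shape[0] % 2:
        raise ValueError("odd haplotype count: panel is not diploid-complete")
    f1 = haps.mean(axis=0)
    major_is_allele1 = f1 > 0.5          # tie (0.5) -> allele 0 is major
    major_freq = np.where(major_is_allele1, f1, 1.0 - f1)
    h0 = haps[0::2]
    h1 = haps[1::2]
    match0 = np.where(major_is_allele1, h0, 1 - h0)
    match1 = np.where(major_is_allele1, h1, 1 - h1)
    codes = (match0 + match1 - 1).astype(np.int8)
    untestable = (f1 == 0.0) | (f1 == 1.0)
    return GenotypeMatrix(
        codes=codes,
        allele_freqs=major_freq,
        subpop_labels=panel.subpop_assignment.copy(),
        major_is_allele1=major_is_allele1,
        untestable=untestable,
    )


def generate_population(
    layout: GenomeLayout,
    config: PopulationConfig,
    ld_corr: float = 0.7,
    fast: bool = True,
) -> GenotypeMatrix:
    """End-to-end population: founders (+ optional forward expansion) -> codes.

    ``fast=True`` samples the final census directly from the founder model,
    skipping forward evolution; the frequency and LD structure downstream
    analyses depend on is the same, at a fraction of the cost.
    """
    rng = np.random.default_rng(config.seed)
    if fast:
        panel = sample_founders(layout, config.n_final, config, ld_corr, rng)
    else:
        n0 = max(2 * config.n_subpops, min(1301, config.n_final))
        panel = sample_founders(layout, n0, config, ld_corr, rng)
        panel = evolve_population(panel, layout, config, rng)
    return encode_genotypes(panel)
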