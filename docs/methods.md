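# Methods

`cgpgwas` is an in-silico systems-genetics pipeline built around one idea:
if a dynamic model describes a cellular trait, the genetic variation behind
that trait must surface as variation in the model's parameters, and a GWAS
run directly on parameter values ("parameters as phenotypes") recovers far
more of that variation than a GWAS on the emergent cellular phenotypes.
The pipeline simulates the whole causal chain — genome, population,
genotype-to-parameter map, paced heart cell, phenotype extraction, QC,
association, prediction, sensitivity analysis — so the claim can be measured
rather than argued.

## Virtual genome and population

The genome is a grid of 20 chromosomes x 2,000 biallelic SNPs at 5,000 bp
spacing (40,000 loci), with a uniform 1 cM/Mb genetic map. Founders come
from a generative model of an ascertained common-SNP panel:

* ancestral allele frequencies uniform on `[maf_floor, 1 - maf_floor]`
  (default floor 0.05, mimicking common-SNP ascertainment);
* per-subpopulation frequencies drawn from a Balding–Nichols beta
  distribution around the ancestral frequency with divergence `fst`
  (default 0.1, 11 subpopulations of equal size);
* within a subpopulation, haplotype alleles form a first-order Markov chain
  along each chromosome targeting correlation `ld_corr = 0.7` between
  adjacent allele indicators, decaying multiplicatively with distance.

Two caveats are worth stating plainly. First, with heterogeneous marginal
frequencies the maximum achievable correlation between two binary indicators
is bounded (Fréchet), so the *realized* mean adjacent-locus correlation is
~0.5 rather than 0.7; the exponential decay shape is preserved, and
within-subpopulation LD reaches the sampling-noise floor by about five loci.
Second, because each locus's subpopulation divergence is drawn
independently, the pooled population carries ancestry-LD: a purely genetic
trait acquires roughly `2*fst/(1+2*fst)` ≈ 17% between-subpopulation
variance, and unlinked SNPs whose divergence profile aligns with the trait's
can reach genome-wide significance. This raises the parameter-level
discovery rate and especially the false-positive rate relative to a
panmictic population (see Limitations).

Forward expansion (random mating within subpopulations, island-model
migration at 0.001 per generation, Poisson recombination on the genetic map,
symmetric diallelic mutation at 1e-8, geometric census growth to 5,000 over
500 generations) is implemented and tested, but the default "fast mode"
samples the final census directly from the founder model: the downstream
statistics depend on the frequency/LD structure, not on the expansion
history, and fast mode makes a full study-scale run take seconds rather than
hours. Genotypes are coded per locus as +1 (homozygous major allele), 0
(heterozygous), −1 (homozygous minor), with ties at frequency 0.5 broken
toward the lower allele index, and monomorphic loci flagged untestable.

## Genotype-to-parameter map

Each model parameter receives `n_causal` causal SNPs sampled uniformly
without replacement — disjoint across parameters by default, so 34 x 400
causal sets cover exactly 13,600 loci. Causal relative effects are i.i.d.
Laplace with mean 0 and standard deviation 0.0035 (scale = sd/√2); the
200-causal-SNP design uses sd 0.0049, which keeps the total parametric
variance essentially unchanged (400·0.0035² ≈ 200·0.0049²). Individual
parameter values are `p(GE + 1)`: the baseline times one plus the
genotype-weighted sum of relative effects. The map is exactly linear in G;
an individual heterozygous at every causal locus of a parameter sits exactly
on the baseline. Mapped values are never clamped; a non-positive value for a
positive-baseline parameter flags the individual as a failure candidate.
Under the default population this yields per-parameter variation of a few
percent (sd) with heavy Laplace tails; the median over parameters of the
maximum absolute relative deviation across 5,000 individuals is ~20%,
within the intended tens-of-percent regime.

Each Monte Carlo run redraws causal sets and effects; the population is
reused across runs (regeneration is a config switch away).

## Heart-cell surrogate

The forward map from parameters to cellular dynamics is a 4-state paced
cell: a Mitchell–Schaeffer-type excitation pair (v, h) and a two-compartment
calcium cycle (Cai, CaSR) with ryanodine-receptor release triggered by v,
SERCA uptake, SR leak, Na/Ca-exchanger and sarcolemmal-pump efflux, and
rapid-buffer factors for cytosolic calmodulin and SR calsequestrin (the full
equations are in the `cellmodel` module docstring). Voltage is reported
through the affine map Vm = −80 + 118·v mV, so `apbase` is fixed at −80 mV
and carries no genetic variance — a known, deliberate deviation from the
full model, whose apbase range is itself under 1.5 mV. Seventeen parameters
carry genetic variation, named for the ion-channel/pump roles they shadow
(gNa, gK1, gKto, gKur, tau_open, tau_close, v_gate, krel, v_rel, Vup, Kup,
gleak, vNCX, K_Ci, vpCa, KpCa, Kcsqn); calmodulin on/off rates enter through
their ratio Kcam.

The surrogate's purpose is structural, not quantitative: action-potential
features must be sensitive to few parameters (the voltage pair is
autonomous) while calcium-transient features are sensitive to many (voltage
drives release; uptake, affinity, leak and efflux shape the transient).
Three constants set the operating regime and were chosen for myocyte
realism: cytosolic buffer capacity Bcam = 150 µM (differential buffering
power ~50 at diastolic calcium), calsequestrin capacity Bcsqn = 500 µM and
cytosol:SR volume ratio λ = 30, sized so one beat releases a large fraction
of SR content. The content-limited release regime matters: with an
effectively unlimited SR, transient amplitude is simply proportional to the
release constant and a single parameter dominates every calcium feature;
with realistic fractional release, amplitude tracks SR content, which is set
by the uptake/leak/efflux balance, and calcium sensitivity spreads across
the subsystem. Sarcolemmal extrusion is kept small relative to SERCA,
as in the mouse ventricular myocyte.

Baselines were calibrated once by coordinate search (`calibrate_baseline`)
at 300 ms pacing against the full model's reference phenotype table:
apd90 and the calcium timing features (ctttp, ctd25–ctd90) all land within
±23% of the reference (tolerance ±30%), apamp within 2.3% of the 118 mV
span. Reference amplitude values (ctamp, ctpeak) are calibration guides,
not requirements; the committed baseline has ctamp ~29% below reference.
The committed `DEFAULT_BASELINES` are the search output; the function
re-derives them.

### Pacing, convergence, integration

Stimulation raises v at 15/118 per ms for 3 ms at the start of each cycle
(100/200/300 ms cycle lengths supported; 300 ms feeds the GWAS by default).
After each interval the beat-initial value and the trajectory integral of
every state variable are compared with the previous interval; a match within
5% relative tolerance (absolute below 1e-12) means convergence. A match
against the interval two back without a match one back is classified as
period-2 alternans → failure; exceeding 10 minutes of simulated time →
failure; a matched beat that ends above the excitation threshold (a cell
parked at a depolarized fixed point) → failure. Integration is fixed-step
RK4 at 0.05 ms with a 0.1 ms output grid, compiled with numba. The system
is non-stiff (fastest rate ~3/ms, so λ·dt ≈ 0.15) and the fixed step makes
population runs bit-reproducible and fast (~10–40 ms per individual);
feature discretization error is orders of magnitude below phenotypic
variance. Simulations start from the quiescent equilibrium of the baseline
cell.

## Phenotypes

Sixteen features per converged beat, eight per trace: initial value, peak,
amplitude (= peak − base exactly) and time-to-peak, plus the times from
stimulus onset to 25/50/75/90% recovery from peak toward base, located by
linear interpolation of the first post-peak crossing. Durations are
referenced to stimulus onset (consistent with the reference table, where
apttp 3.2 ms < apd25 4.34 ms). A trace that never recrosses a recovery
level within the beat yields NaN with a flag.

## QC and split

Failed individuals are removed; then a single-pass fence filter excludes any
individual with any phenotype above Q3 + 2·IQR or below Q1 − 2·IQR
(type-7 quartiles). Survivors are split uniformly at random into 2,500
training individuals (500 in the desk profile) and a test set of the rest.

## Association, prediction, sensitivity

The association test is the standard quantitative-trait scan: per SNP, OLS
of the trait on the genotype code, Wald t with n−2 df, two-sided p,
Bonferroni correction over the full 40,000-SNP panel, significance at
corrected p < 1e-5 (raw 2.5e-10). The scan is vectorised but numerically
identical to a per-SNP regression fit (checked against statsmodels to
1e-10). Discovery rate = |S∩C|/|C| per trait; for cellular phenotypes C is
the union of all parameters' causal sets; FPR = |S\C|/|S|, defined as 0
(flagged) when S is empty.

Explained variance: OLS with intercept on the detected causal SNPs
(minimum-norm for rank-deficient designs), fitted on training, and R² =
squared Pearson correlation of observed on predicted over the test set.
Cross-level prediction uses the union of the SNPs detected by the
parameter-level scans as predictors for a cellular phenotype; an
"all-significant" mode uses S instead of S∩C. Sensitivity is the univariate
regression R² of each phenotype on each parameter over the training set, and
its agreement with GWAS attribution (|D_phen ∩ C_param| counts) is the
Spearman correlation of the vectorised matrices.

## Profiles and problem sizes

* `study_scale`: 5,000 individuals, 40,000 SNPs, the 34-parameter roster
  (names and baselines of the full model's genetically varied parameters),
  400 or 200 causal SNPs per parameter, fast-mode population, no-cell-model
  mode by default. Ten Monte Carlo runs take ~1 minute after the ~30 s
  population build; the package's summary statistics are medians over runs.
* `desk`: 1,000 individuals, 5,000 SNPs on 10 chromosomes, 5
  subpopulations, 8 surrogate parameters (gNa, gK1, gKur, tau_close — the
  AP-dominant voltage side — and krel, Vup, Kup, gleak) with 50 causal SNPs
  each at Laplace sd 0.02, chosen so per-parameter variation spans the same
  tens-of-percent range as the study design; full cell-model stage at
  300 ms pacing, 500-individual training split. Ten runs take roughly ten
  minutes on one CPU.

All randomness flows from explicit seeds (population seed plus per-run
spawned generators); identical config + seed reproduces reports
bit-identically.

## What the generator does and does not emulate

Passing tests show that the statistical machinery behaves correctly on a
population with realistic allele-frequency spectra, exponentially decaying
local LD, and continental-scale structure — not that the synthetic
population matches any real cohort's LD block structure, site-frequency
spectrum, or admixture pattern. Two known consequences:

* Long-range ancestry-LD in the Balding–Nichols pooled population is
  stronger than in the real-data population the reference results came
  from: at fst 0.1 the median parameter discovery rate is ~6% with ~87%
  FPR, versus ~3.4% discovery and ~20% FPR in an unstructured population
  (fst 0) — the latter matching the reported 3.5–4% discovery and 30–40%
  explained-variance bands. The explained-variance statistic is robust to
  this (42% at fst 0.1, 32% at fst 0), because prediction is evaluated
  out-of-sample and the ancestry component it captures is genuinely
  genetic.
* The surrogate preserves the *shape* of the sensitivity structure
  (AP concentrated, CT poly-parametric), so phenotype-level results are
  asserted as orderings (parameters ≫ AP ≫ CT discovery; cross-level ≥
  own-GWAS prediction; AP sensitivity columns lower-entropy than CT), never
  as magnitudes.

## Limitations

* No environmental variance on parameters (deliberate: the comparison is of
  genetic signal strength across levels).
* Additive genotype-parameter map only; no dominance or epistasis.
* apbase is degenerate (affine voltage map); it participates in the
  phenotype tables but carries no signal.
* The IQR filter is applied to parameter values in no-cell-model mode
  (there are no phenotypes to filter on), which differs from the cell-model
  path, where it is applied to phenotypes.
* PLINK-format export is provided for external cross-checking, but PLINK
  itself is never invoked.
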