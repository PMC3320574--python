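"""Monte Carlo orchestration of the full in-silico GWAS experiment.

One experiment = one virtual population, reused across Monte Carlo runs;
each run redraws the causal SNP sets and their Laplace effects, maps
genotypes to model parameters, (optionally) simulates every individual's
paced heart cell and extracts phenotypes, filters outliers, splits into
training/test, performs single-SNP GWAS on every trait, builds multi-SNP
prediction models from the detected SNPs, and runs the linear sensitivity
analysis.  Reported summaries are medians (and means for the matrices) over
runs, mirroring the study's Monte Carlo design.

Two built-in profiles:

* ``study_scale`` - 5,000 individuals, 40,000 SNPs, the 34-parameter roster
  with 400 (or 200) causal SNPs each; by default in no-cell-model mode,
  which stops after parameter-level GWAS/prediction (the parameter-level
  results do not depend on the cell model).
* ``desk`` - 1,000 individuals, 5,000 SNPs, 8 surrogate parameters with 50
  causal SNPs each, full cell-model stage at 300 ms pacing; sized for a
  desk-top property check of the cell-model-dependent claims.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpmap as _gpmap
from .cellmodel import PacingProtocol, desk_roster, simulate_population, surrogate_roster
from .features import AP_FEATURES, CT_FEATURES, FEATURE_NAMES, feature_table
from .gpmap import map_genotypes_to_parameters, sample_causal_sets, sample_effects
from .gwas import assoc_scan_multi, attribution_matrix, causal_metrics, significant_set
from .popgen import ConfigurationError, PopulationConfig, build_layout, generate_population
from .predict import cross_level_prediction, fit_predict_r2
from .qc import iqr_filter, train_test_split
from .sensitivity import concordance, sensitivity_scan

__all__ = ["ExperimentConfig", "RunReport", "study_scale", "desk", "run_experiment",
           "config_from_yaml", "config_to_yaml"]


@dataclass
class ExperimentConfig:
    # genome
    n_chromosomes: int = 20
    loci_per_chromosome: int = 2000
    spacing_bp: float = 5000.0
    cm_per_mb: float = 1.0
    # population
    n_individuals: int = 5000
    n_subpops: int = 11
    generations: int = 500
    mutation_rate: float = 1e-8
    migration_rate: float = 0.001
    fst: float = 0.1
    maf_floor: float = 0.05
    ld_corr: float = 0.7
    fast_population: bool = True
    # genotype -> parameter map
    roster: str = "table1"          # "table1" | "surrogate" | "desk"
    n_causal: int = 400
    effect_sd: float = 0.0035
    disjoint: bool = True
    # cell model
    no_cell_model: bool = False
    bcls: tuple[float, ...] = (300.0,)
    feature_bcl: float = 300.0
    rel_tol: float = 0.05
    max_sim_minutes: float = 10.0
    # qc / split
    iqr_k: float = 2.0
    n_train: int = 2500
    # statistics
    bonferroni_threshold: float = 1e-5
    m_tests: int | None = None
    # Monte Carlo
    mc_runs: int = 10

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def roster_specs(self) -> list[_gpmap.ParameterSpec]:
        if self.roster == "table1":
            return _gpmap.default_parameter_roster()
        if self.roster == "surrogate":
            return surrogate_roster()
        if self.roster == "desk":
            return desk_roster()
        raise ConfigurationError(f"unknown roster {self.roster!r}")


def study_scale(n_causal: int = 400, mc_runs: int = 10,
                no_cell_model: bool = True) -> ExperimentConfig:
    """Study-scale design: 40,000 SNPs, 5,000 individuals, 34 parameters.

    ``n_causal`` of 400 uses Laplace sd 0.0035; 200 uses 0.0049 (the two
    designs carry the same total parametric variance).
    """
    sd = 0.0035 if n_causal == 400 else 0.0049 if n_causal == 200 else 0.0035
    return ExperimentConfig(n_causal=n_causal, effect_sd=sd, mc_runs=mc_runs,
                            no_cell_model=no_cell_model)


def desk(mc_runs: int = 10) -> ExperimentConfig:
    """Desk-scale design with the full cell-model stage.

    1,000 individuals, 5,000 SNPs on 10 chromosomes, 8 surrogate parameters
    with 50 causal SNPs each at Laplace sd 0.02 (chosen so per-parameter
    genetic variation spans roughly the same +/- tens-of-percent range as the
    study design; see docs/methods.md), pacing at 300 ms only.
    """
    return ExperimentConfig(
        n_chromosomes=10, loci_per_chromosome=500,
        n_individuals=1000, n_subpops=5,
        roster="desk", n_causal=50, effect_sd=0.02,
        no_cell_model=False, bcls=(300.0,), feature_bcl=300.0,
        n_train=500, mc_runs=mc_runs,
    )


@dataclass
class RunReport:
    """Per-run tables (rows = Monte Carlo runs) and averaged matrices."""

    config: dict
    seed: int
    param_names: list[str]
    param_discovery: pd.DataFrame
    param_r2: pd.DataFrame
    param_fpr: pd.DataFrame
    phen_discovery: pd.DataFrame | None = None
    phen_own_r2: pd.DataFrame | None = None
    phen_cross_r2: pd.DataFrame | None = None
    phen_all_sig_r2: pd.DataFrame | None = None
    phen_fpr: pd.DataFrame | None = None
    attribution_mean: pd.DataFrame | None = None
    sensitivity_mean: pd.DataFrame | None = None
    concordance_per_run: list[float] = field(default_factory=list)
    exclusions_per_run: list[int] = field(default_factory=list)
    failures_per_run: list[int] = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)

    def medians(self) -> dict[str, float]:
        """Headline medians over runs and traits (percent where rates)."""
        out = {
            "param_discovery_pct": 100.0 * float(np.nanmedian(self.param_discovery.values)),
            "param_r2_pct": 100.0 * float(np.nanmedian(self.param_r2.values)),
            "param_fpr_pct": 100.0 * float(np.nanmedian(self.param_fpr.values)),
        }
        if self.phen_discovery is not None:
            ap = [c for c in self.phen_discovery.columns if c in AP_FEATURES]
            ct = [c for c in self.phen_discovery.columns if c in CT_FEATURES]
            out["ap_discovery_pct"] = 100.0 * float(np.nanmedian(self.phen_discovery[ap].values))
            out["ct_discovery_pct"] = 100.0 * float(np.nanmedian(self.phen_discovery[ct].values))
            out["phen_own_r2_pct"] = 100.0 * float(np.nanmedian(self.phen_own_r2.values))
            out["phen_cross_r2_pct"] = 100.0 * float(np.nanmedian(self.phen_cross_r2.values))
            out["phen_fpr_pct"] = 100.0 * float(np.nanmedian(self.phen_fpr.values))
            out["concordance_median"] = float(np.nanmedian(self.concordance_per_run))
        return out

    def save(self, prefix: str) -> None:
        """Persist the report as TSV tables plus a JSON manifest."""
        tables = {
            "param_discovery": self.param_discovery,
            "param_r2": self.param_r2,
            "param_fpr": self.param_fpr,
            "phen_discovery": self.phen_discovery,
            "phen_own_r2": self.phen_own_r2,
            "phen_cross_r2": self.phen_cross_r2,
            "phen_all_sig_r2": self.phen_all_sig_r2,
            "phen_fpr": self.phen_fpr,
            "attribution_mean": self.attribution_mean,
            "sensitivity_mean": self.sensitivity_mean,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(f"{prefix}_{name}.tsv", sep="\t")
        manifest = {
            "config": self.config,
            "seed": self.seed,
            "medians": self.medians(),
            "concordance_per_run": self.concordance_per_run,
            "exclusions_per_run": self.exclusions_per_run,
            "failures_per_run": self.failures_per_run,
            "stage_seconds": self.stage_seconds,
        }
        with open(f"{prefix}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)


def _trait_scan(Y, names, codes, train_ids, m_tests, threshold):
    """GWAS on each trait over the training split; returns significant sets."""
    results = assoc_scan_multi(Y[train_ids], codes[train_ids], names, m_tests=m_tests)
    return {r.trait: significant_set(r, threshold) for r in results}


def run_experiment(config: ExperimentConfig, seed: int = 0,
                   population=None) -> RunReport:
    """Execute the full Monte Carlo experiment for one configuration.

    ``population`` may carry a pre-generated GenotypeMatrix matching the
    configured genome (the population is reused across Monte Carlo runs
    anyway, and across designs that differ only in the effect map).
    """
    t0 = _time.perf_counter()
    stage_seconds: dict[str, float] = {}
    layout = build_layout(config.n_chromosomes, config.loci_per_chromosome,
                          config.spacing_bp, config.cm_per_mb)
    if population is None:
        pop_cfg = PopulationConfig(
            n_final=config.n_individuals, n_subpops=config.n_subpops,
            generations=config.generations, mutation_rate=config.mutation_rate,
            migration_rate=config.migration_rate, fst=config.fst,
            maf_floor=config.maf_floor, seed=seed,
        )
        G = generate_population(layout, pop_cfg, config.ld_corr,
                                fast=config.fast_population)
    else:
        G = population
        if G.n_loci != config.n_loci or G.n_individuals != config.n_individuals:
            raise ConfigurationError("provided population does not match config")
    stage_seconds["population"] = _time.perf_counter() - t0

    specs = config.roster_specs()
    param_names = [s.name for s in specs]
    m_tests = config.m_tests or config.n_loci
    threshold = config.bonferroni_threshold
    protocols = [
        PacingProtocol(bcl=b, rel_tol=config.rel_tol,
                       max_sim_time=config.max_sim_minutes * 60_000.0)
        for b in config.bcls
    ]

    rows_pd, rows_pr, rows_pf = [], [], []
    rows_fd, rows_fo, rows_fx, rows_fa, rows_ff = [], [], [], [], []
    attr_acc, sens_acc = [], []
    conc, excl, fails = [], [], []

    for run in range(config.mc_runs):
        rng = np.random.default_rng([seed, 1000 + run])
        emap = sample_causal_sets(len(specs), config.n_causal, config.n_loci,
                                  disjoint=config.disjoint, seed=rng)
        emap = sample_effects(emap, config.effect_sd, seed=rng)
        table = map_genotypes_to_parameters(G, emap, specs)
        union = emap.causal_union()

        if config.no_cell_model:
            keep, log = iqr_filter(table.values, table.nonpositive_flags,
                                   config.iqr_k, table.names)
            phen_values = None
            failed = table.nonpositive_flags
        else:
            t_sim = _time.perf_counter()
            beats = simulate_population(table, protocols)
            stage_seconds["cellmodel"] = stage_seconds.get("cellmodel", 0.0) + (
                _time.perf_counter() - t_sim)
            phen_values, failed = feature_table(beats[config.feature_bcl])
            failed |= table.nonpositive_flags
            keep, log = iqr_filter(phen_values, failed, config.iqr_k, FEATURE_NAMES)
        retained = np.flatnonzero(keep)
        excl.append(int(G.n_individuals - retained.size))
        fails.append(int(np.count_nonzero(failed)))
        split = train_test_split(retained, config.n_train, seed=rng, exclusion_log=log)

        t_gwas = _time.perf_counter()
        param_sig = _trait_scan(table.values, param_names, G.codes,
                                split.training_ids, m_tests, threshold)
        param_metrics = {
            name: causal_metrics(param_sig[name], emap.causal_sets[k])
            for k, name in enumerate(param_names)
        }
        rows_pd.append([param_metrics[n].discovery_rate for n in param_names])
        rows_pf.append([param_metrics[n].fpr for n in param_names])
        rows_pr.append([
            fit_predict_r2(table.values[:, k], G.codes,
                           param_metrics[n].detected, split, n).r2
            for k, n in enumerate(param_names)
        ])
        stage_seconds["gwas"] = stage_seconds.get("gwas", 0.0) + (
            _time.perf_counter() - t_gwas)

        if phen_values is not None:
            phen_sig = _trait_scan(phen_values, FEATURE_NAMES, G.codes,
                                   split.training_ids, m_tests, threshold)
            phen_metrics = {n: causal_metrics(phen_sig[n], union) for n in FEATURE_NAMES}
            rows_fd.append([phen_metrics[n].discovery_rate for n in FEATURE_NAMES])
            rows_ff.append([phen_metrics[n].fpr for n in FEATURE_NAMES])
            rows_fo.append([
                fit_predict_r2(phen_values[:, j], G.codes,
                               phen_metrics[n].detected, split, n).r2
                for j, n in enumerate(FEATURE_NAMES)
            ])
            det_by_param = [param_metrics[n].detected for n in param_names]
            rows_fx.append([
                cross_level_prediction(phen_values[:, j], G.codes,
                                       det_by_param, split, n).r2
                for j, n in enumerate(FEATURE_NAMES)
            ])
            rows_fa.append([
                fit_predict_r2(phen_values[:, j], G.codes, phen_sig[n], split, n,
                               mode="all-significant").r2
                for j, n in enumerate(FEATURE_NAMES)
            ])
            detected_sets = {n: phen_metrics[n].detected for n in FEATURE_NAMES}
            attr_acc.append(attribution_matrix(detected_sets, emap))
            sens = sensitivity_scan(table.values[split.training_ids],
                                    phen_values[split.training_ids])
            sens_acc.append(sens)
            conc.append(concordance(sens, attr_acc[-1]))

    idx = pd.RangeIndex(config.mc_runs, name="run")
    report = RunReport(
        config=dataclasses.asdict(config),
        seed=seed,
        param_names=param_names,
        param_discovery=pd.DataFrame(rows_pd, index=idx, columns=param_names),
        param_r2=pd.DataFrame(rows_pr, index=idx, columns=param_names),
        param_fpr=pd.DataFrame(rows_pf, index=idx, columns=param_names),
        exclusions_per_run=excl,
        failures_per_run=fails,
        concordance_per_run=conc,
        stage_seconds=stage_seconds,
    )
    if rows_fd:
        report.phen_discovery = pd.DataFrame(rows_fd, index=idx, columns=FEATURE_NAMES)
        report.phen_own_r2 = pd.DataFrame(rows_fo, index=idx, columns=FEATURE_NAMES)
        report.phen_cross_r2 = pd.DataFrame(rows_fx, index=idx, columns=FEATURE_NAMES)
        report.phen_all_sig_r2 = pd.DataFrame(rows_fa, index=idx, columns=FEATURE_NAMES)
        report.phen_fpr = pd.DataFrame(rows_ff, index=idx, columns=FEATURE_NAMES)
        report.attribution_mean = pd.DataFrame(
            np.mean(attr_acc, axis=0), index=param_names, columns=FEATURE_NAMES)
        report.sensitivity_mean = pd.DataFrame(
            np.mean(sens_acc, axis=0), index=param_names, columns=FEATURE_NAMES)
    stage_seconds["total"] = _time.perf_counter() - t0
    return report


def config_from_yaml(path: str) -> ExperimentConfig:
    """Load an experiment configuration from a YAML key-value file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    if "bcls" in data:
        data["bcls"] = tuple(data["bcls"])
    return ExperimentConfig(**data)


def config_to_yaml(config: ExperimentConfig, path: str) -> None:
    import yaml

    data = dataclasses.asdict(config)
    data["bcls"] = list(data["bcls"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
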