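"""Full pipeline, desk scale: parameters versus cellular phenotypes.

Runs the desk profile (1,000 individuals, 5,000 SNPs, 8 surrogate
parameters, full paced-cell stage) for a few Monte Carlo runs and prints the
headline comparison: GWAS on parameters versus GWAS on the emergent
action-potential (AP) and calcium-transient (CT) phenotypes.

Takes a couple of minutes on one CPU.
"""

import numpy as np

from cgpgwas import desk, run_experiment
from cgpgwas.features import AP_FEATURES, CT_FEATURES

report = run_experiment(desk(mc_runs=3), seed=1)
m = report.medians()

print(f"median discovery rate: parameters {m['param_discovery_pct']:.2f}%  "
      f"AP {m['ap_discovery_pct']:.2f}%  CT {m['ct_discovery_pct']:.2f}%")
print(f"median explained variance: parameters {m['param_r2_pct']:.1f}%  "
      f"phenotypes own-GWAS {m['phen_own_r2_pct']:.1f}%  "
      f"phenotypes from parameter-GWAS SNPs {m['phen_cross_r2_pct']:.1f}%")
print(f"sensitivity/attribution concordance (median over runs): "
      f"{m['concordance_median']:.2f}")
print(f"failures per run: {report.failures_per_run}; "
      f"exclusions per run: {report.exclusions_per_run}")

print("\nGWAS on parameters finds an order of magnitude more causal SNPs than"
      "\nGWAS on the cellular phenotypes, and predicting phenotypes from the"
      "\nparameter-detected SNPs recovers much of the gap -- the dynamic model's"
      "\nparameters act as containers of heritability that the emergent traits"
      "\nhide.")
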