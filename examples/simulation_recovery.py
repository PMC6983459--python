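"""Planted-effect recovery on fully synthetic cohorts.

Simulates case-control studies at the default design (574 vs 828
subjects, control carrier rate 14/828) with a planted carrier odds
ratio of 4, collapses carriers subject-level, and shows that the
estimated odds ratio recovers the planted value.
"""

import numpy as np

from csburden import (
    SimulationConfig,
    collapse_carriers,
    fisher_one_sided,
    odds_ratio,
    simulate_cohort,
)

estimates, pvalues = [], []
for seed in range(30):
    ds = simulate_cohort(
        SimulationConfig(seed=seed, planted_or=4.0, novelty_leak_rate=0.0)
    )
    counts = collapse_carriers(ds.variants, ds.genotypes, ds.cases, ds.controls)
    or_, _ = odds_ratio(counts)
    if or_ is not None:
        estimates.append(or_)
    pvalues.append(fisher_one_sided(counts))

print(f"planted odds ratio : 4.0")
print(f"median estimate    : {np.median(estimates):.2f}  ({len(estimates)} replicates)")
print(f"median one-sided P : {np.median(pvalues):.4f}")
# The median cross-product odds ratio sits near the planted 4.0 and the
# exact test rejects the null in most replicates, confirming that the
# generator's enrichment model and the collapsing estimator agree.
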