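"""How much adult methylation variation is already visible at birth?

For each site, methylation is residualised for covariates at birth and at
the oldest visit of the late-visit cohort, and the Pearson correlation of
the residuals is computed across individuals seen at both.  r squared is
the share of adult variance predictable from birth.
"""

import numpy as np

from clocktraj import CohortArm, CohortConfig, SiteTruth, generate_cohort
from clocktraj import variance_explained
from clocktraj.correlation import correlate_all_sites

truths = [
    SiteTruth(cpg_id="cg_stable", mu0=0.5, sd_intercept=0.04, sd_slope=2e-4,
              sd_resid=0.008),   # individual differences laid down at birth
    SiteTruth(cpg_id="cg_drift", mu0=0.5, sd_intercept=0.01, sd_slope=0.003,
              sd_resid=0.008),   # differences mostly emerge later
    SiteTruth(cpg_id="cg_noise", mu0=0.5, sd_resid=0.02),
]
cfg = CohortConfig(
    arms=(CohortArm("A", 60, (0.0, 6.0, 9.8), (0.0, 0.5, 0.3)),
          CohortArm("B", 250, (0.0, 7.5, 17.1), (0.0, 0.2, 1.0))),
    n_sites=3, seed=8, n_batches=3,
)
table, cov, _ = generate_cohort(cfg, truths=truths)

res = correlate_all_sites(table, cov)
print(res[["cpg_id", "r", "p", "n", "significant"]].to_string(index=False))
for _, row in res.iterrows():
    print(f"{row.cpg_id}: {100 * variance_explained(row.r):.0f}% of adult "
          "variance predictable from birth")
# The birth-anchored site shows a high correlation (its random intercept
# dominates), the drift site a moderate one, and the pure-noise site none.
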