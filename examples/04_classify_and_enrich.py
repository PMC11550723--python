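"""Classify sites into developmental features and test clock enrichment.

Runs the full pipeline on a small synthetic study in which the "clocks"
deliberately over-sample sites with high intercept variance.  The var-at-
birth enrichment should come out well above 1; a random clock would sit
near 1 on every feature.
"""

import tempfile

from clocktraj.pipeline import PipelineConfig, run_full

cfg = PipelineConfig(
    out_dir=tempfile.mkdtemp(prefix="clocktraj_demo_"),
    seed=3, n_sites=300, n_individuals=(90, 60), n_samples=None,
    n_clock_sites=(25, 20), clock_mode="designed", match_ratio=4,
)
report = run_full(cfg)

print(f"outputs in {cfg.out_dir}\n")
prev_all = report["prevalence"]["all"]
prev_first = report["prevalence"]["first"]
print(f"{'feature':28s} {'all sites':>9s} {'first-gen clock':>15s}")
for feat in ("changes", "var_at_birth", "rate_var_from_birth", "nonlinear_at_6"):
    print(f"{feat:28s} {prev_all[feat]:9.2f} {prev_first[feat]:15.2f}")

print("\nenrichment (clock vs all non-clock sites):")
for row in report["enrichment"]:
    if row["feature"] == "var_at_birth":
        print(f"  {row['group']:13s} OR={row['odds_ratio']:.2f} "
              f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] p={row['p']:.2e}")
print("\nafter matching the background on the fitted intercept SD:")
for row in report["matched_enrichment"]:
    if row["feature"] == "var_at_birth":
        print(f"  {row['group']:13s} OR={row['odds_ratio']:.2f} p={row['p']:.2e} "
              f"(SMD {row['smd_before']:.2f} -> {row['smd_after']:.2f})")
# Matching on the very property the clock was built from removes the
# enrichment: the matched odds ratios collapse towards 1.
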