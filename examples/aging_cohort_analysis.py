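"""Cohort workflow: recover planted node-level aging effects.

Builds a synthetic life-span cohort (60 subjects, ages 4-85) in which five
weak nodes carry planted connectivity trends (+/-5% per decade, three
increasing and two decreasing), runs the per-subject Ising criticality and
synergy profiling, and tests each node's synergy-age association with the
skipped Spearman correlation under Hochberg family-wise error control.
"""

import numpy as np

from connsyn import (
    desk_config,
    generate_aging_cohort,
    planted_recovery_spec,
    run_cohort_analysis,
)
from connsyn.ising import desk_protocol

spec, planted = planted_recovery_spec(seed=101)
manifest, matrices = generate_aging_cohort(spec)
print(f"cohort: {manifest.n_subjects} subjects, ages "
      f"{manifest.ages.min():.0f}-{manifest.ages.max():.0f} y")
print(f"planted effects (node: sign): {planted}\n")

config = desk_config(
    seed=101,
    protocol=desk_protocol(
        betas=np.linspace(0.3, 1.8, 12),
        relaxation_sweeps=2000,
        discard_sweeps=1000,
        collect_sweeps=5000,
        n_runs=2,
    ),
    triplet_mode="dense",
    max_triplets=6000,
    n_boot=1000,
)
bundle = run_cohort_analysis(matrices, manifest, config)

sig = bundle.age_result[bundle.age_result["significant"]]
print("nodes with synergy significantly associated with age "
      "(Hochberg alpha = 0.05):")
for row in sig.itertuples():
    tag = "planted" if row.node in planted else "FALSE POSITIVE"
    print(f"  node {row.node:2d}  rho = {row.rho:+.2f}  "
          f"p_adj = {row.p_hochberg:.4f}  [{tag}]")

print("\nstrength-age follow-up on the significant nodes:")
for row in bundle.strength_followup.itertuples():
    print(f"  node {row.node:2d}  rho = {row.rho:+.2f}  "
          f"significant = {bool(row.significant)}")
print(
    "\nAll five planted nodes should appear with the planted sign and no"
    "\nother node should be flagged; increasing-synergy nodes also show an"
    "\nincreasing structural strength, mirroring the planted mechanism."
)
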