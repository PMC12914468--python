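"""Run one benchmark grid cell with replicate-level confidence intervals.

Fits the rank-profile classifier on seeded replicates of the 5%
differential scenario and aggregates test AUCs with a t-distribution CI
(df = replicates - 1) — the aggregation used for all simulation tables.
A reduced replicate count keeps this demo around a minute.
"""

import ranklearn as rl

cfg = rl.ScenarioConfig(scenario="true_differential", diff_fraction=0.05)
cell = rl.run_cell(cfg, n_replicates=8, seed=1)
row = cell.row()
print(f"scenario={row['scenario']} diff_fraction={row['diff_fraction']} "
      f"model={row['model']} replicates={row['n_replicates']}")
print(f"development AUC {row['dev_auc']:.3f} "
      f"(95% CI {row['dev_ci_low']:.3f}-{row['dev_ci_high']:.3f})")
print(f"test        AUC {row['test_auc']:.3f} "
      f"(95% CI {row['test_ci_low']:.3f}-{row['test_ci_high']:.3f})")
print("per-replicate test AUCs:",
      [round(float(a), 3) for a in cell.replicate_test_aucs])
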