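"""Fit a rank profile on synthetic data and score a held-out test set.

Generates one differential-expression scenario (5% of features shifted in
cases), learns the feature rank profile with the two-phase stochastic
search, then scores the test samples by rank concordance. Prints the test
AUC with a bootstrap CI: higher similarity = more case-like ordering.
"""

import numpy as np

import ranklearn as rl

cfg = rl.ScenarioConfig(scenario="true_differential", diff_fraction=0.05, seed=7)
split, test, truth = rl.generate_scenario(cfg)
print(f"development: D1 n={split.d1.n}, D2 n={split.d2.n}, D3 n={split.d3.n}; "
      f"test n={test.n}; p={test.p}")
print(f"true differential features: {truth['true_feature_ids']}")

profile, state = rl.fit(split, rl.SearchConfig(seed=7))
print(f"search ran {state.iterations_run} iterations, "
      f"{len(state.trajectory) - 1} accepted moves, "
      f"early stop: {state.stopped_early}")
print(f"final development TSS triple: "
      f"{tuple(round(s, 2) for s in state.tss_triple)}")

scores = rl.risk_scores(test, profile, feature_ids=split.d1.feature_ids)
report = rl.bootstrap_ci(scores, test.labels, rng=np.random.default_rng(7))
print(f"test AUC {report.auc:.3f} "
      f"(95% bootstrap CI {report.ci_low:.3f}-{report.ci_high:.3f})")

# where did the truly shifted features end up in the learned profile?
ranks = profile.order[truth["true_feature_indices"]]
print(f"profile ranks of the {len(ranks)} true features (1..{test.p}, higher "
      f"= more case-elevated): {sorted(ranks.tolist())}")
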