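"""Simulation benchmark orchestration.

Runs the (scenario x differential-fraction) grid: each cell generates seeded
replicates, fits the rank-profile classifier (and optional baselines) on
the development split, scores the held-out test set, and aggregates
replicate AUCs with a t-distribution confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import BaselineSpec, fit_baseline
from .evaluation import auc, t_ci
from .optimizer import SearchConfig, fit
from .scoring import risk_scores, similarity_scores
from .simulate import ScenarioConfig, generate_scenario

__all__ = ["CellResult", "run_cell", "run_benchmark", "standard_grid"]


def standard_grid() -> dict[str, tuple[ScenarioConfig, str]]:
    """The canonical simulation benchmark cells.

    Maps a cell name to (scenario config, model), where model is
    ``"rbl"`` for the rank-profile classifier or ``"lr_forward"`` for the
    logistic-regression comparator with forward feature selection.
    """

    def c(**kw):
        return ScenarioConfig(**kw)

    return {
        "basic_1pct": (c(diff_fraction=0.01), "rbl"),
        "basic_5pct": (c(diff_fraction=0.05), "rbl"),
        "basic_5pct_large_n": (
            c(diff_fraction=0.05, n_cases=100, n_controls=100), "rbl"),
        "missing10_1pct": (
            c(scenario="missing", diff_fraction=0.01, missing_rate=0.1), "rbl"),
        "missing50_1pct": (
            c(scenario="missing", diff_fraction=0.01, missing_rate=0.5), "rbl"),
        "missing50_20pct": (
            c(scenario="missing", diff_fraction=0.20, missing_rate=0.5), "rbl"),
        "batch_1pct": (
            c(scenario="batch", diff_fraction=0.01, n_cases=60, n_controls=60),
            "rbl"),
        "batch_5pct": (
            c(scenario="batch", diff_fraction=0.05, n_cases=60, n_controls=60),
            "rbl"),
        "batch_5pct_lr": (
            c(scenario="batch", diff_fraction=0.05, n_cases=60, n_controls=60),
            "lr_forward"),
        "correlation_1pct": (
            c(scenario="correlation", diff_fraction=0.01), "rbl"),
    }


@dataclass(frozen=True)
class CellResult:
    scenario: str
    diff_fraction: float
    model: str
    replicate_dev_aucs: np.ndarray
    replicate_test_aucs: np.ndarray

    @property
    def mean_test_auc(self) -> float:
        return float(self.replicate_test_aucs.mean())

    def row(self) -> dict:
        dev = t_ci(self.replicate_dev_aucs)
        test = t_ci(self.replicate_test_aucs)
        return {
            "scenario": self.scenario,
            "diff_fraction": self.diff_fraction,
            "model": self.model,
            "n_replicates": len(self.replicate_test_aucs),
            "dev_auc": round(dev.auc, 4),
            "dev_ci_low": round(dev.ci_low, 4),
            "dev_ci_high": round(dev.ci_high, 4),
            "test_auc": round(test.auc, 4),
            "test_ci_low": round(test.ci_low, 4),
            "test_ci_high": round(test.ci_high, 4),
        }


def _fit_rbl_replicate(cfg: ScenarioConfig, search: SearchConfig, seed: int):
    rng = np.random.default_rng(seed)
    split, test, _ = generate_scenario(cfg, rng)
    profile, state = fit(split, search, rng=rng)
    dev_scores = np.concatenate(
        [similarity_scores(split.d1, profile), similarity_scores(split.d2, profile)]
    )
    dev_labels = np.concatenate([split.d1.labels, split.d2.labels])
    dev_auc = auc(dev_scores, dev_labels)
    test_auc = auc(risk_scores(test, profile), test.labels)
    return dev_auc, test_auc


def _fit_baseline_replicate(cfg: ScenarioConfig, spec: BaselineSpec, seed: int):
    rng = np.random.default_rng(seed)
    split, test, _ = generate_scenario(cfg, rng)
    result = fit_baseline(spec, split, test, rng=rng)
    return result["development"].auc, result["test"].auc


def run_cell(
    cfg: ScenarioConfig,
    n_replicates: int = 20,
    seed: int = 0,
    search: SearchConfig | None = None,
    baseline: BaselineSpec | None = None,
) -> CellResult:
    """Run one grid cell: ``n_replicates`` seeded replicates of one model.

    ``baseline=None`` fits the rank-profile classifier; otherwise the given
    comparator. Replicate k uses a child seed derived from ``seed``.
    """
    search = search or SearchConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    dev_aucs, test_aucs = [], []
    for s in seeds:
        if baseline is None:
            d, t = _fit_rbl_replicate(cfg, search, int(s))
            model = "rank_profile"
        else:
            d, t = _fit_baseline_replicate(cfg, baseline, int(s))
            model = f"{baseline.model}+{baseline.selection}"
        dev_aucs.append(d)
        test_aucs.append(t)
    return CellResult(
        scenario=cfg.scenario,
        diff_fraction=cfg.diff_fraction,
        model=model,
        replicate_dev_aucs=np.array(dev_aucs),
        replicate_test_aucs=np.array(test_aucs),
    )


def run_benchmark(
    scenarios: list[ScenarioConfig],
    n_replicates: int = 20,
    seed: int = 0,
    search: SearchConfig | None = None,
    baselines: list[BaselineSpec] | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Run a grid of scenario cells and return one table row per model.

    When ``out_dir`` is given, writes ``benchmark.csv``, ``benchmark.json``
    and a reproducibility manifest. Per-replicate failures abort the run;
    every row is fully reproducible from (configs, seed).
    """
    rows = []
    for k, cfg in enumerate(scenarios):
        cell_seed = seed + 1000 * k
        rows.append(run_cell(cfg, n_replicates, cell_seed, search).row())
        for spec in baselines or []:
            rows.append(
                run_cell(cfg, n_replicates, cell_seed, search, baseline=spec).row()
            )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "benchmark.csv", index=False)
        table.to_json(out_dir / "benchmark.json", orient="records", indent=2)
        manifest = {
            "package_version": __version__,
            "seed": seed,
            "n_replicates": n_replicates,
            "search": asdict(search or SearchConfig()),
            "scenarios": [asdict(c) for c in scenarios],
            "baselines": [asdict(b) for b in baselines or []],
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return table
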