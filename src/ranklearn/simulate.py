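"""Synthetic omics benchmark scenarios.

Generates the four stress-test worlds used to benchmark rank-based
classification against intensity-based baselines:

``true_differential``
    Gaussian feature table (per-feature mean ~ U(50, 70), variance
    ~ U(1, 80), both classes identical) with a fraction of features shifted
    upward in cases by a per-feature constant ~ N(60, 60) (mean, variance);
    each shifted feature is verified differential by Welch's t-test.
``missing``
    The differential world plus MCAR masking of an exact fraction of all
    matrix entries.
``batch``
    Training data unshifted; the test half is split into three batches of
    20 samples (10 cases / 10 controls) receiving additive constants from
    U(100, 300), U(300, 500) and U(500, 700) — magnitudes change, within-
    sample rank order provably does not.
``correlation``
    The differential world plus a shared per-case-sample value ~ N(10, 10)
    (mean, variance) added to every true differential feature, inducing
    positive correlation among them within cases.

Splitting mirrors the development protocol: 70/30 stratified
development/test, development subdivided ~69/31 into D1/D2, and D3 (same
size as D2) resampled from D1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .optimizer import DevelopmentSplit

__all__ = [
    "ScenarioConfig",
    "base_matrix",
    "apply_differential",
    "apply_missing",
    "apply_batch",
    "apply_correlation",
    "make_splits",
    "generate_scenario",
]

SCENARIOS = ("true_differential", "missing", "batch", "correlation")

# development-set subdivision mirrors the 27/39 train fraction of the
# real-data protocol; D3 is resampled from D1 with |D3| = |D2|
D1_FRACTION = 27.0 / 39.0
DEV_FRACTION = 0.7


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation scenario."""

    scenario: str = "true_differential"
    n_cases: int = 30
    n_controls: int = 30
    p: int = 300
    diff_fraction: float = 0.05
    missing_rate: float = 0.0
    batch_ranges: tuple = ((100.0, 300.0), (300.0, 500.0), (500.0, 700.0))
    batch_per_sample: bool = False
    mean_range: tuple = (50.0, 70.0)
    variance_range: tuple = (1.0, 80.0)
    shift_mean: float = 60.0
    shift_variance: float = 60.0
    corr_shift_mean: float = 10.0
    corr_shift_variance: float = 10.0
    missing_in_test: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.diff_fraction * self.p < 1:
            raise ValueError("diff_fraction * p must be at least 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_differential(self) -> int:
        return int(np.ceil(self.diff_fraction * self.p))


def base_matrix(cfg: ScenarioConfig, rng: np.random.Generator) -> ExpressionMatrix:
    """Null feature table: per-feature Gaussians, identical in both classes."""
    mu = rng.uniform(*cfg.mean_range, size=cfg.p)
    var = rng.uniform(*cfg.variance_range, size=cfg.p)
    values = rng.normal(mu, np.sqrt(var), size=(cfg.n, cfg.p))
    labels = np.concatenate(
        [np.ones(cfg.n_cases, dtype=np.int64), np.zeros(cfg.n_controls, dtype=np.int64)]
    )
    return ExpressionMatrix(values=values, labels=labels)


def apply_differential(
    matrix: ExpressionMatrix,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Shift a random feature subset upward in cases; verify by Welch t-test.

    Returns the shifted matrix and the 0-based indices of the true
    differential features. A feature whose shift leaves it non-significant
    (p >= 0.05) has its shift redrawn, up to ``max_retries`` times.
    """
    out = matrix.copy()
    k = cfg.n_differential
    chosen = np.sort(rng.choice(matrix.p, size=k, replace=False))
    sd = np.sqrt(cfg.shift_variance)
    case = out.case_mask
    for f in chosen:
        base_col = matrix.values[:, f]
        for attempt in range(max_retries + 1):
            shift = rng.normal(cfg.shift_mean, sd)
            col = base_col.copy()
            col[case] = col[case] + shift
            t, pval = stats.ttest_ind(col[case], col[~case], equal_var=False)
            if pval < 0.05:
                out.values[:, f] = col
                break
        else:
            raise RuntimeError(
                f"feature {matrix.feature_ids[f]} not significant after "
                f"{max_retries} shift redraws"
            )
    return out, chosen


def apply_missing(
    matrix: ExpressionMatrix, cfg: ScenarioConfig, rng: np.random.Generator
) -> ExpressionMatrix:
    """Mask exactly round(rate * n * p) entries uniformly at random (MCAR)."""
    if cfg.missing_rate == 0.0:
        return matrix.copy()
    out = matrix.copy()
    n_mask = int(round(cfg.missing_rate * out.n * out.p))
    flat = rng.choice(out.n * out.p, size=n_mask, replace=False)
    mask = out.missing_mask.reshape(-1)
    mask[flat] = True
    out.missing_mask = mask.reshape(out.n, out.p)
    out.values[out.missing_mask] = np.nan
    return out


def apply_batch(
    matrix: ExpressionMatrix, cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Add one additive constant per batch to all features of each batch group.

    The matrix (normally the test partition) is divided into
    ``len(batch_ranges)`` equal groups, stratified so each holds the same
    number of cases and controls. Returns the shifted matrix and the batch
    assignment per sample. Within-sample rank order is unchanged.
    """
    g = len(cfg.batch_ranges)
    case_idx = np.flatnonzero(matrix.case_mask)
    ctrl_idx = np.flatnonzero(~matrix.case_mask)
    if len(case_idx) % g or len(ctrl_idx) % g:
        raise ValueError(
            f"cases ({len(case_idx)}) and controls ({len(ctrl_idx)}) must each "
            f"divide evenly into {g} batch groups"
        )
    rng.shuffle(case_idx)
    rng.shuffle(ctrl_idx)
    assignment = np.empty(matrix.n, dtype=np.int64)
    per_case = len(case_idx) // g
    per_ctrl = len(ctrl_idx) // g
    for b in range(g):
        assignment[case_idx[b * per_case : (b + 1) * per_case]] = b
        assignment[ctrl_idx[b * per_ctrl : (b + 1) * per_ctrl]] = b

    out = matrix.copy()
    for b, (lo, hi) in enumerate(cfg.batch_ranges):
        rows = assignment == b
        if cfg.batch_per_sample:
            shift = rng.uniform(lo, hi, size=(int(rows.sum()), 1))
        else:
            shift = rng.uniform(lo, hi)
        out.values[rows] = out.values[rows] + shift
    out.values[out.missing_mask] = np.nan
    return out, assignment


def apply_correlation(
    matrix: ExpressionMatrix,
    true_features: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Add a shared per-case-sample value to all true differential features."""
    out = matrix.copy()
    case_rows = np.flatnonzero(out.case_mask)
    sd = np.sqrt(cfg.corr_shift_variance)
    shared = rng.normal(cfg.corr_shift_mean, sd, size=case_rows.size)
    for r, s in zip(case_rows, shared):
        out.values[r, true_features] = out.values[r, true_features] + s
    out.values[out.missing_mask] = np.nan
    return out


def _stratified_indices(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into (first, rest), per-class rounded fractions."""
    first, rest = [], []
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        k = int(round(fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        first.append(idx[:k])
        rest.append(idx[k:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(rest))


def make_splits(
    matrix: ExpressionMatrix,
    scenario: str,
    rng: np.random.Generator,
    cfg: ScenarioConfig | None = None,
) -> tuple[DevelopmentSplit, ExpressionMatrix]:
    """Produce (DevelopmentSplit, test matrix) for a scenario.

    Non-batch: stratified 70/30 development/test. Batch: a stratified 50/50
    split — development stays unshifted, the test half receives the batch
    constants. Development is subdivided into D1/D2 (~69/31) and D3 (same
    size as D2) is resampled from D1 without replacement, stratified.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "batch":
        dev_idx, test_idx = _stratified_indices(matrix.labels, 0.5, rng)
        dev = matrix.subset(dev_idx)
        test, _ = apply_batch(
            matrix.subset(test_idx), cfg or ScenarioConfig(scenario="batch"), rng
        )
    else:
        dev_idx, test_idx = _stratified_indices(matrix.labels, DEV_FRACTION, rng)
        dev = matrix.subset(dev_idx)
        test = matrix.subset(test_idx)

    d1_idx, d2_idx = _stratified_indices(dev.labels, D1_FRACTION, rng)
    d1 = dev.subset(d1_idx)
    d2 = dev.subset(d2_idx)
    # D3: |D2| samples resampled from D1, stratified to keep both classes
    frac = d2_idx.size / d1_idx.size
    d3_idx, _ = _stratified_indices(d1.labels, frac, rng)
    d3 = d1.subset(d3_idx)
    return DevelopmentSplit(d1=d1, d2=d2, d3=d3, d3_rows_in_d1=d3_idx), test


def generate_scenario(
    cfg: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> tuple[DevelopmentSplit, ExpressionMatrix, dict]:
    """End-to-end scenario generation: matrix, perturbations, splits.

    Returns (development split, test matrix, truth) where ``truth`` records
    the true differential feature ids and applied shifts.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    matrix = base_matrix(cfg, rng)
    matrix, true_features = apply_differential(matrix, cfg, rng)
    if cfg.scenario == "correlation":
        matrix = apply_correlation(matrix, true_features, cfg, rng)
    complete = matrix
    if cfg.scenario == "missing":
        matrix = apply_missing(matrix, cfg, rng)
    split, test = make_splits(matrix, cfg.scenario, rng, cfg)
    if cfg.scenario == "missing" and not cfg.missing_in_test:
        # restore the test partition from the pre-masking matrix
        rows = [complete.sample_ids.index(s) for s in test.sample_ids]
        test = complete.subset(np.asarray(rows))
    truth = {
        "scenario": cfg.scenario,
        "true_feature_ids": [matrix.feature_ids[f] for f in true_features],
        "true_feature_indices": true_features.tolist(),
    }
    return split, test, truth
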