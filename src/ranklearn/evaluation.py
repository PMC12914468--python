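"""AUC computation and confidence intervals.

Two CI flavours are provided, matching their distinct use cases:
``bootstrap_ci`` (percentile bootstrap over resampled samples) for a single
dataset's AUC, and ``t_ci`` (t-distribution, df = n - 1) for a mean AUC
across simulation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AUCReport", "auc", "bootstrap_ci", "t_ci"]


@dataclass(frozen=True)
class AUCReport:
    auc: float
    ci_low: float
    ci_high: float
    method: str  # "bootstrap" or "t_distribution"
    n_resamples_or_reps: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n": self.n_resamples_or_reps,
        }


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one-half.

    Probability that a random case scores above a random control, ties
    contributing 0.5. Invariant under strictly increasing transforms of the
    scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n2 = int((labels == 0).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # mid-ranks handle ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2))


def bootstrap_ci(
    scores,
    labels,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> AUCReport:
    """Percentile bootstrap CI for the AUC of one score vector.

    Whole (score, label) pairs are resampled with replacement; resamples
    containing a single class are redrawn so the AUC stays defined.
    """
    rng = np.random.default_rng(rng)
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    point = auc(scores, labels)
    n = scores.shape[0]
    boot = np.empty(n_resamples)
    redraws = 0
    for b in range(n_resamples):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
            redraws += 1
            if redraws > 100 * n_resamples:
                raise RuntimeError("bootstrap could not draw two-class resamples")
        boot[b] = auc(scores[idx], lab)
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AUCReport(
        auc=point,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        method="bootstrap",
        n_resamples_or_reps=n_resamples,
    )


def t_ci(replicate_aucs, alpha: float = 0.05) -> AUCReport:
    """Mean +/- t_{alpha/2, df} x SE across replicates, df = n - 1."""
    vals = np.asarray(replicate_aucs, dtype=np.float64)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("t-distribution CI requires at least 2 replicates")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    half = tcrit * se
    return AUCReport(
        auc=mean,
        ci_low=float(max(0.0, mean - half)),
        ci_high=float(min(1.0, mean + half)),
        method="t_distribution",
        n_resamples_or_reps=n,
    )
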