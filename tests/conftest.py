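"""Shared fixtures and independent oracles.

The brute-force oracle here is the literal definition of the pairwise
concordance score — a plain Python double loop over unordered feature
pairs — kept deliberately separate from the package's optimized kernels so
it can certify them.
"""

import numpy as np
import pytest

from ranklearn import DevelopmentSplit, ExpressionMatrix, RankProfile


def brute_similarity(x, order, missing) -> int:
    """Literal double-loop concordance sum; the independent scoring oracle."""
    p = len(x)
    s = 0
    for i in range(p):
        for j in range(i + 1, p):
            if missing[i] or missing[j]:
                continue
            d = (order[i] - order[j]) * (x[i] - x[j])
            s += int(d > 0) - int(d < 0)
    return s


def brute_tss(matrix: ExpressionMatrix, profile: RankProfile) -> float:
    scores = np.array(
        [
            brute_similarity(matrix.values[k], profile.order, matrix.missing_mask[k])
            for k in range(matrix.n)
        ]
    )
    case = matrix.case_mask
    return float(scores[case].mean() - scores[~case].mean())


def random_instance(rng, p=None, n_ties=True, missing_rate=0.25):
    """A random feature vector (with ties and missing values) and profile."""
    p = p if p is not None else int(rng.integers(2, 13))
    order = rng.permutation(p) + 1
    pool = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0] if n_ties else None
    x = rng.choice(pool, size=p) if pool else rng.normal(size=p)
    miss = rng.random(p) < missing_rate
    xm = x.copy()
    xm[miss] = np.nan
    return xm, miss, RankProfile(order)


def planted_split(p=5, n_per_class=4, noise=0.0, rng=None):
    """A noiseless (or near) planted instance: cases follow the identity
    ordering scaled by 10, controls follow its reversal. The identity
    profile is the unique global optimum of the group contrast."""
    rng = rng or np.random.default_rng(0)
    base = 10.0 * np.arange(1, p + 1)
    cases = base + noise * rng.normal(size=(n_per_class, p))
    ctrls = base[::-1] + noise * rng.normal(size=(n_per_class, p))
    values = np.vstack([cases, ctrls])
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    d = ExpressionMatrix(values=values, labels=labels)
    return DevelopmentSplit(d1=d, d2=d.copy(), d3=d.copy())


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """6 samples x 4 features with a couple of missing cells."""
    values = rng.normal(50, 5, size=(6, 4))
    values[0, 1] = np.nan
    values[4, 3] = np.nan
    labels = np.array([1, 1, 1, 0, 0, 0])
    return ExpressionMatrix(values=values, labels=labels)
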