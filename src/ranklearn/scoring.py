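"""Pairwise rank-concordance scoring.

The per-sample similarity score counts, over all unordered feature pairs,
how often the sample's observed ordering of a pair agrees with the rank
profile (+1), disagrees (-1), or is undetermined because of a tie or a
missing value (0). Because only within-sample orderings enter, the score is
exactly invariant to any strictly increasing transform of a sample — in
particular to additive batch shifts.

Scores are accumulated in integer arithmetic so that accept/reject
comparisons in the optimizer are exactly reproducible.
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .matrix import ExpressionMatrix, RankProfile, SimilarityResult

__all__ = [
    "pairwise_concordance",
    "similarity_score",
    "similarity_scores",
    "total_similarity_score",
    "risk_scores",
]


@nb.njit(cache=True)
def _similarity_one(x, miss, order):  # pragma: no cover - exercised via wrappers
    """Concordant minus discordant pairs in O(p log p).

    Observed entries are laid out in profile-rank order; the score is then
    C(m,2) - tie_pairs - 2 * inversions, with inversions (strict value
    descents) counted by bottom-up merge sort. Exactly equals the literal
    double loop over unordered pairs.
    """
    p = x.shape[0]
    m = 0
    for i in range(p):
        if not miss[i]:
            m += 1
    if m < 2:
        return 0
    ranks = np.empty(m, dtype=np.int64)
    vals = np.empty(m, dtype=np.float64)
    k = 0
    for i in range(p):
        if not miss[i]:
            ranks[k] = order[i]
            vals[k] = x[i]
            k += 1
    seq = vals[np.argsort(ranks)]

    buf = seq.copy()
    tmp = np.empty(m, dtype=np.float64)
    inv = 0
    width = 1
    while width < m:
        start = 0
        while start < m:
            mid = min(start + width, m)
            end = min(start + 2 * width, m)
            i = start
            j = mid
            k2 = start
            while i < mid and j < end:
                if buf[i] <= buf[j]:
                    tmp[k2] = buf[i]
                    i += 1
                else:  # strict descent: inversion with all remaining left items
                    inv += mid - i
                    tmp[k2] = buf[j]
                    j += 1
                k2 += 1
            while i < mid:
                tmp[k2] = buf[i]
                i += 1
                k2 += 1
            while j < end:
                tmp[k2] = buf[j]
                j += 1
                k2 += 1
            for q in range(start, end):
                buf[q] = tmp[q]
            start += 2 * width
        width *= 2

    ties = 0
    run = 1
    for i in range(1, m):  # buf is now sorted
        if buf[i] == buf[i - 1]:
            run += 1
        else:
            ties += run * (run - 1) // 2
            run = 1
    ties += run * (run - 1) // 2
    total = m * (m - 1) // 2
    return total - ties - 2 * inv


@nb.njit(cache=True)
def _similarity_batch(values, miss, order):  # pragma: no cover
    n = values.shape[0]
    out = np.empty(n, dtype=np.int64)
    for k in range(n):
        out[k] = _similarity_one(values[k], miss[k], order)
    return out


@nb.njit(cache=True)
def _sign(d):  # pragma: no cover
    if d > 0.0:
        return 1
    if d < 0.0:
        return -1
    return 0


@nb.njit(cache=True)
def _delta_one(x, miss, order, i, j):  # pragma: no cover
    """Change in similarity when the ranks at positions i and j are swapped.

    Only the <= 2(p-2)+1 pairs involving i or j can change.
    """
    p = x.shape[0]
    ai = order[i]
    aj = order[j]
    d = 0
    if not miss[i]:
        xi = x[i]
        for k in range(p):
            if k == i or k == j or miss[k]:
                continue
            diff = xi - x[k]
            if diff == 0.0:
                continue
            ak = order[k]
            d += _sign((aj - ak) * diff) - _sign((ai - ak) * diff)
    if not miss[j]:
        xj = x[j]
        for k in range(p):
            if k == i or k == j or miss[k]:
                continue
            diff = xj - x[k]
            if diff == 0.0:
                continue
            ak = order[k]
            d += _sign((ai - ak) * diff) - _sign((aj - ak) * diff)
    if not miss[i] and not miss[j]:
        # the (i, j) pair itself flips sign under the swap
        d -= 2 * _sign((ai - aj) * (x[i] - x[j]))
    return d


@nb.njit(cache=True)
def _delta_batch(values, miss, order, i, j):  # pragma: no cover
    n = values.shape[0]
    out = np.empty(n, dtype=np.int64)
    for k in range(n):
        out[k] = _delta_one(values[k], miss[k], order, i, j)
    return out


def _as_vector(x, missing=None):
    x = np.asarray(x, dtype=np.float64)
    if missing is None:
        missing = ~np.isfinite(x)
    else:
        missing = np.asarray(missing, dtype=bool) | ~np.isfinite(x)
    return x, missing


def pairwise_concordance(x, profile: RankProfile, i: int, j: int, missing=None) -> int:
    """Concordance of one feature pair: +1 agree, -1 disagree, 0 tie/missing.

    ``i`` and ``j`` are 0-based feature indices.
    """
    x, miss = _as_vector(x, missing)
    p = profile.p
    if x.shape[0] != p:
        raise ValueError(f"feature vector has length {x.shape[0]}, profile has p={p}")
    if not (0 <= i < p and 0 <= j < p):
        raise IndexError(f"feature indices ({i}, {j}) out of range for p={p}")
    if miss[i] or miss[j]:
        return 0
    d = (profile.order[i] - profile.order[j]) * (x[i] - x[j])
    return int(np.sign(d))


def similarity_score(x, profile: RankProfile, missing=None) -> int:
    """Similarity of one sample with a profile: sum over unordered pairs."""
    x, miss = _as_vector(x, missing)
    if x.shape[0] != profile.p:
        raise ValueError(
            f"feature vector has length {x.shape[0]}, profile has p={profile.p}"
        )
    return int(_similarity_one(x, miss, profile.order))


def similarity_scores(data: ExpressionMatrix, profile: RankProfile) -> np.ndarray:
    """Per-sample similarity scores for every row of ``data``."""
    if data.p != profile.p:
        raise ValueError(f"data has p={data.p} features, profile has p={profile.p}")
    return _similarity_batch(data.values, data.missing_mask, profile.order)


def total_similarity_score(data: ExpressionMatrix, profile: RankProfile) -> SimilarityResult:
    """Group-contrast objective: mean case similarity minus mean control similarity."""
    data.require_both_classes("total_similarity_score input")
    scores = similarity_scores(data, profile)
    u_cases = float(scores[data.case_mask].mean())
    u_controls = float(scores[~data.case_mask].mean())
    return SimilarityResult(
        per_sample=scores,
        u_cases=u_cases,
        u_controls=u_controls,
        tss=u_cases - u_controls,
    )


def risk_scores(
    test: ExpressionMatrix, profile: RankProfile, feature_ids: list[str] | None = None
) -> np.ndarray:
    """Score test samples against a learned profile; higher = more case-like.

    If ``feature_ids`` (the training feature order) is given, the test
    matrix must present the same features in the same order.
    """
    if feature_ids is not None:
        if list(test.feature_ids) != list(feature_ids):
            unmatched = sorted(
                set(test.feature_ids).symmetric_difference(feature_ids)
            ) or ["<order differs>"]
            raise ValueError(
                "test feature ids do not match the training order: "
                + ", ".join(str(u) for u in unmatched[:10])
            )
    if test.p != profile.p:
        raise ValueError(f"test has p={test.p} features, profile has p={profile.p}")
    return _similarity_batch(test.values, test.missing_mask, profile.order)
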