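"""Two-phase stochastic search for the optimal feature rank profile.

Phase 1 (specialized initialization) screens ``n_init`` random permutations,
keeping a candidate only when its similarity-score AUCs exceed 0.5 on all
three development datasets (D1 training, D2 and D3 validation) and their
mean improves on the incumbent. Phase 2 is a swap-based hill search: at each
iteration two profile positions are exchanged, and the move is accepted only
if the total similarity score (TSS) strictly increases on D1, D2 and D3
simultaneously. Checkpointed early stopping halts the search once the D1
AUC has not improved for a fraction ``g`` of iterations past the last
checkpoint.

Per-sample scores are maintained incrementally: a swap touches only the
feature pairs involving the two swapped positions, so each proposal costs
O(n * p) instead of O(n * p^2). The delta path is exact (integer
arithmetic) and is verified against full recomputation in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import auc
from .matrix import ExpressionMatrix, RankProfile
from .scoring import _delta_batch, similarity_score, similarity_scores

__all__ = [
    "SearchConfig",
    "SearchState",
    "DevelopmentSplit",
    "initialize_profile",
    "propose_swap",
    "accept_move",
    "check_early_stop",
    "delta_similarity_update",
    "fit",
]


@dataclass(frozen=True)
class SearchConfig:
    """Tuning knobs of the permutation search.

    g: stop parameter — fraction of extra iterations allowed past the last
       checkpoint without a D1 AUC improvement before halting.
    temperature: optional Metropolis-Hastings extension; ``None`` (default)
       keeps the literal strict-improvement acceptance rule.
    """

    g: float = 0.5
    n_init: int = 100
    max_iter: int = 5000
    checkpoint_interval: int = 500
    seed: int | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("stop parameter g must be positive")
        if self.n_init < 1 or self.max_iter < 1 or self.checkpoint_interval < 1:
            raise ValueError("n_init, max_iter and checkpoint_interval must be >= 1")


@dataclass(frozen=True)
class DevelopmentSplit:
    """The three labeled development datasets driving the search.

    ``d3_rows_in_d1``, when set, records that D3's rows are the given row
    indices of D1 (the resampling protocol); the optimizer then reuses D1
    scores for D3 instead of recomputing them. Purely an optimization —
    results are identical either way.
    """

    d1: ExpressionMatrix
    d2: ExpressionMatrix
    d3: ExpressionMatrix
    d3_rows_in_d1: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = self.d1.p
        for name, d in (("D1", self.d1), ("D2", self.d2), ("D3", self.d3)):
            if d.p != p:
                raise ValueError(f"{name} has p={d.p}, expected {p}")
            if d.feature_ids != self.d1.feature_ids:
                raise ValueError(f"{name} feature order differs from D1")
            d.require_both_classes(name)
        if self.d3_rows_in_d1 is not None:
            rows = np.asarray(self.d3_rows_in_d1)
            if not np.array_equal(self.d1.values[rows], self.d3.values, equal_nan=True):
                raise ValueError("d3_rows_in_d1 does not index D3's rows within D1")
            object.__setattr__(self, "d3_rows_in_d1", rows)

    @property
    def p(self) -> int:
        return self.d1.p

    @property
    def datasets(self) -> tuple[ExpressionMatrix, ...]:
        return (self.d1, self.d2, self.d3)


@dataclass
class SearchState:
    """Mutable bookkeeping of the Phase 2 search."""

    profile: RankProfile
    s1: float
    s2: float
    s3: float
    auc_train_prev: float
    auc_val1_prev: float
    auc_val2_prev: float
    last_checkpoint_t: int | None = None
    auc_at_last_checkpoint: float = -np.inf
    iterations_run: int = 0
    stopped_early: bool = False
    trajectory: list = field(default_factory=list)

    @property
    def tss_triple(self) -> tuple[float, float, float]:
        return (self.s1, self.s2, self.s3)

    def adopt(self, profile, s_triple, auc_triple) -> None:
        self.profile = profile
        self.s1, self.s2, self.s3 = s_triple
        self.auc_train_prev, self.auc_val1_prev, self.auc_val2_prev = auc_triple


def _tss(scores: np.ndarray, data: ExpressionMatrix) -> float:
    case = data.case_mask
    return float(scores[case].mean() - scores[~case].mean())


def _split_scores(split: DevelopmentSplit, profile: RankProfile) -> list[np.ndarray]:
    """Per-sample similarity scores on D1/D2/D3, reusing D1 rows for D3."""
    s1 = similarity_scores(split.d1, profile)
    s2 = similarity_scores(split.d2, profile)
    if split.d3_rows_in_d1 is not None:
        s3 = s1[split.d3_rows_in_d1]
    else:
        s3 = similarity_scores(split.d3, profile)
    return [s1, s2, s3]


def initialize_profile(
    split: DevelopmentSplit, cfg: SearchConfig, rng: np.random.Generator
) -> RankProfile:
    """Phase 1: screen random permutations with a triple AUC > 0.5 gate."""
    p = split.p
    profile = RankProfile.identity(p)
    a_aucs = [
        auc(sc, d.labels)
        for sc, d in zip(_split_scores(split, profile), split.datasets)
    ]
    for _ in range(cfg.n_init):
        cand = RankProfile.random(p, rng)
        b_aucs = [
            auc(sc, d.labels)
            for sc, d in zip(_split_scores(split, cand), split.datasets)
        ]
        if min(b_aucs) > 0.5 and np.mean(b_aucs) > np.mean(a_aucs):
            profile, a_aucs = cand, b_aucs
    return profile


def propose_swap(
    profile: RankProfile, rng: np.random.Generator
) -> tuple[RankProfile, int, int]:
    """Swap two uniformly chosen distinct positions of the profile."""
    p = profile.p
    i = int(rng.integers(p))
    j = int(rng.integers(p - 1))
    if j >= i:
        j += 1
    return profile.swap(i, j), i, j


def accept_move(state: SearchState, s4: float, s5: float, s6: float) -> bool:
    """Strict simultaneous TSS improvement on D1, D2 and D3."""
    return s4 > state.s1 and s5 > state.s2 and s6 > state.s3


def check_early_stop(state: SearchState, t: int, cfg: SearchConfig) -> bool:
    """Record checkpoints and decide whether the search should halt.

    At every multiple of ``checkpoint_interval`` the current D1 AUC is
    snapshotted; the search stops once ``t`` has run a fraction ``g`` past
    the last checkpoint with no strict D1 AUC improvement over the snapshot.
    """
    if t % cfg.checkpoint_interval == 0:
        state.last_checkpoint_t = t
        state.auc_at_last_checkpoint = state.auc_train_prev
    if state.last_checkpoint_t is None:
        return False
    return (
        t >= state.last_checkpoint_t * (1.0 + cfg.g)
        and state.auc_train_prev <= state.auc_at_last_checkpoint
    )


def delta_similarity_update(
    x, profile: RankProfile, i: int, j: int, cached_score: int, missing=None
) -> int:
    """Similarity of ``x`` with the (i, j)-swapped profile from a cached score.

    ``cached_score`` must equal ``similarity_score(x, profile)``; staleness
    is the caller's responsibility. Touches only pairs involving i or j.
    """
    x = np.asarray(x, dtype=np.float64)
    if missing is None:
        miss = ~np.isfinite(x)
    else:
        miss = np.asarray(missing, dtype=bool) | ~np.isfinite(x)
    delta = _delta_batch(x[None, :], miss[None, :], profile.order, i, j)[0]
    return int(cached_score + delta)


def fit(
    split: DevelopmentSplit,
    cfg: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RankProfile, SearchState]:
    """Run the full two-phase search and return (profile, state).

    A single seeded generator drives Phase 1 candidates and Phase 2 swap
    positions, so runs are reproducible from ``cfg.seed``.
    """
    cfg = cfg or SearchConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    profile = initialize_profile(split, cfg, rng)

    datasets = split.datasets
    cached = _split_scores(split, profile)
    s_triple = tuple(_tss(sc, d) for sc, d in zip(cached, datasets))
    auc_triple = tuple(auc(sc, d.labels) for sc, d in zip(cached, datasets))
    state = SearchState(
        profile=profile,
        s1=s_triple[0],
        s2=s_triple[1],
        s3=s_triple[2],
        auc_train_prev=auc_triple[0],
        auc_val1_prev=auc_triple[1],
        auc_val2_prev=auc_triple[2],
    )
    state.trajectory.append(
        {"t": 0, "move": None, "tss": s_triple, "auc": auc_triple}
    )

    order = profile.order.copy()
    for t in range(1, cfg.max_iter + 1):
        state.iterations_run = t
        i = int(rng.integers(split.p))
        j = int(rng.integers(split.p - 1))
        if j >= i:
            j += 1
        d1, d2 = datasets[0], datasets[1]
        delta1 = _delta_batch(d1.values, d1.missing_mask, order, i, j)
        delta2 = _delta_batch(d2.values, d2.missing_mask, order, i, j)
        if split.d3_rows_in_d1 is not None:
            delta3 = delta1[split.d3_rows_in_d1]
        else:
            d3 = datasets[2]
            delta3 = _delta_batch(d3.values, d3.missing_mask, order, i, j)
        deltas = [delta1, delta2, delta3]
        proposal_scores = [c + dl for c, dl in zip(cached, deltas)]
        s4, s5, s6 = (
            _tss(ps, d) for ps, d in zip(proposal_scores, datasets)
        )
        accepted = accept_move(state, s4, s5, s6)
        if not accepted and cfg.temperature is not None:
            gain = (s4 - state.s1) + (s5 - state.s2) + (s6 - state.s3)
            accepted = rng.random() < math.exp(min(0.0, gain) / cfg.temperature)
        if accepted:
            order[i], order[j] = order[j], order[i]
            cached = proposal_scores
            new_profile = RankProfile(order.copy())
            new_aucs = tuple(
                auc(sc, d.labels) for sc, d in zip(cached, datasets)
            )
            state.adopt(new_profile, (s4, s5, s6), new_aucs)
            state.trajectory.append(
                {"t": t, "move": (i, j), "tss": (s4, s5, s6), "auc": new_aucs}
            )
        if check_early_stop(state, t, cfg):
            state.stopped_early = True
            break

    return state.profile, state
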