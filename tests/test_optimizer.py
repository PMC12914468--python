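"""Tests for the two-phase permutation search."""

import itertools

import numpy as np
import pytest

import ranklearn as rl
from ranklearn.optimizer import (
    SearchState,
    accept_move,
    check_early_stop,
    delta_similarity_update,
    initialize_profile,
    propose_swap,
)
from ranklearn.scoring import similarity_score

from conftest import planted_split, random_instance


def _state(s=(0.0, 0.0, 0.0), auc=0.7):
    return SearchState(
        profile=rl.RankProfile([1, 2]),
        s1=s[0], s2=s[1], s3=s[2],
        auc_train_prev=auc, auc_val1_prev=auc, auc_val2_prev=auc,
    )


class TestProposeSwap:
    def test_p2_unique_other_permutation(self, rng):
        prof, i, j = propose_swap(rl.RankProfile([1, 2]), rng)
        assert prof.order.tolist() == [2, 1] and {i, j} == {0, 1}

    def test_involution(self, rng):
        prof = rl.RankProfile(rng.permutation(6) + 1)
        once, i, j = propose_swap(prof, rng)
        assert once.swap(i, j).order.tolist() == prof.order.tolist()

    def test_uniform_over_position_pairs(self):
        """Chi-square goodness of fit of swap pairs against uniform, p=4."""
        from scipy import stats

        rng = np.random.default_rng(7)
        prof = rl.RankProfile([1, 2, 3, 4])
        counts = {}
        for _ in range(10_000):
            _, i, j = propose_swap(prof, rng)
            counts[frozenset((i, j))] = counts.get(frozenset((i, j)), 0) + 1
        assert len(counts) == 6
        _, pval = stats.chisquare(list(counts.values()))
        assert pval > 1e-3


class TestAcceptMove:
    def test_equal_scores_rejected(self):
        st = _state((1.0, 2.0, 3.0))
        assert not accept_move(st, 1.0, 2.0, 3.0)

    def test_one_non_strict_coordinate_rejects(self):
        st = _state((1.0, 2.0, 3.0))
        assert not accept_move(st, 2.0, 3.0, 3.0)

    def test_strict_triple_improvement_accepts(self):
        st = _state((1.0, 2.0, 3.0))
        assert accept_move(st, 1.5, 2.5, 3.5)
        st.adopt(st.profile, (1.5, 2.5, 3.5), (0.8, 0.8, 0.8))
        assert st.tss_triple == (1.5, 2.5, 3.5)


class TestEarlyStop:
    def test_stalled_run_stops_at_expected_iteration(self):
        """With checkpoint 500 and g=0.5, a run whose training AUC never
        improves past the t=500 snapshot stops exactly at t=750."""
        cfg = rl.SearchConfig(g=0.5)
        st = _state(auc=0.7)
        stopped_at = None
        for t in range(1, 2000):
            if check_early_stop(st, t, cfg):
                stopped_at = t
                break
        assert stopped_at == 750

    def test_improvement_defers_stop(self):
        cfg = rl.SearchConfig(g=0.5)
        st = _state(auc=0.7)
        for t in range(1, 600):
            assert not check_early_stop(st, t, cfg)
        st.auc_train_prev = 0.8  # improvement after the t=500 checkpoint
        assert not check_early_stop(st, 750, cfg)

    def test_never_stops_before_first_checkpoint(self):
        cfg = rl.SearchConfig(g=0.5, checkpoint_interval=500)
        st = _state(auc=0.7)
        assert all(not check_early_stop(st, t, cfg) for t in range(1, 500))


class TestDeltaUpdate:
    def test_matches_full_recomputation(self, rng):
        """Randomized oracle equivalence, 500 trials, ties and missing."""
        for _ in range(500):
            x, miss, profile = random_instance(rng)
            p = profile.p
            i, j = rng.choice(p, size=2, replace=False)
            cached = similarity_score(x, profile)
            got = delta_similarity_update(x, profile, int(i), int(j), cached)
            assert got == similarity_score(x, profile.swap(int(i), int(j)))

    def test_swap_of_two_missing_features_is_noop(self):
        x = np.array([1.0, np.nan, 3.0, np.nan])
        prof = rl.RankProfile([2, 1, 4, 3])
        cached = similarity_score(x, prof)
        assert delta_similarity_update(x, prof, 1, 3, cached) == cached

    def test_p2_swap_negates(self):
        x = np.array([3.0, 1.0])
        prof = rl.RankProfile([1, 2])
        cached = similarity_score(x, prof)
        assert delta_similarity_update(x, prof, 0, 1, cached) == -cached


class TestInitializeProfile:
    def test_planted_data_clears_auc_gate(self, rng):
        split = planted_split(p=5)
        cfg = rl.SearchConfig(n_init=50)
        profile = initialize_profile(split, cfg, rng)
        from ranklearn.scoring import similarity_scores

        for d in split.datasets:
            assert rl.auc(similarity_scores(d, profile), d.labels) > 0.5

    def test_failed_gate_returns_seed_permutation(self, rng):
        # all-identical samples: every AUC is exactly 0.5, gate never fires
        d = rl.ExpressionMatrix(values=np.ones((4, 3)), labels=[1, 1, 0, 0])
        split = rl.DevelopmentSplit(d1=d, d2=d.copy(), d3=d.copy())
        profile = initialize_profile(split, rl.SearchConfig(n_init=1), rng)
        assert profile.order.tolist() == [1, 2, 3]

    def test_degenerate_split_rejected(self):
        d_ok = rl.ExpressionMatrix(values=np.ones((4, 3)), labels=[1, 1, 0, 0])
        d_bad = rl.ExpressionMatrix(values=np.ones((2, 3)), labels=[1, 1])
        with pytest.raises(ValueError, match="D2"):
            rl.DevelopmentSplit(d1=d_ok, d2=d_bad, d3=d_ok.copy())


class TestFit:
    def test_finds_global_optimum_on_planted_data(self):
        """On a noiseless planted instance (p=5) the search attains the TSS
        maximum certified by exhaustive enumeration of all 120 profiles."""
        split = planted_split(p=5)
        best = max(
            rl.total_similarity_score(split.d1, rl.RankProfile(np.array(perm))).tss
            for perm in itertools.permutations(range(1, 6))
        )
        cfg = rl.SearchConfig(seed=3, g=100.0, max_iter=3000)  # stop disabled
        profile, state = rl.fit(split, cfg)
        assert rl.total_similarity_score(split.d1, profile).tss == pytest.approx(best)

    def test_seeded_determinism(self):
        split = planted_split(p=5, noise=2.0)
        cfg = rl.SearchConfig(seed=11, max_iter=300)
        prof_a, state_a = rl.fit(split, cfg)
        prof_b, state_b = rl.fit(split, cfg)
        assert prof_a.order.tolist() == prof_b.order.tolist()
        assert [m["move"] for m in state_a.trajectory] == [
            m["move"] for m in state_b.trajectory
        ]

    def test_monotone_acceptance_trajectory(self):
        """Accepted TSS triples increase strictly coordinate-wise, and the
        final D1 TSS is at least the initialization's."""
        split = planted_split(p=6, noise=3.0, rng=np.random.default_rng(5))
        profile, state = rl.fit(split, rl.SearchConfig(seed=2, max_iter=600))
        triples = [m["tss"] for m in state.trajectory]
        for prev, cur in zip(triples, triples[1:]):
            assert all(c > p for c, p in zip(cur, prev))
        assert state.s1 >= triples[0][0]
        assert rl.total_similarity_score(split.d1, profile).tss == pytest.approx(
            state.s1
        )

    def test_d3_subset_optimization_matches_plain_split(self):
        """Supplying d3_rows_in_d1 must not change the fitted profile."""
        rng = np.random.default_rng(9)
        values = rng.normal(50, 5, size=(16, 8))
        values[:8, :2] += 10.0
        labels = np.array([1] * 8 + [0] * 8)
        m = rl.ExpressionMatrix(values=values, labels=labels)
        d1 = m.subset(np.r_[0:6, 8:14])
        d2 = m.subset(np.r_[6:8, 14:16])
        rows = np.array([0, 1, 8 - 2, 9 - 2])  # rows of d1
        d3 = d1.subset(rows)
        cfg = rl.SearchConfig(seed=4, max_iter=200)
        prof_plain, _ = rl.fit(rl.DevelopmentSplit(d1, d2, d3), cfg)
        prof_opt, _ = rl.fit(
            rl.DevelopmentSplit(d1, d2, d3, d3_rows_in_d1=rows), cfg
        )
        assert prof_plain.order.tolist() == prof_opt.order.tolist()
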