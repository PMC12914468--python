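"""Tests for the synthetic scenario generator."""

import numpy as np
import pytest
from scipy import stats

import ranklearn as rl
from ranklearn.scoring import similarity_scores
from ranklearn.simulate import (
    apply_batch,
    apply_correlation,
    apply_differential,
    apply_missing,
    base_matrix,
    make_splits,
)


class TestBaseMatrix:
    def test_determinism(self):
        cfg = rl.ScenarioConfig(p=50, seed=3)
        a = base_matrix(cfg, np.random.default_rng(3))
        b = base_matrix(cfg, np.random.default_rng(3))
        assert np.array_equal(a.values, b.values)

    def test_moment_ranges(self):
        """With many samples, per-feature means land in (50, 70) and
        variances in (1, 80) up to Monte-Carlo error."""
        cfg = rl.ScenarioConfig(p=40, n_cases=5000, n_controls=5000)
        m = base_matrix(cfg, np.random.default_rng(0))
        col_means = m.values.mean(axis=0)
        col_vars = m.values.var(axis=0, ddof=1)
        assert col_means.min() > 49.0 and col_means.max() < 71.0
        assert col_vars.min() > 0.5 and col_vars.max() < 90.0


class TestApplyDifferential:
    def test_one_percent_gives_three_features(self):
        cfg = rl.ScenarioConfig(diff_fraction=0.01, p=300)
        rng = np.random.default_rng(1)
        shifted, true_idx = apply_differential(base_matrix(cfg, rng), cfg, rng)
        assert len(true_idx) == 3

    def test_all_selected_features_significant(self):
        cfg = rl.ScenarioConfig(diff_fraction=0.05, p=100)
        rng = np.random.default_rng(2)
        shifted, true_idx = apply_differential(base_matrix(cfg, rng), cfg, rng)
        case = shifted.case_mask
        for f in true_idx:
            _, pval = stats.ttest_ind(
                shifted.values[case, f], shifted.values[~case, f], equal_var=False
            )
            assert pval < 0.05

    def test_null_features_type_i_calibrated(self):
        """Across seeds, non-selected features reject the equal-means null at
        roughly the nominal 5% rate."""
        cfg = rl.ScenarioConfig(diff_fraction=0.05, p=100)
        rates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            shifted, true_idx = apply_differential(base_matrix(cfg, rng), cfg, rng)
            null = np.setdiff1d(np.arange(cfg.p), true_idx)
            case = shifted.case_mask
            _, pvals = stats.ttest_ind(
                shifted.values[case][:, null],
                shifted.values[~case][:, null],
                equal_var=False,
            )
            rates.append((pvals < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_ground_truth_recovery(self):
        """True differential features carry the largest |t| statistics."""
        cfg = rl.ScenarioConfig(diff_fraction=0.01, p=300)
        rng = np.random.default_rng(4)
        shifted, true_idx = apply_differential(base_matrix(cfg, rng), cfg, rng)
        case = shifted.case_mask
        t, _ = stats.ttest_ind(
            shifted.values[case], shifted.values[~case], equal_var=False
        )
        top3 = np.argsort(np.abs(t))[-3:]
        assert set(top3) == set(true_idx)


class TestApplyMissing:
    def test_exact_count(self):
        cfg = rl.ScenarioConfig(scenario="missing", missing_rate=0.5, p=300)
        rng = np.random.default_rng(5)
        masked = apply_missing(base_matrix(cfg, rng), cfg, rng)
        assert int(masked.missing_mask.sum()) == 9000

    def test_zero_rate_identity(self):
        cfg = rl.ScenarioConfig(p=20)
        rng = np.random.default_rng(6)
        m = base_matrix(cfg, rng)
        out = apply_missing(m, cfg, rng)
        assert np.array_equal(out.values, m.values)
        assert not out.missing_mask.any()

    def test_mcar_uniform_over_columns(self):
        """Mean per-column missing fraction approximates the target rate."""
        cfg = rl.ScenarioConfig(scenario="missing", missing_rate=0.3, p=100)
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            masked = apply_missing(base_matrix(cfg, rng), cfg, rng)
            fracs.append(masked.missing_mask.mean(axis=0))
        fracs = np.vstack(fracs)
        assert abs(fracs.mean() - 0.3) < 1e-6  # exact count overall
        assert fracs.mean(axis=0).std() < 0.05  # no column bias


class TestApplyBatch:
    def test_rank_scores_invariant(self):
        cfg = rl.ScenarioConfig(scenario="batch", n_cases=30, n_controls=30)
        rng = np.random.default_rng(7)
        m = base_matrix(cfg, rng)
        shifted, groups = apply_batch(m, cfg, rng)
        profile = rl.RankProfile(rng.permutation(cfg.p) + 1)
        assert np.array_equal(
            similarity_scores(m, profile), similarity_scores(shifted, profile)
        )
        assert np.bincount(groups).tolist() == [20, 20, 20]

    def test_third_group_shift_range(self):
        cfg = rl.ScenarioConfig(scenario="batch", n_cases=30, n_controls=30)
        rng = np.random.default_rng(8)
        m = base_matrix(cfg, rng)
        shifted, groups = apply_batch(m, cfg, rng)
        delta = shifted.values[groups == 2].mean(axis=1) - m.values[
            groups == 2
        ].mean(axis=1)
        assert ((delta > 500) & (delta < 700)).all()

    def test_indivisible_partition_rejected(self):
        cfg = rl.ScenarioConfig(
            scenario="batch", n_cases=31, n_controls=29, p=10, diff_fraction=0.1
        )
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="divide"):
            apply_batch(base_matrix(cfg, rng), cfg, rng)


class TestApplyCorrelation:
    def _setup(self, corr_mean=10.0, corr_var=10.0, seed=10):
        cfg = rl.ScenarioConfig(
            scenario="correlation",
            diff_fraction=0.05,
            p=100,
            corr_shift_mean=corr_mean,
            corr_shift_variance=corr_var,
        )
        rng = np.random.default_rng(seed)
        m, true_idx = apply_differential(base_matrix(cfg, rng), cfg, rng)
        return cfg, rng, m, true_idx

    def test_induces_case_correlation(self):
        cfg, rng, m, true_idx = self._setup()
        out = apply_correlation(m, true_idx, cfg, rng)

        def mean_corr(rows):
            c = np.corrcoef(rows[:, true_idx].T)
            return c[np.triu_indices_from(c, 1)].mean()

        assert mean_corr(out.values[out.case_mask]) > mean_corr(
            out.values[~out.case_mask]
        )

    def test_controls_unchanged(self):
        cfg, rng, m, true_idx = self._setup()
        out = apply_correlation(m, true_idx, cfg, rng)
        assert np.array_equal(out.values[~out.case_mask], m.values[~m.case_mask])

    def test_degenerate_zero_shift(self):
        cfg, rng, m, true_idx = self._setup(corr_mean=0.0, corr_var=0.0)
        out = apply_correlation(m, true_idx, cfg, rng)
        assert np.array_equal(out.values, m.values)


class TestMakeSplits:
    def test_70_30_arithmetic(self):
        cfg = rl.ScenarioConfig(p=30)
        rng = np.random.default_rng(11)
        m = base_matrix(cfg, rng)
        split, test = make_splits(m, "true_differential", rng, cfg)
        assert split.d1.n + split.d2.n == 42 and test.n == 18
        assert split.d3.n == split.d2.n

    def test_batch_test_is_shifted_sixty(self):
        cfg = rl.ScenarioConfig(scenario="batch", n_cases=60, n_controls=60, p=30)
        rng = np.random.default_rng(12)
        m = base_matrix(cfg, rng)
        split, test = make_splits(m, "batch", rng, cfg)
        assert test.n == 60 and split.d1.n + split.d2.n == 60
        # every test sample was shifted upward by at least the lowest range
        originals = {s: v for s, v in zip(m.sample_ids, m.values.mean(axis=1))}
        lifted = [
            v - originals[s] for s, v in zip(test.sample_ids, test.values.mean(axis=1))
        ]
        assert min(lifted) > 100.0

    def test_all_partitions_carry_both_classes(self):
        for seed in range(5):
            cfg = rl.ScenarioConfig(p=20, seed=seed)
            split, test, _ = rl.generate_scenario(cfg)
            for d in (*split.datasets, test):
                assert d.n_cases >= 1 and d.n_controls >= 1

    def test_full_scenario_reproducible(self):
        cfg = rl.ScenarioConfig(
            scenario="missing", missing_rate=0.2, p=40, seed=21
        )
        s1, t1, tr1 = rl.generate_scenario(cfg)
        s2, t2, tr2 = rl.generate_scenario(cfg)
        assert np.array_equal(t1.values, t2.values, equal_nan=True)
        assert tr1["true_feature_ids"] == tr2["true_feature_ids"]
        assert np.array_equal(s1.d1.missing_mask, s2.d1.missing_mask)
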