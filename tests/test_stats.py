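import numpy as np
import pytest
from scipy import stats as sps

from gazepheno import stats
from gazepheno.core import GROUP_ASD, GROUP_TD


class TestCohensD:
    def test_hand_example(self):
        assert stats.cohens_d([2, 4, 6], [1, 3, 5]) == pytest.approx(0.5)

    def test_equal_groups_zero(self):
        assert stats.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 30)
        assert stats.cohens_d(a, b) == pytest.approx(-stats.cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            stats.cohens_d([1, 1, 1], [2, 2])


class TestBootstrapEffect:
    def test_identical_distributions_ci_contains_zero(self, rng):
        vals = rng.normal(0, 1, 50)
        res = stats.bootstrap_effect(vals, vals.copy(), n_iter=2000, seed=1)
        assert res.ci_low < 0 < res.ci_high
        assert res.p > 0.05

    def test_planted_one_sd_shift_recovered(self, rng):
        a = rng.normal(1.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        res = stats.bootstrap_effect(a, b, n_iter=2000, seed=2)
        assert 0.8 <= res.d <= 1.2
        assert res.p < 0.01

    def test_same_seed_identical_result(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        r1 = stats.bootstrap_effect(a, b, n_iter=500, seed=3)
        r2 = stats.bootstrap_effect(a, b, n_iter=500, seed=3)
        assert r1.d == r2.d and r1.ci_low == r2.ci_low and r1.p == r2.p


class TestEpochSampling:
    def test_pair_is_disjoint_and_in_range(self, rng):
        total, dur = 43 * 60.0, 600.0
        for _ in range(50):
            pair = stats.sample_epochs(total, dur, 2, rng)
            assert 0 <= pair.start_a <= total - dur
            assert 0 <= pair.start_b <= total - dur
            assert abs(pair.start_a - pair.start_b) >= dur

    def test_duration_equal_total_forces_zero_start(self, rng):
        assert stats.sample_epochs(600.0, 600.0, 1, rng) == 0.0

    def test_infeasible_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            stats.sample_epochs(43 * 60.0, 22 * 60.0, 2, rng)
        with pytest.raises(ValueError):
            stats.sample_epochs(100.0, 200.0, 1, rng)

    def test_exact_tiling_pair(self, rng):
        pair = stats.sample_epochs(1200.0, 600.0, 2, rng)
        assert {pair.start_a, pair.start_b} == {0.0, 600.0}

    def test_start_distribution_uniform(self):
        rng = np.random.default_rng(99)
        starts = [stats.sample_epochs(1000.0, 100.0, 1, rng)
                  for _ in range(10_000)]
        res = sps.kstest(np.asarray(starts) / 900.0, "uniform")
        assert res.pvalue > 0.01

    def test_overlapping_pair_invariant_rejected(self):
        with pytest.raises(ValueError):
            stats.EpochPair(start_a=0.0, start_b=50.0, duration_s=100.0)


class TestPartialRankCorrelation:
    def test_printed_four_point_example(self):
        r = stats.partial_rank_correlation(
            x=[1, 2, 3, 4], y=[2, 1, 4, 3], z=[1, 3, 2, 4], w=[1, 2, 3, 4])
        assert r == pytest.approx(0.8)

    def test_constant_covariates_reduce_to_spearman(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(0, 0.5, 12)
        z = np.ones(12)
        r = stats.partial_rank_correlation(x, y, z, z)
        assert r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-9)

    def test_self_partial_rejected(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValueError):
            stats.partial_rank_correlation(x, [2, 1, 4, 3], x, [1, 2, 3, 4])


class TestFDR:
    def test_hand_bh_example(self):
        np.testing.assert_allclose(stats.fdr_adjust([0.005, 0.05]),
                                   [0.01, 0.05])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(stats.fdr_adjust([0.03]), [0.03])

    def test_equal_ps_fixed_point_and_idempotence(self):
        p = np.full(5, 0.02)
        adj = stats.fdr_adjust(p)
        np.testing.assert_allclose(adj, p)
        np.testing.assert_allclose(stats.fdr_adjust(adj), adj)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0.001, 1.0, 20)
        adj = stats.fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_input(self):
        assert len(stats.fdr_adjust([])) == 0


class TestDemographicTests:
    def test_t_hand_example(self):
        t, df = stats.two_sample_t([1, 2, 3], [3, 4, 5])
        assert t == pytest.approx(-2.449, abs=1e-3)
        assert df == 4

    def test_t_equal_groups_zero(self):
        t, _ = stats.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_t_df_at_cohort_sizes(self, rng):
        t, df = stats.two_sample_t(rng.normal(size=105), rng.normal(size=48))
        assert df == 151

    def test_chi_square_sex_table(self):
        assert stats.chi_square_independence([[74, 31], [38, 10]]) == \
            pytest.approx(0.864, abs=5e-4)

    def test_chi_square_proportional_table_zero(self):
        assert stats.chi_square_independence([[10, 10], [10, 10]]) == 0.0

    def test_chi_square_hand_yates(self):
        assert stats.chi_square_independence([[20, 10], [10, 20]]) == \
            pytest.approx(5.4)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            stats.chi_square_independence([[0, 0], [5, 5]])


def _feature_df(groups, values, pids=None):
    import pandas as pd

    pids = pids or [f"p{i}" for i in range(len(groups))]
    return pd.DataFrame({"participant_id": pids, "group": groups,
                         "pct_face": values})


class TestFamiliaritySplit:
    def _metas(self, ratings):
        from gazepheno.core import ParticipantMeta

        return {f"p{i}": ParticipantMeta(f"p{i}",
                                         GROUP_ASD if i % 2 else GROUP_TD,
                                         familiarity={"EpA": r}
                                         if r is not None else {})
                for i, r in enumerate(ratings)}

    def test_rating_five_and_missing_excluded(self, rng):
        ratings = [7, 8, 2, 3, 5, None, 6, 1, 9, 2, 8, 3]
        metas = self._metas(ratings)
        df = _feature_df([metas[f"p{i}"].group for i in range(12)],
                         rng.normal(70, 5, 12))
        res = stats.familiarity_split_tests(df, metas, "EpA", ["pct_face"])
        pooled = [r for r in res if r["stratum"] == "all"][0]
        assert pooled["n_familiar"] + pooled["n_unfamiliar"] == 10

    def test_empty_stratum_skipped(self, rng):
        ratings = [1, 2, 3, 2, 1, 3]
        metas = self._metas(ratings)
        df = _feature_df([metas[f"p{i}"].group for i in range(6)],
                         rng.normal(70, 5, 6))
        res = stats.familiarity_split_tests(df, metas, "EpA", ["pct_face"])
        assert res == []

    def test_identical_distributions_small_t(self, rng):
        n = 60
        ratings = [8 if i < n // 2 else 2 for i in range(n)]
        metas = self._metas(ratings)
        df = _feature_df([metas[f"p{i}"].group for i in range(n)],
                         rng.normal(70, 5, n))
        res = stats.familiarity_split_tests(df, metas, "EpA", ["pct_face"])
        pooled = [r for r in res if r["stratum"] == "all"][0]
        assert abs(pooled["t"]) < 3


class TestSeverityCorrelation:
    def _metas(self, severities):
        from gazepheno.core import ParticipantMeta

        return {f"p{i}": ParticipantMeta(f"p{i}", GROUP_ASD,
                                         severity_css=s)
                for i, s in enumerate(severities)}

    def test_monotone_severity_rho_one(self):
        vals = np.array([60.0, 65.0, 70.0, 75.0, 80.0])
        metas = self._metas(vals / 10)
        df = _feature_df([GROUP_ASD] * 5, vals)
        res = stats.severity_correlation(df, metas, ["pct_face"])
        assert res[0]["rho"] == pytest.approx(1.0)

    def test_missing_severity_dropped_pairwise(self, rng):
        metas = self._metas([3.0, None, 5.0, 7.0, None, 9.0])
        df = _feature_df([GROUP_ASD] * 6, rng.normal(70, 5, 6))
        res = stats.severity_correlation(df, metas, ["pct_face"])
        assert res[0]["n"] == 4

    def test_tied_severity_rejected(self):
        metas = self._metas([5.0] * 5)
        df = _feature_df([GROUP_ASD] * 5, [60, 61, 62, 63, 64.0])
        with pytest.raises(ValueError):
            stats.severity_correlation(df, metas, ["pct_face"])

    def test_independent_severity_small_rho(self, rng):
        n = 80
        metas = self._metas(rng.uniform(3, 10, n))
        df = _feature_df([GROUP_ASD] * n, rng.normal(70, 5, n))
        res = stats.severity_correlation(df, metas, ["pct_face"])
        assert abs(res[0]["rho"]) < 0.35
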