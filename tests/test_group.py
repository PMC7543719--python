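import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubdrs import (
    auc_logit_ci,
    build_atlas,
    fit_duration_lme,
    fit_duration_robust,
    group_auc,
    mean_fc,
    ranksum_one_tailed,
)
from hubdrs.connectivity import KIND_EPOCH_MEAN, ConnectivityMatrix
from hubdrs import drop_interhemispheric

from conftest import brute_force_drs, random_epoch_mean


class TestMeanFc:
    def test_constant_offdiagonal(self, atlas10):
        w = 0.4
        vals = np.full((10, 10), w)
        np.fill_diagonal(vals, 1.0)
        fc = ConnectivityMatrix(values=vals, atlas=atlas10, kind=KIND_EPOCH_MEAN)
        assert mean_fc(fc) == pytest.approx(w)

    def test_balanced_positive_negative_cancel(self, atlas4):
        vals = np.eye(4)
        r = 0.3
        vals[0, 1] = vals[1, 0] = r
        vals[2, 3] = vals[3, 2] = -r
        fc = ConnectivityMatrix(values=vals, atlas=atlas4, kind=KIND_EPOCH_MEAN)
        assert mean_fc(fc) == pytest.approx(0.0)

    def test_matches_upper_triangle_oracle(self, atlas10):
        fc = random_epoch_mean(atlas10, np.random.default_rng(0))
        oracle = np.mean([fc.values[i, j] for i in range(10)
                          for j in range(i + 1, 10)])
        assert mean_fc(fc) == pytest.approx(oracle, abs=1e-12)

    def test_masked_matrix_rejected(self, atlas10):
        fc = drop_interhemispheric(random_epoch_mean(atlas10,
                                                     np.random.default_rng(1)))
        with pytest.raises(ValueError, match="masked"):
            mean_fc(fc)


class TestGroupAuc:
    def test_perfect_separation(self):
        assert group_auc([0.1, 0.2, 0.3], [0.5, 0.6]) == 1.0

    def test_identical_values(self):
        assert group_auc([0.4, 0.4], [0.4, 0.4, 0.4]) == 0.5

    def test_matches_228_pair_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.uniform(0, 1, 12).round(1)  # rounding forces ties
            y = rng.uniform(0, 1, 19).round(1)
            assert group_auc(x, y) == pytest.approx(
                brute_force_drs(x, y), abs=1e-12
            )

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=12),
        st.lists(st.integers(0, 10), min_size=1, max_size=19),
    )
    def test_pair_enumeration_property(self, x, y):
        assert group_auc(x, y) == pytest.approx(brute_force_drs(x, y), abs=1e-12)


class TestAucLogitCi:
    def test_reproduces_published_interval(self):
        lo, hi = auc_logit_ci(0.76, 12, 19, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.54, 0.90)

    def test_symmetric_about_half_for_equal_groups(self):
        lo, hi = auc_logit_ci(0.5, 10, 10)
        assert lo + hi == pytest.approx(1.0)

    def test_higher_level_interval_strictly_contains_lower(self):
        lo95, hi95 = auc_logit_ci(0.7, 12, 19, 0.95)
        lo99, hi99 = auc_logit_ci(0.7, 12, 19, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.01, 0.99), st.integers(2, 50), st.integers(2, 50))
    def test_bounds_always_inside_unit_interval(self, auc, n1, n2):
        lo, hi = auc_logit_ci(auc, n1, n2)
        assert 0.0 < lo < auc < hi < 1.0 or lo < auc < hi

    def test_degenerate_auc_rejected(self):
        for a in (0.0, 1.0):
            with pytest.raises(ValueError):
                auc_logit_ci(a, 12, 19)


class TestRanksum:
    def test_small_tie_free_sample_is_exact(self):
        res = ranksum_one_tailed([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 6)

    def test_all_tied_samples_give_no_evidence(self):
        res = ranksum_one_tailed([1.0], [1.0])
        assert res.p_value >= 0.5

    def test_large_sample_uses_asymptotic_path(self):
        rng = np.random.default_rng(3)
        res = ranksum_one_tailed(rng.normal(size=12), rng.normal(size=19))
        assert res.method == "asymptotic"

    def test_approximation_close_to_permutation_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.6, 1.0, 19)
        p = ranksum_one_tailed(x, y).p_value
        # Monte-Carlo permutation oracle: one-tailed p = P(U_x_perm <= U_x_obs)
        pooled = np.concatenate([x, y])
        from scipy.stats import rankdata

        def u_of_x(arr2d):
            ranks = rankdata(arr2d, axis=1)
            return ranks[:, :12].sum(axis=1) - 12 * 13 / 2

        obs = u_of_x(pooled[None, :])[0]
        n_perm = 100_000
        prng = np.random.default_rng(5)
        perms = np.array([prng.permutation(pooled) for _ in range(n_perm)])
        p_mc = float(np.mean(u_of_x(perms) <= obs))
        assert abs(p - p_mc) < 0.01


class TestFitDurationRobust:
    def test_noise_free_line_recovered_exactly(self):
        dur = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 5.0, 10.0])
        a, b = 0.1, 0.05
        y = a + b * np.log10(dur)
        res = fit_duration_robust(y, dur)
        assert res.slope == pytest.approx(b, abs=1e-8)
        assert res.intercept == pytest.approx(a, abs=1e-8)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert res.lrt_p < 1e-6

    def test_null_type_one_error_controlled(self):
        # mean FC independent of duration: p < 0.05 should be rare
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            dur = 10 ** rng.uniform(0.3, 1.6, 31)
            y = rng.normal(0.15, 0.01, 31)
            if fit_duration_robust(y, dur).lrt_p < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10

    def test_outlier_resistance_versus_least_squares(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        dur = 10 ** rng.uniform(0.3, 1.6, 30)
        b = 0.05
        y = 0.1 + b * np.log10(dur) + rng.normal(0, 0.001, 30)
        dur = np.append(dur, 20.0)
        y = np.append(y, 5.0)  # gross outlier
        robust = fit_duration_robust(y, dur)
        X = sm.add_constant(np.log10(dur))
        ols_slope = sm.OLS(y, X).fit().params[1]
        assert abs(robust.slope - b) < 0.1 * b
        assert abs(ols_slope - b) > abs(robust.slope - b)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_duration_robust([0.1, 0.2], [1.0, 2.0])  # too few
        with pytest.raises(ValueError):
            fit_duration_robust([0.1, 0.2, 0.3], [1.0, -2.0, 3.0])
        with pytest.raises(ValueError):
            fit_duration_robust([0.1, 0.2, 0.3], [5.0, 5.0, 5.0])


class TestFitDurationLme:
    def test_recovers_planted_slope_and_segment_offsets(self):
        rng = np.random.default_rng(8)
        n, b, c = 60, 0.05, 0.02
        dur = 10 ** rng.uniform(0.3, 1.6, n)
        rows_y, rows_d, rows_s = [], [], []
        for k, off in enumerate((-c, 0.0, c), start=1):
            rows_y.append(0.1 + off + b * np.log10(dur)
                          + rng.normal(0, 0.005, n))
            rows_d.append(dur)
            rows_s.append(np.full(n, k))
        res = fit_duration_lme(np.concatenate(rows_y), np.concatenate(rows_d),
                               np.concatenate(rows_s))
        assert abs(res.slope - b) < 2 * res.slope_se
        assert res.lrt_p < 0.01

    def test_null_model_rarely_rejected(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            dur = np.tile(10 ** rng.uniform(0.3, 1.6, 20), 3)
            seg = np.repeat([1, 2, 3], 20)
            y = rng.normal(0.15, 0.01, 60)
            if fit_duration_lme(y, dur, seg).lrt_p < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10

    def test_single_segment_is_an_error(self):
        with pytest.raises(ValueError, match="fit_duration_robust"):
            fit_duration_lme([0.1, 0.2, 0.3], [1.0, 2.0, 3.0], [1, 1, 1])
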