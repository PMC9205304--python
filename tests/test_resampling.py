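"""Bootstrap, leave-one-out cross-validation and permutation tests."""

import numpy as np
import pytest

import endosex as es
from endosex.exceptions import BootstrapError

from conftest import brute_force_grid_threshold


class TestBootstrap:
    def test_zero_variance_collapses_ci(self):
        res = es.bootstrap_ci(
            [5.0] * 6, [20.0] * 6, es.equal_error_threshold,
            n_replicates=50, seed=0,
        )
        assert res.ci_low == res.ci_high == res.point

    def test_seed_determinism(self, hatchling_sample):
        f, m = hatchling_sample
        a = es.bootstrap_ci(f, m, es.equal_error_threshold, n_replicates=100, seed=9)
        b = es.bootstrap_ci(f, m, es.equal_error_threshold, n_replicates=100, seed=9)
        assert (a.point, a.ci_low, a.ci_high) == (b.point, b.ci_low, b.ci_high)

    def test_interval_contains_bootstrap_median(self, hatchling_sample):
        f, m = hatchling_sample
        res = es.bootstrap_ci(
            f, m, es.equal_error_threshold,
            n_replicates=200, seed=4, keep_replicates=True,
        )
        med = np.nanmedian(res.replicates)
        assert res.ci_low <= med <= res.ci_high

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (50, 800):
            cfg = es.scenario_config("hatchling_naive", seed=6, n_female=n, n_male=n)
            ds = es.generate_hormone_dataset(cfg)
            res = es.bootstrap_ci(
                ds.hormone_values("F"), ds.hormone_values("M"),
                es.equal_error_threshold, n_replicates=200, seed=6,
            )
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0]

    def test_too_many_failures_error(self):
        # succeeds on the original sample (all values distinct) but fails
        # on nearly every bootstrap replicate (which contains duplicates)
        def flaky(f, m):
            if len(np.unique(f)) < len(f):
                raise RuntimeError("duplicate draw")
            return 1.0

        with pytest.raises(BootstrapError):
            es.bootstrap_ci([1, 2, 3], [4, 5, 6], flaky, n_replicates=20, seed=0)


class TestLOOCV:
    def test_separated_data_zero_error(self, toy_separated):
        cv = es.loocv_threshold_error(toy_separated, estimator="T_E")
        assert (cv.err_female, cv.err_male, cv.err_overall) == (0.0, 0.0, 0.0)
        assert cv.n_folds == 10

    @pytest.mark.parametrize("estimator,objective", [
        ("T_E", lambda ef, em: abs(ef - em)),
        ("T_m", lambda ef, em: ef + em),
    ])
    def test_matches_per_fold_refit_oracle(self, estimator, objective):
        f = [10.0, 20.0, 30.0]
        m = [25.0, 35.0, 45.0]
        mis_f = mis_m = 0
        for i in range(3):
            thr, _ = brute_force_grid_threshold(
                [v for j, v in enumerate(f) if j != i], m, 0.1, objective
            )
            mis_f += f[i] > thr
        for j in range(3):
            thr, _ = brute_force_grid_threshold(
                f, [v for k, v in enumerate(m) if k != j], 0.1, objective
            )
            mis_m += m[j] <= thr
        # explicit smallest-value tie rule to match the oracle's convention
        cv = es.loocv_threshold_error((f, m), estimator=estimator, tie="smallest")
        assert cv.err_female == pytest.approx(mis_f / 3)
        assert cv.err_male == pytest.approx(mis_m / 3)
        assert cv.err_overall == pytest.approx((mis_f + mis_m) / 6)

    def test_overall_is_sample_weighted(self, hatchling_sample):
        f, m = hatchling_sample
        cv = es.loocv_threshold_error((f, m), estimator="T_E")
        weighted = (cv.err_female * f.size + cv.err_male * m.size) / (f.size + m.size)
        assert cv.err_overall == pytest.approx(weighted)

    def test_needs_three_per_sex(self):
        with pytest.raises(ValueError):
            es.loocv_threshold_error(([1.0, 2.0], [5.0, 6.0, 7.0]))


class TestPermutationTest:
    def test_identical_groups_p_near_one(self):
        v = [3.0, 4.0, 5.0, 6.0]
        res = es.permutation_t_test(v, list(v), n_perm=500, seed=0)
        assert res.p_value > 0.9

    def test_constant_equal_groups_p_one(self):
        res = es.permutation_t_test([2.0, 2.0], [2.0, 2.0], n_perm=100, seed=0)
        assert res.p_value == 1.0

    def test_strong_signal_small_p(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 1, 20)
        y = rng.normal(0, 1, 20)
        res = es.permutation_t_test(x, y, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.ci_low < res.mean_difference < res.ci_high

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.normal(1, 1, 15).tolist()
        y = rng.normal(0, 1, 15).tolist()
        # swapping group order flips the statistic but not the p-value
        a = es.permutation_t_test(x, y, n_perm=2000, seed=5)
        b = es.permutation_t_test(y, x, n_perm=2000, seed=5)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value, abs=0.03)

    def test_seed_determinism(self):
        x, y = [1.0, 2.0, 3.0], [2.5, 3.5, 4.5]
        a = es.permutation_t_test(x, y, n_perm=200, seed=3)
        b = es.permutation_t_test(x, y, n_perm=200, seed=3)
        assert a.p_value == b.p_value


class TestFSHResponse:
    def test_no_change_pairs(self):
        pairs = [es.FSHResponse(id=str(i), pre=50.0, post=50.0) for i in range(4)]
        s = es.fsh_response_summary(pairs)
        assert (s.mean_delta, s.se_delta, s.mean_pct_change) == (0.0, 0.0, 0.0)

    def test_single_pair_arithmetic(self):
        s = es.fsh_response_summary([es.FSHResponse(id="a", pre=100.0, post=361.0)])
        assert s.mean_delta == pytest.approx(261.0)
        assert s.mean_pct_change == pytest.approx(261.0)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError, match="bad"):
            es.fsh_response_summary([es.FSHResponse(id="bad", pre=0.0, post=10.0)])

    def test_paired_extraction_from_dataset(self):
        cfg = es.scenario_config(
            "hatchling_postFSH_paired", seed=1, n_female=5, n_male=4
        )
        ds = es.generate_paired_fsh(cfg)
        pairs = es.paired_responses(ds)
        assert len(pairs) == 9
        assert all(p.post > 0 and p.pre > 0 for p in pairs)
        assert len(es.paired_responses(ds, sex="M")) == 4
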