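import numpy as np
import pytest
from scipy import stats as sps

from tauvbm.stats import _bca_percentiles, bca_ci, bonferroni, paired_t, partial_pearson


class TestPairedT:
    def test_identical_vectors_give_zero_effect(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == 0.0
        assert res.t_stat == 0.0
        assert res.p_two_sided == 1.0

    def test_closed_form_sqrt3(self):
        # d = (1, 0, 2): mean 1, sd 1, t = 1 / (1/sqrt(3)) = sqrt(3)
        res = paired_t([1.0, 0.0, 2.0], [0.0, 0.0, 0.0])
        assert res.t_stat == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_matches_scipy_ttest_rel(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        res = paired_t(a, b)
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert res.t_stat == pytest.approx(t_ref, rel=1e-12)
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-12)

    def test_swapping_sides_flips_sign_keeps_p(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        r1, r2 = paired_t(a, b), paired_t(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_incomplete_pairs_dropped(self):
        a = [1.0, np.nan, 2.0, 3.0, 0.5]
        b = [0.0, 1.0, np.nan, 1.0, 0.0]
        assert paired_t(a, b).n_pairs == 3  # rows with a NaN on either side drop

    def test_constant_nonzero_difference_flags_degenerate(self):
        res = paired_t([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert res.degenerate
        assert res.p_two_sided == 0.0


class TestPartialPearson:
    def test_no_covariates_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-9)

    def test_perfect_residualization_of_a_covariate(self, rng):
        z = rng.normal(size=40)
        x = rng.normal(size=40)
        res = partial_pearson(x, z.copy(), covariates=z)
        assert abs(res.r) < 1e-10

    def test_recursion_formula_two_covariates(self, rng):
        # fixed 10-row fixture: r_xy.zw via the recursive partial-correlation
        # formula, computed independently of the residualization route
        x, y, z, w = (rng.normal(size=10) for _ in range(4))
        y = y + 0.5 * x + 0.3 * z

        def r(a, b):
            return sps.pearsonr(a, b)[0]

        def partial1(rab, rac, rbc):
            return (rab - rac * rbc) / np.sqrt((1 - rac**2) * (1 - rbc**2))

        r_xy_z = partial1(r(x, y), r(x, z), r(y, z))
        r_xw_z = partial1(r(x, w), r(x, z), r(w, z))
        r_yw_z = partial1(r(y, w), r(y, z), r(w, z))
        expected = partial1(r_xy_z, r_xw_z, r_yw_z)
        res = partial_pearson(x, y, covariates=np.column_stack([z, w]))
        assert res.r == pytest.approx(expected, abs=1e-10)
        assert res.df == 10 - 2 - 2

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=["x", "y", "c1", "c2"])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_pearson(df.x, df.y, covariates=df[["c1", "c2"]].to_numpy())
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_two_sided == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        C = rng.normal(size=(30, 2))
        base = partial_pearson(x, y, C)
        scaled = partial_pearson(
            3.0 * x - 7.0, -0.5 * y + 2.0, np.column_stack([10 * C[:, 0] + 1, C[:, 1] / 4])
        )
        assert abs(abs(scaled.r) - abs(base.r)) < 1e-10

    def test_rank_deficient_covariates_fatal(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            partial_pearson(x, y, np.column_stack([z, 2 * z]))


class TestBcaCI:
    def test_degenerate_data_gives_point_interval(self):
        lo, hi = bca_ci(np.mean, np.full(10, 3.3), n_boot=200, seed=0)
        assert (lo, hi) == (3.3, 3.3)

    def test_forced_zero_bias_and_accel_is_percentile(self, rng):
        # with z0 = a = 0 the adjusted percentiles are exactly alpha/2 and
        # 1 - alpha/2, and the interval equals the plain percentile interval
        # computed from the same resample stream
        assert _bca_percentiles(0.0, 0.0, 0.05) == pytest.approx((0.025, 0.975))
        x = rng.normal(size=40)
        seed = 123
        lo, hi = bca_ci(
            lambda s: np.mean(s, axis=-1),
            x,
            n_boot=1000,
            seed=seed,
            force_z0=0.0,
            force_accel=0.0,
            vectorized=True,
        )
        boot_rng = np.random.default_rng(seed)
        idx = np.empty((1000, 40), dtype=int)
        idx[:, np.arange(40)] = np.arange(40)[boot_rng.integers(0, 40, size=(1000, 40))]
        boot = x[idx].mean(axis=1)
        ref = np.quantile(boot, [0.025, 0.975])
        assert (lo, hi) == pytest.approx(tuple(ref), abs=1e-12)

    def test_endpoints_within_bootstrap_range_and_monotone_alpha(self, rng):
        x = rng.exponential(size=30)
        ci95 = bca_ci(np.mean, x, n_boot=1000, alpha=0.05, seed=5)
        ci80 = bca_ci(np.mean, x, n_boot=1000, alpha=0.20, seed=5)
        assert x.min() <= ci95[0] <= ci95[1] <= x.max()
        assert ci80[0] >= ci95[0] and ci80[1] <= ci95[1]

    def test_stratified_resampling_preserves_stratum_sizes(self, rng):
        data = np.concatenate([np.zeros(10), np.ones(20)])
        strata = data.copy()
        # the fraction of ones is invariant under stratified resampling, so
        # every bootstrap statistic equals the point estimate exactly
        lo, hi = bca_ci(np.mean, data, n_boot=300, strata=strata, seed=2)
        assert (lo, hi) == pytest.approx((2 / 3, 2 / 3))

    def test_undefined_statistic_triggers_redraw_then_fatal(self, rng):
        x = rng.normal(size=6)

        def fragile(sample):
            if sample[0] != x[0]:
                raise ValueError("undefined")
            return float(np.mean(sample))

        with pytest.raises(RuntimeError, match="10%"):
            bca_ci(fragile, x, n_boot=400, seed=3)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=25)
        assert bca_ci(np.mean, x, n_boot=500, seed=9) == bca_ci(np.mean, x, n_boot=500, seed=9)


class TestBonferroni:
    def test_hand_formula(self):
        np.testing.assert_allclose(bonferroni([0.01], m=3), [0.03])
        np.testing.assert_allclose(bonferroni([0.5], m=3), [1.0])

    def test_elementwise_loop_oracle(self, rng):
        p = rng.uniform(size=12)
        expected = [min(1.0, v * 20) for v in p]
        np.testing.assert_allclose(bonferroni(p, m=20), expected)

    def test_family_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)
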