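import numpy as np
import pytest
import statsmodels.api as sm

from summr import (
    InsufficientInstrumentsError,
    egger,
    ivw,
    leave_one_out,
    orient_positive_exposure,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from summr.estimators import _weighted_median_point

from conftest import make_harmonized, random_harmonized


class TestWaldRatios:
    def test_direct_arithmetic(self):
        t = make_harmonized([0.1], [0.01], [0.05], [0.01])
        (_, est), = wald_ratios(t)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        t = make_harmonized([0.1], [0.01], [0.0], [0.01])
        (_, est), = wald_ratios(t)
        assert est.theta == 0.0

    def test_zero_exposure_effect_skipped_with_warning(self):
        t = make_harmonized([0.1, 0.0], [0.01] * 2, [0.05, 0.02], [0.01] * 2)
        with pytest.warns(UserWarning, match="zero exposure"):
            out = wald_ratios(t)
        assert len(out) == 1

    def test_matches_ratio_formula_on_random_tables(self, rng):
        t = random_harmonized(rng, J=12)
        ok = t.ok()
        for (snp, est), (_, row) in zip(wald_ratios(t), ok.iterrows()):
            assert est.theta == pytest.approx(row.beta_out / row.beta_exp, rel=1e-12)
            assert est.se == pytest.approx(row.se_out / abs(row.beta_exp), rel=1e-12)


class TestIVW:
    def test_worked_three_snp_instance(self):
        t = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                            [0.02, 0.05, 0.09], [0.01, 0.01, 0.02])
        est = ivw(t)
        assert est.theta == pytest.approx(210 / 900, rel=1e-12)

    def test_single_instrument_equals_wald_ratio(self):
        t = make_harmonized([0.1], [0.01], [0.05], [0.01])
        est = ivw(t, min_instruments=1)
        (_, wald), = wald_ratios(t)
        assert est.theta == pytest.approx(wald.theta)
        assert est.se == pytest.approx(wald.se)

    def test_insufficient_instruments_error(self):
        t = make_harmonized([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(t)

    def test_homogeneous_ratios_give_exact_theta_and_fixed_se(self):
        bx = np.array([0.1, 0.2, 0.3])
        t = make_harmonized(bx, [0.01] * 3, 0.7 * bx, [0.01] * 3)
        fixed = ivw(t, random_effects=False)
        random = ivw(t, random_effects=True)
        assert fixed.theta == pytest.approx(0.7, rel=1e-12)
        assert random.se == pytest.approx(fixed.se)  # Q = 0 -> scale floored at 1

    def test_random_effects_never_deflates_se(self, rng):
        for _ in range(20):
            t = random_harmonized(rng)
            assert ivw(t, True).se >= ivw(t, False).se - 1e-15

    def test_matches_wls_through_origin_oracle(self, rng):
        """IVW equals weighted least squares of Gamma on gamma through the
        origin (independent statsmodels fit) to 1e-10."""
        for _ in range(50):
            t = random_harmonized(rng, J=int(rng.integers(3, 12)))
            ok = t.ok()
            fit = sm.WLS(ok["beta_out"], ok[["beta_exp"]],
                         weights=1.0 / ok["se_out"] ** 2).fit()
            est = ivw(t, random_effects=False)
            assert est.theta == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_ci_brackets_estimate(self, rng):
        est = ivw(random_harmonized(rng))
        assert est.ci_low <= est.theta <= est.ci_high
        assert est.ci_high - est.theta == pytest.approx(1.96 * est.se, rel=1e-3)


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.01 + 0.3 * bx
        res = egger(make_harmonized(bx, [0.01] * 4, by, [0.01] * 4))
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope.theta == pytest.approx(0.3, abs=1e-12)

    def test_insufficient_instruments_error(self):
        t = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(t)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(50):
            t = random_harmonized(rng, J=int(rng.integers(4, 12)))
            ok = t.ok()
            X = sm.add_constant(ok["beta_exp"])
            fit = sm.WLS(ok["beta_out"], X, weights=1.0 / ok["se_out"] ** 2).fit()
            res = egger(t)
            assert res.intercept == pytest.approx(fit.params.iloc[0], abs=1e-10)
            assert res.slope.theta == pytest.approx(fit.params.iloc[1], abs=1e-10)

    def test_zero_intercept_exact_data_slope_equals_fixed_ivw(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.4 * bx  # alpha_j = 0 exactly
        t = make_harmonized(bx, [0.01] * 4, by, [0.01] * 4)
        res = egger(t)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.theta == pytest.approx(ivw(t, random_effects=False).theta, abs=1e-10)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.1, 0.2, 0.3])  # ratios 1, 2, 3
        est = weighted_median(make_harmonized(bx, [0.01] * 3, by, [0.01] * 3), n_boot=0)
        assert est.theta == pytest.approx(2.0)

    def test_majority_weight_cluster_wins(self):
        bx = np.full(10, 0.2)
        ratios = np.array([0.2] * 6 + [1.0] * 4)
        ratios = ratios + np.linspace(-0.004, 0.004, 10)  # break exact ties
        by = ratios * bx
        sy = np.array([0.005] * 6 + [0.02] * 4)  # valid cluster holds >50% weight
        est = weighted_median(make_harmonized(bx, [0.01] * 10, by, sy), n_boot=0)
        assert est.theta == pytest.approx(0.2, abs=0.05)

    def test_interpolation_formula_oracle(self, rng):
        """The estimate equals the S_j = cumsum(w') - w'/2 interpolation at
        S = 0.5, evaluated directly."""
        t = random_harmonized(rng, J=9)
        ok = t.ok()
        ratios = (ok["beta_out"] / ok["beta_exp"]).to_numpy()
        w = (ok["beta_exp"] ** 2 / ok["se_out"] ** 2).to_numpy()
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        s = np.cumsum(wn) - wn / 2
        expected = np.interp(0.5, s, r)
        est = weighted_median(t, n_boot=0)
        assert est.theta == pytest.approx(expected, rel=1e-12)

    def test_duplicated_near_zero_weight_snp_is_inert(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.1, 0.2, 0.3])
        base = _weighted_median_point(by / bx, np.ones(3))
        dup = _weighted_median_point(np.r_[by / bx, 2.0], np.r_[np.ones(3), 1e-15])
        assert dup == pytest.approx(base, abs=1e-9)

    def test_bootstrap_se_reproducible(self, rng):
        t = random_harmonized(rng)
        a = weighted_median(t, n_boot=200, seed=11)
        b = weighted_median(t, n_boot=200, seed=11)
        c = weighted_median(t, n_boot=200, seed=12)
        assert a.se == b.se
        assert a.se != c.se


class TestWeightedMode:
    def test_degenerate_density_returns_common_ratio(self):
        bx = np.full(4, 0.1)
        by = 0.3 * bx
        est = weighted_mode(make_harmonized(bx, [0.01] * 4, by, [0.01] * 4), n_boot=0)
        assert est.theta == pytest.approx(0.3)

    def test_bimodal_majority_mode(self):
        bx = np.full(10, 0.2)
        ratios = np.array([0.2] * 7 + [0.8] * 3) + np.linspace(0, 0.02, 10)
        est = weighted_mode(make_harmonized(bx, [0.01] * 10, ratios * bx, [0.01] * 10),
                            n_boot=0)
        assert est.theta == pytest.approx(0.2, abs=0.06)

    def test_bandwidth_scaling_is_continuous_not_an_error(self, rng):
        t = random_harmonized(rng)
        e1 = weighted_mode(t, phi=1.0, n_boot=0)
        e2 = weighted_mode(t, phi=2.0, n_boot=0)
        assert np.isfinite(e2.theta)
        assert abs(e2.theta - e1.theta) < 0.5

    def test_insufficient_instruments_error(self):
        t = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(t)


class TestLeaveOneOut:
    def test_row_count_matches_instruments(self, rng):
        t = random_harmonized(rng, J=3)
        assert len(leave_one_out(t)) == 3

    def test_homogeneous_table_all_equal_full_estimate(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        t = make_harmonized(bx, [0.01] * 4, 0.25 * bx, [0.01] * 4)
        full = ivw(t).theta
        for _, est in leave_one_out(t):
            assert est.theta == pytest.approx(full, rel=1e-12)

    def test_excluding_gross_outlier_moves_estimate_most(self, rng):
        t = random_harmonized(rng, J=8, theta=0.2)
        t.pairs.loc[3, "beta_out"] += 0.5  # gross outlier
        full = ivw(t).theta
        moves = {snp: abs(est.theta - full) for snp, est in leave_one_out(t)}
        assert max(moves, key=moves.get) == t.pairs.loc[3, "snp_id"]


class TestOddsRatio:
    def test_null_effect_is_or_one(self):
        est = ivw(make_harmonized([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.01] * 2))
        assert to_odds_ratio(est).odds_ratio == pytest.approx(1.0)

    def test_log_or_converts_to_reporting_scale(self):
        """ln(OR) = -0.677 corresponds to OR ~ 0.508 (an additional SD of
        schooling halving dependence risk)."""
        t = make_harmonized([0.1, 0.2], [0.01] * 2, [-0.0677, -0.1354], [0.01] * 2)
        est = to_odds_ratio(ivw(t), outcome_binary=True)
        assert est.theta == pytest.approx(-0.677, rel=1e-10)
        assert est.odds_ratio == pytest.approx(0.508, abs=0.001)

    def test_ci_ordering_preserved(self, rng):
        est = to_odds_ratio(ivw(random_harmonized(rng)))
        assert est.or_ci_low < est.odds_ratio < est.or_ci_high

    def test_continuous_outcome_is_noop_with_warning(self, rng):
        est = ivw(random_harmonized(rng))
        with pytest.warns(UserWarning):
            assert to_odds_ratio(est, outcome_binary=False) is est


class TestSignFlipInvariance:
    def test_all_but_egger_invariant_under_subset_sign_flips(self, rng):
        t = random_harmonized(rng, J=10)
        flipped = t.pairs.copy()
        mask = np.zeros(10, bool)
        mask[[1, 4, 7]] = True
        flipped.loc[mask, ["beta_exp", "beta_out"]] *= -1
        t2 = type(t)(pairs=flipped)
        assert ivw(t2).theta == pytest.approx(ivw(t).theta, abs=1e-12)
        assert weighted_median(t2, n_boot=0).theta == pytest.approx(
            weighted_median(t, n_boot=0).theta, abs=1e-12)
        assert weighted_mode(t2, n_boot=0).theta == pytest.approx(
            weighted_mode(t, n_boot=0).theta, abs=1e-9)

    def test_egger_changes_without_orientation_but_not_after(self, rng):
        t = random_harmonized(rng, J=10)
        flipped = t.pairs.copy()
        flipped.loc[[0, 2, 5], ["beta_exp", "beta_out"]] *= -1
        t2 = type(t)(pairs=flipped)
        raw_differs = abs(egger(t2).slope.theta - egger(t).slope.theta) > 1e-8
        assert raw_differs
        o1 = egger(orient_positive_exposure(t))
        o2 = egger(orient_positive_exposure(t2))
        assert o2.slope.theta == pytest.approx(o1.slope.theta, abs=1e-12)
        assert o2.intercept == pytest.approx(o1.intercept, abs=1e-12)
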