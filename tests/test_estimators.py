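"""GLS-IVW and GLS-Egger estimation, Q, model selection, OR presentation."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2

from corrmr import (
    EGGER,
    IVW,
    LDMatrix,
    MRFit,
    gls_egger,
    gls_ivw,
    q_statistic,
    select_model,
    to_odds_ratio,
    wald_ratio,
)
from corrmr.estimators import Z_95, format_or_ci

from conftest import random_pd_corr


def ivw_closed_form(bx, by, sy):
    """Classical fixed-effect IVW weighted average (independent summation)."""
    w = 1.0 / np.asarray(sy) ** 2
    slope = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sqrt(1.0 / np.sum(w * bx**2))
    return slope, se


class TestWaldRatio:
    def test_direct_division(self):
        fit = wald_ratio(0.5, 0.05, 0.1, 0.05)
        assert fit.slope == pytest.approx(0.2)
        assert fit.slope_se == pytest.approx(0.1)

    def test_null_outcome(self):
        fit = wald_ratio(0.5, 0.05, 0.0, 0.05)
        assert fit.slope == 0.0 and fit.pval == pytest.approx(1.0)

    def test_negative_exposure_effect(self):
        fit = wald_ratio(-0.2, 0.02, 0.1, 0.02)
        assert fit.slope == pytest.approx(-0.5)
        assert fit.slope_se == pytest.approx(0.1)

    def test_zero_bx_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)


class TestGlsIvw:
    def test_two_instrument_hand_example(self):
        fit = gls_ivw([1.0, 1.0], [0.2, 0.4], [0.1, 0.1])
        assert fit.slope == pytest.approx(0.3)
        assert fit.slope_se == pytest.approx(np.sqrt(0.005), abs=1e-10)
        # residuals +-0.1 with se 0.1 -> Q = 2 on 1 df
        assert fit.q_stat == pytest.approx(2.0, abs=1e-10)
        assert fit.q_df == 1

    def test_identity_ld_matches_closed_form_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 15))
            bx = rng.normal(0.2, 0.1, k)
            by = rng.normal(0.0, 0.1, k)
            sy = rng.uniform(0.02, 0.3, k)
            fit = gls_ivw(bx, by, sy)
            slope, se = ivw_closed_form(bx, by, sy)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.slope_se == pytest.approx(se, abs=1e-10)

    def test_single_instrument_reduces_to_wald(self):
        fit = gls_ivw([0.5], [0.1], [0.05])
        wald = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert fit.slope == pytest.approx(wald.slope)
        assert fit.slope_se == pytest.approx(wald.slope_se)

    def test_duplicated_instrument_matches_single_wald(self):
        """2x2 GLS with near-unit correlation collapses the duplicate row."""
        r = np.array([[1.0, 0.999], [0.999, 1.0]])
        ld = LDMatrix(["a", "b"], r)
        fit = gls_ivw([0.5, 0.5], [0.1, 0.1], [0.05, 0.05], ld)
        wald = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert fit.slope == pytest.approx(wald.slope, abs=1e-3)
        # explicit 2x2 GLS inversion oracle
        omega = np.outer([0.05, 0.05], [0.05, 0.05]) * r
        oi = np.linalg.inv(omega)
        bx = np.array([0.5, 0.5])
        by = np.array([0.1, 0.1])
        slope = (bx @ oi @ by) / (bx @ oi @ bx)
        se = np.sqrt(1.0 / (bx @ oi @ bx))
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.slope_se == pytest.approx(se, abs=1e-12)

    def test_orientation_invariance_under_signed_flip(self, rng):
        """Flipping (bx_i, by_i, signed r row/col i) leaves IVW unchanged."""
        k = 8
        ld = random_pd_corr(rng, k)
        bx = rng.normal(0.2, 0.1, k)
        by = rng.normal(0.05, 0.1, k)
        sy = rng.uniform(0.02, 0.2, k)
        fit0 = gls_ivw(bx, by, sy, ld)
        signs = rng.choice([-1.0, 1.0], size=k)
        fit1 = gls_ivw(bx * signs, by * signs, sy, ld.flip(signs))
        assert fit1.slope == pytest.approx(fit0.slope, abs=1e-12)
        assert fit1.slope_se == pytest.approx(fit0.slope_se, abs=1e-12)
        assert fit1.q_stat == pytest.approx(fit0.q_stat, abs=1e-10)


class TestGlsEgger:
    def test_two_instruments_saturate_the_line(self):
        fit = gls_egger([0.2, 0.5], [0.1, 0.3], [0.05, 0.05])
        assert fit.q_stat == pytest.approx(0.0, abs=1e-18)
        assert fit.q_df == 0

    def test_identity_ld_matches_wls_oracle(self, rng):
        """statsmodels WLS is the independent weighted-regression route."""
        for _ in range(25):
            k = int(rng.integers(3, 20))
            bx = np.abs(rng.normal(0.3, 0.1, k))
            by = rng.normal(0.05, 0.1, k)
            sy = rng.uniform(0.02, 0.3, k)
            fit = gls_egger(bx, by, sy)
            wls = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
            assert fit.intercept == pytest.approx(wls.params[0], abs=1e-10)
            assert fit.slope == pytest.approx(wls.params[1], abs=1e-10)
            # WLS scales the covariance by its residual MSE; undo for the
            # fixed-variance GLS convention
            scale = np.sqrt(wls.scale)
            assert fit.intercept_se == pytest.approx(wls.bse[0] / scale, rel=1e-8)
            assert fit.slope_se == pytest.approx(wls.bse[1] / scale, rel=1e-8)

    def test_egger_q_never_exceeds_ivw_q(self, rng):
        """Adding a free intercept cannot increase the residual quadratic."""
        for _ in range(20):
            k = int(rng.integers(3, 15))
            ld = random_pd_corr(rng, k)
            bx = np.abs(rng.normal(0.3, 0.1, k))
            by = rng.normal(0.0, 0.15, k)
            sy = rng.uniform(0.02, 0.3, k)
            assert gls_egger(bx, by, sy, ld).q_stat <= gls_ivw(
                bx, by, sy, ld
            ).q_stat + 1e-10

    def test_fewer_than_two_instruments_rejected(self):
        with pytest.raises(ValueError):
            gls_egger([0.5], [0.1], [0.05])


class TestQStatistic:
    def test_zero_residuals(self):
        q, df, p = q_statistic([0.0, 0.0, 0.0], np.eye(3) * 0.01, df=2)
        assert q == 0.0 and p == pytest.approx(1.0)

    def test_hand_two_instrument_example(self):
        omega = np.eye(2) * 0.01
        q, _, _ = q_statistic([0.1, -0.1], omega, df=1)
        assert q == pytest.approx(2.0)

    def test_null_mean_matches_chi_square_df(self, rng):
        """Homogeneous-data Q has chi-square mean = df (k=20, 2000 reps)."""
        k, reps = 20, 2000
        qs = np.empty(reps)
        bx = np.full(k, 0.3)
        sy = np.full(k, 0.1)
        for i in range(reps):
            by = 0.5 * bx + sy * rng.standard_normal(k)
            qs[i] = gls_ivw(bx, by, sy).q_stat
        mc_se = qs.std(ddof=1) / np.sqrt(reps)
        assert abs(qs.mean() - (k - 1)) < 3 * mc_se

    def test_nonpositive_df_reports_missing_p(self):
        q, df, p = q_statistic([0.1], np.eye(1) * 0.01, df=0)
        assert p is None


class TestSelectModel:
    def make_fit(self, method, q, k=10):
        return MRFit(
            method=method, slope=0.1, slope_se=0.05, ci_low=0.0, ci_high=0.2,
            pval=0.05, q_stat=q, q_df=k - (1 if method == IVW else 2),
            q_pval=0.5, n_instruments_used=k,
            instrument_ids=tuple(f"v{i}" for i in range(k)),
        )

    def test_equal_q_prefers_ivw(self):
        assert select_model(self.make_fit(IVW, 9.0), self.make_fit(EGGER, 9.0)) == IVW

    def test_large_q_difference_selects_egger(self):
        # chi-square(1) 0.95 quantile oracle: 3.841; 10 > 3.841 -> Egger
        assert chi2.ppf(0.95, 1) == pytest.approx(3.841, abs=5e-4)
        assert select_model(self.make_fit(IVW, 19.0), self.make_fit(EGGER, 9.0)) == EGGER

    def test_two_instruments_force_ivw(self):
        assert (
            select_model(self.make_fit(IVW, 100.0, k=2), self.make_fit(EGGER, 0.0, k=2))
            == IVW
        )

    def test_mismatched_sets_rejected(self):
        a = self.make_fit(IVW, 9.0, k=10)
        b = self.make_fit(EGGER, 5.0, k=9)
        with pytest.raises(ValueError, match="instrument sets"):
            select_model(a, b)


class TestOddsRatioPresentation:
    def test_null_slope_gives_unit_or(self):
        orr, lo, hi = to_odds_ratio(0.0, 0.1)
        assert orr == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # symmetric on the log scale

    def test_printed_style_protective_example(self):
        slope = np.log(0.83)
        se = (np.log(0.88) - np.log(0.79)) / (2 * Z_95)
        assert format_or_ci(slope, se) == "OR 0.83, 95%CI 0.79; 0.88"

    def test_printed_style_risk_example(self):
        # back-derive from the printed CI: slope at the log-scale midpoint
        slope = (np.log(1.16) + np.log(3.89)) / 2
        se = (np.log(3.89) - np.log(1.16)) / (2 * Z_95)
        assert format_or_ci(slope, se) == "OR 2.12, 95%CI 1.16; 3.89"


def test_egger_recovers_slope_and_intercept_in_simulation(rng):
    """k=50 independent instruments, slope 0.2, directional intercept 0.05."""
    reps = 200
    slopes = np.empty(reps)
    intercepts = np.empty(reps)
    for i in range(reps):
        k = 50
        bx = np.abs(rng.normal(0.3, 0.1, k))
        sy = np.full(k, 0.05)
        by = 0.2 * bx + 0.05 + sy * rng.standard_normal(k)
        fit = gls_egger(bx, by, sy)
        slopes[i], intercepts[i] = fit.slope, fit.intercept
    for est, target in ((slopes, 0.2), (intercepts, 0.05)):
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - target) < 3 * mc_se


def test_egger_and_ivw_agree_without_pleiotropy(rng):
    """Null reps: |slope difference| below combined SEs in >= 95% of cases."""
    reps, k = 500, 30
    agree = 0
    for _ in range(reps):
        # dispersed effect sizes: with tightly clustered bx the Egger
        # slope is barely identified and its SE balloons
        bx = rng.exponential(0.2, k)
        sy = np.full(k, 0.05)
        by = 0.2 * bx + sy * rng.standard_normal(k)
        fi = gls_ivw(bx, by, sy)
        fe = gls_egger(bx, by, sy)
        if abs(fi.slope - fe.slope) < fi.slope_se + fe.slope_se:
            agree += 1
    assert agree / reps >= 0.95
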