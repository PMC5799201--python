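"""IVW, bivariate-normal MLE and MR-Egger estimators."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from summr import (CollinearityError, DomainError, EstimationError,
                   InsufficientDataError, egger_regression, ivw_estimate,
                   mle_estimate, wald_summary)
from summr.estimators import _loglik

from .conftest import make_instruments


class TestWaldSummary:
    # (beta, se) -> published OR (95% CI) and P, reproduced at printed
    # precision; one unit in the last printed digit is attributable to the
    # inputs themselves being rounded to 3 dp.
    PUBLISHED = [
        (0.189, 0.148, 1.21, 0.90, 1.62, 0.201),   # all glioma, ratio method
        (0.184, 0.106, 1.20, 0.98, 1.48, 0.083),   # all glioma, likelihood
        (-0.471, 0.261, 0.62, 0.37, 1.04, 0.070),  # GBM, ratio method
        (-0.479, 0.186, 0.62, 0.43, 0.89, 0.010),  # GBM, likelihood
        (0.177, 0.281, 1.19, 0.69, 2.07, 0.529),   # non-GBM, ratio method
        (0.177, 0.199, 1.19, 0.81, 1.76, 0.373),   # non-GBM, likelihood
    ]

    @pytest.mark.parametrize("beta,se,or_,lo,hi,p", PUBLISHED)
    def test_reproduces_published_cells(self, beta, se, or_, lo, hi, p):
        w = wald_summary(beta, se, 0.05)
        assert w.or_ == pytest.approx(or_, abs=0.01)
        assert w.ci_low == pytest.approx(lo, abs=0.01)
        assert w.ci_high == pytest.approx(hi, abs=0.01)
        assert w.p == pytest.approx(p, abs=0.002)

    def test_null_effect(self):
        w = wald_summary(0.0, 0.2)
        assert w.or_ == 1.0 and w.p == 1.0

    def test_ci_brackets_or(self):
        w = wald_summary(0.3, 0.1)
        assert w.ci_low < w.or_ < w.ci_high

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DomainError):
            wald_summary(0.1, 0.0)


class TestIvw:
    def test_two_snp_worked_example(self):
        # Oracle: direct evaluation of the inverse-variance formulas and a
        # weighted regression through the origin give beta 0.208, se 0.08944.
        ins = make_instruments([0.5, 0.25], [0.1, 0.06], 0.05)
        est = ivw_estimate(ins)
        assert est.beta == pytest.approx(0.208, abs=1e-12)
        assert est.se == pytest.approx(0.08944271909999159, abs=1e-12)
        assert est.n_snps == 2

    def test_null_numerator(self):
        est = ivw_estimate(make_instruments([0.5, 0.2], [0.0, 0.0], 0.05))
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_single_snp_is_wald_ratio(self):
        est = ivw_estimate(make_instruments([0.4], [0.1], [0.05]))
        assert est.beta == pytest.approx(0.1 / 0.4)
        assert est.se == pytest.approx(0.05 / 0.4)

    def test_matches_wls_through_origin(self, rng):
        # Independent oracle: statsmodels WLS with no intercept.
        for _ in range(20):
            k = rng.integers(2, 12)
            x = rng.normal(0, 0.1, k)
            y = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.01, 0.2, k)
            est = ivw_estimate(make_instruments(x, y, sy))
            wls = sm.WLS(y, x[:, None], weights=sy ** -2.0).fit()
            assert est.beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_empty_and_degenerate_errors(self):
        with pytest.raises(EstimationError):
            ivw_estimate([])
        with pytest.raises(EstimationError):
            ivw_estimate(make_instruments([0.0, 0.0], [0.1, 0.2], 0.05))


class TestMle:
    def test_collapses_to_ivw_without_exposure_error(self):
        ins = make_instruments([0.5, 0.25], [0.1, 0.06], 0.05, sx=1e-8)
        ivw = ivw_estimate(ins)
        mle = mle_estimate(ins)
        assert mle.beta == pytest.approx(ivw.beta, abs=1e-4)
        assert mle.se == pytest.approx(ivw.se, abs=1e-4)

    def test_single_strong_snp_is_wald_ratio(self):
        ins = make_instruments([0.5], [0.1], [0.05], sx=[1e-6])
        assert mle_estimate(ins).beta == pytest.approx(0.2, abs=1e-4)

    def test_unbiased_under_the_generating_model(self, rng):
        # Monte-Carlo oracle: beta = 0, K = 4, errors drawn from the assumed
        # bivariate-normal model; the mean estimate is within 3 MC SEs of 0.
        xi = np.array([-0.047, -0.052, -0.056, -0.027])
        sx = np.array([0.013, 0.012, 0.013, 0.015])
        sy = np.full(4, 0.05)
        betas = []
        for _ in range(1000):
            x = rng.normal(xi, sx)
            y = rng.normal(0.0, sy)
            betas.append(mle_estimate(make_instruments(x, y, sy, sx)).beta)
        mean = np.mean(betas)
        mc_se = np.std(betas, ddof=1) / math.sqrt(len(betas))
        assert abs(mean) < 3 * mc_se

    def test_loglik_at_optimum_beats_ivw_start(self, random_instruments):
        est, fit = mle_estimate(random_instruments, return_fit=True)
        ivw = ivw_estimate(random_instruments)
        x = np.array([i.x for i in random_instruments])
        sx2 = np.array([i.sigma_x for i in random_instruments]) ** 2
        y = np.array([i.y for i in random_instruments])
        sy2 = np.array([i.sigma_y for i in random_instruments]) ** 2
        ll_start = _loglik(ivw.beta, x, x, sx2, y, sy2)
        assert fit.converged
        assert len(fit.xi) == est.n_snps
        assert fit.loglik >= ll_start - 1e-10


class TestEgger:
    def test_exact_fit_through_origin(self):
        ins = make_instruments([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], 0.05)
        res = egger_regression(ins)
        assert res.slope.beta == pytest.approx(0.2, abs=1e-10)
        assert res.intercept.estimate == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_absorbed_by_intercept(self):
        ins = make_instruments([0.1, 0.2, 0.3], [0.03, 0.05, 0.07], 0.05)
        res = egger_regression(ins)
        assert res.slope.beta == pytest.approx(0.2, abs=1e-10)
        assert res.intercept.estimate == pytest.approx(0.01, abs=1e-10)

    def test_matches_closed_form_normal_equations(self, rng):
        # Independent oracle: (D' W D)^-1 D' W y with D = [1, x], after the
        # same x >= 0 orientation.
        for _ in range(20):
            k = 10
            x = rng.normal(0, 0.08, k)
            y = rng.normal(0.01 + 0.3 * np.abs(x), 0.05)
            sy = rng.uniform(0.02, 0.1, k)
            res = egger_regression(make_instruments(x, y, sy))
            sgn = np.where(x < 0, -1, 1)
            xo, yo = x * sgn, y * sgn
            design = np.column_stack([np.ones(k), xo])
            w = np.diag(sy ** -2.0)
            coef = np.linalg.solve(design.T @ w @ design, design.T @ w @ yo)
            assert res.intercept.estimate == pytest.approx(coef[0], abs=1e-10)
            assert res.slope.beta == pytest.approx(coef[1], abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientDataError):
            egger_regression(make_instruments([0.1, 0.2], [0.02, 0.04], 0.05))

    def test_collinear_design(self):
        with pytest.raises(CollinearityError):
            egger_regression(make_instruments([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], 0.05))

    def test_t_reference_widens_small_sample_ci(self, random_instruments):
        normal = egger_regression(random_instruments, use_t=False)
        student = egger_regression(random_instruments, use_t=True)
        assert student.slope.ci_high - student.slope.ci_low \
            > normal.slope.ci_high - normal.slope.ci_low


class TestEstimatorProperties:
    def test_scale_equivariance(self, random_instruments):
        # Multiplying all exposure effects by c divides every slope by c.
        c = 2.5
        scaled = make_instruments(
            [c * i.x for i in random_instruments],
            [i.y for i in random_instruments],
            [i.sigma_y for i in random_instruments],
            [c * i.sigma_x for i in random_instruments])
        assert ivw_estimate(scaled).beta * c == pytest.approx(
            ivw_estimate(random_instruments).beta, rel=1e-10)
        assert mle_estimate(scaled).beta * c == pytest.approx(
            mle_estimate(random_instruments).beta, rel=1e-6)
        assert egger_regression(scaled).slope.beta * c == pytest.approx(
            egger_regression(random_instruments).slope.beta, rel=1e-10)

    def test_joint_negation_invariance(self, random_instruments):
        negated = make_instruments(
            [-i.x for i in random_instruments],
            [-i.y for i in random_instruments],
            [i.sigma_y for i in random_instruments],
            [i.sigma_x for i in random_instruments])
        assert ivw_estimate(negated).beta == pytest.approx(
            ivw_estimate(random_instruments).beta, rel=1e-12)
        assert mle_estimate(negated).beta == pytest.approx(
            mle_estimate(random_instruments).beta, rel=1e-6)
        assert egger_regression(negated).slope.beta == pytest.approx(
            egger_regression(random_instruments).slope.beta, rel=1e-12)

    def test_or_equals_exp_beta_exactly(self, random_instruments):
        for est in (ivw_estimate(random_instruments),
                    mle_estimate(random_instruments),
                    egger_regression(random_instruments).slope):
            assert est.or_ == pytest.approx(math.exp(est.beta), abs=1e-12)
            assert est.ci_low < est.or_ < est.ci_high
            assert 0 < est.p <= 1
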