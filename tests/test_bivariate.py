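import math

import numpy as np
import pytest
from scipy.special import logit

from hbpmeta.bivariate import (
    BivariateFit,
    InsufficientDataError,
    _profiled_loglik,
    cochran_q_i2,
    fit_bivariate_ml,
    fit_bivariate_reml,
    lr_from_sens_spec,
    pooled_summary,
    threshold_correlation,
)
from hbpmeta.io_model import StudyDataset, StudyRecord, transform_dataset


def _identical_dataset(k=5):
    return StudyDataset(
        records=tuple(StudyRecord(f"s{i}", tp=86, fp=15, fn=14, tn=85) for i in range(k))
    )


def _manual_fit(mu1, mu2, t1=0.5, t2=0.5, rho=0.0, se=0.1):
    off = rho * t1 * t2
    return BivariateFit(
        mu=np.array([mu1, mu2]),
        sigma_between=np.array([[t1 * t1, off], [off, t2 * t2]]),
        vcov_fixed=np.diag([se * se, se * se]),
        loglik=0.0,
        method="reml",
        n_studies=10,
        n_fixed=2,
        converged=True,
    )


class TestFit:
    def test_identical_studies_collapse_to_zero_heterogeneity(self):
        fit = fit_bivariate_reml(_identical_dataset())
        assert fit.tau1 == 0.0
        assert fit.tau2 == 0.0
        assert fit.mu[0] == pytest.approx(logit(86 / 100), abs=1e-5)
        assert fit.mu[1] == pytest.approx(logit(15 / 100), abs=1e-5)

    def test_too_few_studies_raises(self):
        ds = StudyDataset(records=(StudyRecord("a", tp=10, fp=2, fn=5, tn=20),))
        with pytest.raises(InsufficientDataError):
            fit_bivariate_reml(ds)

    def test_k2_warns_but_fits(self):
        ds = StudyDataset(
            records=(
                StudyRecord("a", tp=80, fp=10, fn=20, tn=90),
                StudyRecord("b", tp=60, fp=30, fn=40, tn=70),
            )
        )
        with pytest.warns(UserWarning, match="k=2"):
            fit_bivariate_reml(ds)

    def test_optimum_beats_random_feasible_points(self, six_study_dataset):
        """Probabilistic optimizer audit: no random draw improves the REML value."""
        fit = fit_bivariate_reml(six_study_dataset, seed=1)
        tr = transform_dataset(six_study_dataset)
        y = np.array([[t.y1, t.y2] for t in tr])
        v = np.array([[t.v1, t.v2] for t in tr])
        X = np.ones((len(tr), 1))
        rng = np.random.default_rng(42)
        for _ in range(100):
            t1, t2 = rng.uniform(0.01, 2.0, size=2)
            rho = rng.uniform(-0.99, 0.99)
            ll, _, _ = _profiled_loglik(t1, t2, rho, y, v, X, restricted=True)
            assert ll <= fit.loglik + 1e-8

    def test_zero_between_study_variance_equals_gls_closed_form(self, six_study_dataset):
        tr = transform_dataset(six_study_dataset)
        y = np.array([[t.y1, t.y2] for t in tr])
        v = np.array([[t.v1, t.v2] for t in tr])
        X = np.ones((len(tr), 1))
        _, beta, _ = _profiled_loglik(0.0, 0.0, 0.0, y, v, X, restricted=True)
        w1, w2 = 1 / v[:, 0], 1 / v[:, 1]
        assert beta[0] == pytest.approx(np.sum(w1 * y[:, 0]) / np.sum(w1), abs=1e-12)
        assert beta[1] == pytest.approx(np.sum(w2 * y[:, 1]) / np.sum(w2), abs=1e-12)

    def test_ml_loglik_at_least_null_structure(self, six_study_dataset):
        reml = fit_bivariate_reml(six_study_dataset, seed=0)
        ml = fit_bivariate_ml(six_study_dataset, seed=0)
        assert ml.method == "ml"
        assert reml.method == "reml"
        assert np.isfinite(ml.loglik) and np.isfinite(reml.loglik)


class TestLrFromSensSpec:
    def test_chance_line_gives_unit_ratios(self):
        assert lr_from_sens_spec(0.5, 0.5) == pytest.approx((1.0, 1.0, 1.0))

    def test_hand_worked_pair(self):
        lr_pos, lr_neg, dor = lr_from_sens_spec(0.9, 0.85)
        assert lr_pos == pytest.approx(6.0)
        assert lr_neg == pytest.approx(0.117647, abs=1e-6)
        assert dor == pytest.approx(51.0)
        # same DOR as the cross-product on the matching 2x2 table
        assert dor == pytest.approx((90 * 85) / (10 * 15))

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="continuity"):
            lr_from_sens_spec(1.0, 0.8)


class TestThresholdCorrelation:
    def test_diagonal_between_covariance_gives_zero(self):
        fit = _manual_fit(1.0, -1.0, t1=0.5, t2=0.7, rho=0.0)
        assert threshold_correlation(fit) == 0.0

    def test_zero_variance_yields_undefined_signal(self):
        fit = _manual_fit(1.0, -1.0, t1=0.0, t2=0.7)
        assert math.isnan(threshold_correlation(fit))


class TestCochranQ:
    def test_identical_studies_have_no_heterogeneity(self):
        tr = transform_dataset(_identical_dataset())
        q, i2 = cochran_q_i2(tr, "sensitivity")
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0

    def test_hand_computed_toy_logits(self):
        """y = (0, 0, 3) with equal unit variances: pooled 1, Q = 6, I2 = 66.7%."""
        from hbpmeta.io_model import TransformedStudy

        tr = [
            TransformedStudy(f"s{i}", y1=y, y2=0.1, v1=1.0, v2=1.0,
                             n_diseased=10, n_nondiseased=10, corrected=False)
            for i, y in enumerate([0.0, 0.0, 3.0])
        ]
        q, i2 = cochran_q_i2(tr, "sensitivity")
        assert q == pytest.approx(6.0)
        assert i2 == pytest.approx(66.666, abs=1e-2)


class TestPooledSummary:
    def test_chance_fit_maps_to_half_and_unit_ratios(self):
        s = pooled_summary(_manual_fit(0.0, 0.0), mc_draws=2000, seed=0)
        assert s.sensitivity == 0.5
        assert s.specificity == 0.5
        assert s.lr_pos == pytest.approx(1.0)
        assert s.lr_neg == pytest.approx(1.0)
        assert s.dor == pytest.approx(1.0)

    def test_dor_identity_holds_exactly(self, six_study_dataset):
        fit = fit_bivariate_reml(six_study_dataset, seed=0)
        s = pooled_summary(fit, transform_dataset(six_study_dataset), mc_draws=2000, seed=0)
        assert s.dor == pytest.approx(s.lr_pos / s.lr_neg, abs=1e-9)
        assert 0 <= s.i2_sens <= 100 and 0 <= s.i2_spec <= 100

    def test_monte_carlo_ci_stable_across_seeds(self):
        fit = _manual_fit(logit(0.861), logit(0.152), se=0.2)
        a = pooled_summary(fit, mc_draws=100_000, seed=1)
        b = pooled_summary(fit, mc_draws=100_000, seed=2)
        for x, y in [(a.lr_pos_ci, b.lr_pos_ci), (a.lr_neg_ci, b.lr_neg_ci), (a.dor_ci, b.dor_ci)]:
            assert abs(x[0] - y[0]) / y[0] < 0.005
            assert abs(x[1] - y[1]) / y[1] < 0.005

    def test_wald_cis_bracket_point_estimates(self, six_study_dataset):
        fit = fit_bivariate_reml(six_study_dataset, seed=0)
        s = pooled_summary(fit, mc_draws=2000, seed=0)
        assert s.sensitivity_ci[0] < s.sensitivity < s.sensitivity_ci[1]
        assert s.specificity_ci[0] < s.specificity < s.specificity_ci[1]
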