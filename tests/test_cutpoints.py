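import math

import numpy as np
import pytest
from scipy.special import expit

from hbpmeta.bivariate import InsufficientDataError
from hbpmeta.cutpoints import (
    CutpointFit,
    _wls_line,
    bootstrap_cutoff_ci,
    find_lr_thresholds,
    fit_cutpoint_model,
    lr_curves,
    optimal_cutoff_youden,
    predict_accuracy,
    select_transform,
)
from hbpmeta.io_model import StudyDataset, StudyRecord
from hbpmeta.synthetic import TWO_LINE_TRUTH, simulate_two_line


def _exact_fit(co=None, transform="log", cutoff_range=(14.96, 92.5)):
    co = dict(TWO_LINE_TRUTH if co is None else co)
    return CutpointFit(
        transform=transform,
        a_d=co["a_d"], b_d=co["b_d"], a_nd=co["a_nd"], b_nd=co["b_nd"],
        aic=0.0, weighting="sample-size",
        included_studies=("a", "b", "c"), cutoff_range=cutoff_range,
    )


class TestWlsLine:
    def test_exact_linear_data_recovered_to_1e9(self):
        x = np.array([1.0, 2.0, 3.5, 5.0])
        y = 0.7 - 1.3 * x
        a, b, rss = _wls_line(x, y, np.array([10.0, 20.0, 5.0, 8.0]))
        assert a == pytest.approx(0.7, abs=1e-9)
        assert b == pytest.approx(-1.3, abs=1e-9)
        assert rss == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_match_ols_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, 12)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 12)
        a, b, _ = _wls_line(x, y, np.ones(12))
        coef = np.polyfit(x, y, 1)
        assert b == pytest.approx(coef[0], abs=1e-10)
        assert a == pytest.approx(coef[1], abs=1e-10)

    def test_constant_x_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            _wls_line(np.ones(4), np.arange(4.0), np.ones(4))


class TestFitCutpointModel:
    def test_insufficient_cutoff_studies_rejected(self):
        ds = StudyDataset(
            records=(
                StudyRecord("a", tp=40, fp=9, fn=9, tn=40, cutoff=20.0),
                StudyRecord("b", tp=42, fp=8, fn=8, tn=41, cutoff=35.0),
                StudyRecord("c", tp=45, fp=6, fn=7, tn=44),  # no cutoff
            )
        )
        with pytest.raises(InsufficientDataError):
            fit_cutpoint_model(ds, "log")

    def test_all_equal_cutoffs_rejected(self):
        ds = StudyDataset(
            records=tuple(
                StudyRecord(f"s{i}", tp=40 + i, fp=9, fn=9, tn=40, cutoff=30.0)
                for i in range(4)
            )
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_cutpoint_model(ds, "log")

    def test_slope_recovery_from_generated_data(self):
        """Large simulated corpus: fitted slopes near the generating truth."""
        ds, co = simulate_two_line(seed=77, k=60, n_range=(300, 400),
                                  cutoff_range=(5, 150))
        fit = fit_cutpoint_model(ds, "log")
        assert fit.b_d == pytest.approx(co["b_d"], rel=0.15)
        assert fit.b_nd == pytest.approx(co["b_nd"], rel=0.15)
        assert fit.k == 60


class TestSelectTransform:
    def test_reports_all_three_aics(self):
        ds, _ = simulate_two_line(seed=8, k=15)
        fit = select_transform(ds)
        assert set(fit.aic_by_transform) == {"identity", "log", "sqrt"}
        assert fit.aic == min(fit.aic_by_transform.values())

    def test_two_distinct_cutoffs_tie_broken_toward_log(self):
        # with only two distinct cutoff values every monotone transform fits
        # the two group means equally well -> identical AICs -> log preferred
        records = tuple(
            StudyRecord(f"s{i}", tp=tp, fp=fp, fn=60 - tp, tn=80 - fp, cutoff=c)
            for i, (tp, fp, c) in enumerate(
                [(55, 20, 20.0), (52, 22, 20.0), (40, 5, 60.0), (42, 6, 60.0)]
            )
        )
        fit = select_transform(StudyDataset(records=records))
        assert fit.transform == "log"
        assert "tie" in fit.tie_note


class TestPredictAccuracy:
    def test_line_zero_crossing_gives_half_half(self):
        co = {"a_d": -2.0, "b_d": 1.0, "a_nd": -3.0, "b_nd": 1.5}
        fit = _exact_fit(co)
        sens, spec = predict_accuracy(fit, math.exp(2.0), warn_extrapolation=False)
        assert sens == pytest.approx(0.5, abs=1e-12)
        sens, spec = predict_accuracy(fit, math.exp(2.0), warn_extrapolation=False)
        spec_at = expit(-3.0 + 1.5 * 2.0)
        assert spec == pytest.approx(spec_at, abs=1e-12)

    def test_monotone_in_cutoff(self):
        fit = _exact_fit()
        grid = np.geomspace(8, 110, 50)
        sens, spec = predict_accuracy(fit, grid, warn_extrapolation=False)
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)

    def test_extrapolation_warns(self):
        fit = _exact_fit()
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_accuracy(fit, 150.0)


class TestYoudenOptimum:
    def test_symmetric_lines_peak_exactly_at_pivot(self):
        # mirror-image lines around f0 = ln 30: J is symmetric, argmax = 30
        f0, b, g = math.log(30.0), 2.0, 1.5
        co = {"a_d": -b * f0 - g, "b_d": b, "a_nd": -b * f0 + g, "b_nd": b}
        fit = _exact_fit(co, cutoff_range=(10.0, 90.0))
        c_star, j, sens, spec = optimal_cutoff_youden(fit)
        assert c_star == pytest.approx(30.0, rel=1e-6)
        assert sens == pytest.approx(spec, abs=1e-9)

    def test_report_values_reproduced_by_predict(self):
        fit = _exact_fit()
        c_star, j, sens, spec = optimal_cutoff_youden(fit)
        s2, sp2 = predict_accuracy(fit, c_star, warn_extrapolation=False)
        assert (float(s2), float(sp2)) == (sens, spec)
        assert j == pytest.approx(sens + spec - 1, abs=1e-15)

    def test_useless_marker_raises(self):
        # identical CDFs in both groups: J = 0 at every cutoff
        co = {"a_d": -2.0, "b_d": 1.0, "a_nd": -2.0, "b_nd": 1.0}
        fit = _exact_fit(co)
        with pytest.raises(ValueError, match="Youden"):
            optimal_cutoff_youden(fit)


class TestLrCurves:
    def test_dor_identity_on_grid(self):
        fit = _exact_fit()
        curves = lr_curves(fit, n_grid=200)
        dor = (curves["sens"] * curves["spec"]) / (
            (1 - curves["sens"]) * (1 - curves["spec"])
        )
        assert np.allclose(curves["lr_pos"] / curves["lr_neg"], dor, rtol=1e-10)

    def test_extrapolated_region_flagged(self):
        fit = _exact_fit()
        curves = lr_curves(fit, n_grid=500)
        g = curves["cutoff"]
        inside = (g >= 14.96) & (g <= 92.5)
        assert np.array_equal(curves["extrapolated"], ~inside)


class TestFindLrThresholds:
    def test_anchored_truth_crosses_at_published_thresholds(self):
        fit = _exact_fit()
        rule_in, rule_out, note = find_lr_thresholds(fit)
        assert rule_in == pytest.approx(41.3, abs=0.05)
        assert rule_out == pytest.approx(30.1, abs=0.05)
        assert rule_out < rule_in

    def test_trivial_target_hits_grid_edge_or_absent(self):
        fit = _exact_fit()
        rule_in, _, note = find_lr_thresholds(fit, lr_pos_target=1.0)
        # LR+ > 1 across this grid: the rule-in zone starts at the grid edge
        assert rule_in == pytest.approx(0.5 * 14.96, rel=1e-9)
        assert "entire grid" in note

    def test_unreachable_target_reported_as_absent(self):
        fit = _exact_fit()
        rule_in, _, note = find_lr_thresholds(fit, lr_pos_target=1e6)
        assert rule_in is None
        assert "not achieved" in note


class TestBootstrap:
    def test_fixed_seed_reproduces_interval(self):
        ds, _ = simulate_two_line(seed=13, k=12)
        a, fa = bootstrap_cutoff_ci(ds, "log", B=60, seed=5)
        b, fb = bootstrap_cutoff_ci(ds, "log", B=60, seed=5)
        assert a == b and fa == fb

    def test_interval_brackets_point_estimate(self):
        ds, _ = simulate_two_line(seed=13, k=12)
        fit = fit_cutpoint_model(ds, "log")
        c_star, *_ = optimal_cutoff_youden(fit)
        (lo, hi), _ = bootstrap_cutoff_ci(ds, "log", B=200, seed=5)
        assert lo <= c_star <= hi

    def test_cluster_bootstrap_covers_generating_optimum(self):
        """Scaled-down nested check: percentile CI covers the true optimum
        in a clear majority of outer replicates."""
        true_fit = _exact_fit()
        c_true, *_ = optimal_cutoff_youden(true_fit)
        covered = 0
        n_outer = 60
        for r in range(n_outer):
            ds, _ = simulate_two_line(seed=90_000 + r, k=12)
            (lo, hi), _ = bootstrap_cutoff_ci(ds, "log", B=150, seed=r)
            covered += lo <= c_true <= hi
        assert covered / n_outer >= 0.80
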