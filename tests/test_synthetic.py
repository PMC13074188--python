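import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import norm

from hbpmeta.synthetic import (
    TWO_LINE_TRUTH,
    SimulationConfig,
    published_corpus_config,
    simulate_dataset,
    simulate_from_bivariate,
    simulate_two_line,
    true_accuracy_at_cutoff,
    two_line_truth,
)


class TestTrueAccuracy:
    def test_cutoff_at_diseased_median_gives_half_sensitivity(self):
        cfg = SimulationConfig(mu_d=math.log(40), sigma_d=0.8, mu_nd=1.0, sigma_nd=1.0)
        sens, _ = true_accuracy_at_cutoff(cfg, 0.0, 0.0, 40.0)
        assert sens == pytest.approx(0.5, abs=1e-12)

    def test_identical_distributions_have_zero_youden_everywhere(self):
        cfg = SimulationConfig(mu_d=1.0, sigma_d=1.0, mu_nd=1.0, sigma_nd=1.0)
        for c in (5.0, 30.0, 90.0):
            sens, spec = true_accuracy_at_cutoff(cfg, 0.0, 0.0, c)
            assert sens + spec == pytest.approx(1.0, abs=1e-12)

    def test_unit_separation_gives_phi_of_one(self):
        cfg = SimulationConfig(
            mu_d=math.log(40) + 1, sigma_d=1.0, mu_nd=math.log(40) - 1, sigma_nd=1.0
        )
        sens, spec = true_accuracy_at_cutoff(cfg, 0.0, 0.0, 40.0)
        assert sens == pytest.approx(norm.cdf(1), abs=1e-12)
        assert spec == pytest.approx(norm.cdf(1), abs=1e-12)

    def test_monotone_in_cutoff(self):
        cfg = published_corpus_config()
        grid = np.geomspace(5, 200, 80)
        acc = [true_accuracy_at_cutoff(cfg, 0.1, -0.2, c) for c in grid]
        sens = np.array([a[0] for a in acc])
        spec = np.array([a[1] for a in acc])
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)


class TestSimulateDataset:
    def test_same_seed_reproduces_bit_exactly(self):
        cfg = published_corpus_config(seed=11)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.dataset.to_frame().equals(b.dataset.to_frame())
        assert a.true_sens == b.true_sens

    def test_margins_consistent_and_groups_above_floor(self, emulated_corpus_sim):
        cfg = emulated_corpus_sim.config
        for r in emulated_corpus_sim.dataset.records:
            assert r.n_diseased >= cfg.min_group
            assert r.n_nondiseased >= cfg.min_group
            assert cfg.n_range[0] <= r.n <= cfg.n_range[1]
            assert cfg.cutoff_range[0] <= r.cutoff <= cfg.cutoff_range[1]

    def test_no_heterogeneity_fixed_cutoff_shares_one_truth(self):
        cfg = dataclasses.replace(
            published_corpus_config(seed=2),
            tau_d=0.0,
            tau_nd=0.0,
            cutoff_law="fixed-list",
            cutoff_list=(30.0,),
        )
        sim = simulate_dataset(cfg)
        assert len(set(sim.true_sens)) == 1
        assert len(set(sim.true_spec)) == 1
        assert sim.true_sens[0] == pytest.approx(0.86, abs=1e-9)
        assert sim.true_spec[0] == pytest.approx(0.85, abs=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(prevalence=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(sigma_d=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(cutoff_range=(-1.0, 5.0))
        with pytest.raises(ValueError):
            SimulationConfig(cutoff_law="fixed-list")


class TestPaperLikeConfig:
    def test_documented_defaults(self):
        cfg = published_corpus_config()
        assert cfg.k == 12
        assert cfg.n_range == (58, 390)
        assert cfg.prevalence == pytest.approx(841 / 1761)
        assert cfg.prevalence == pytest.approx(0.4775, abs=5e-4)
        assert cfg.cutoff_range == (14.96, 92.5)
        assert cfg.cutoff_law == "log-uniform"

    def test_calibration_anchor_at_30ng(self):
        cfg = published_corpus_config()
        sens, spec = true_accuracy_at_cutoff(cfg, 0.0, 0.0, 30.0)
        assert sens == pytest.approx(0.86, abs=1e-9)
        assert spec == pytest.approx(0.85, abs=1e-9)


class TestBivariateGenerator:
    def test_deterministic_and_margins(self):
        mu = [1.5, -1.5]
        S = np.diag([0.25, 0.25])
        a = simulate_from_bivariate(mu, S, k=8, seed=3)
        b = simulate_from_bivariate(mu, S, k=8, seed=3)
        assert a.to_frame().equals(b.to_frame())
        assert all(r.n_diseased >= 5 and r.n_nondiseased >= 5 for r in a.records)


class TestTwoLineTruth:
    def test_scale_one_is_identity(self):
        assert two_line_truth(1.0) == pytest.approx(TWO_LINE_TRUTH)

    def test_scaling_preserves_accuracy_at_pivot(self):
        from scipy.special import expit

        lc = math.log(28.4)
        for s in (0.6, 0.8, 1.0):
            co = two_line_truth(s)
            sens = 1 - expit(co["a_d"] + co["b_d"] * lc)
            spec = expit(co["a_nd"] + co["b_nd"] * lc)
            assert sens == pytest.approx(
                1 - expit(TWO_LINE_TRUTH["a_d"] + TWO_LINE_TRUTH["b_d"] * lc), abs=1e-12
            )
            assert spec == pytest.approx(
                expit(TWO_LINE_TRUTH["a_nd"] + TWO_LINE_TRUTH["b_nd"] * lc), abs=1e-12
            )

    def test_generator_counts_follow_cutoffs(self):
        ds, co = simulate_two_line(seed=5, k=10)
        assert ds.k == 10
        assert co == TWO_LINE_TRUTH
        assert all(r.cutoff is not None for r in ds.records)


class TestGeneratorCalibration:
    def test_pooled_estimates_track_truth_and_threshold_effect_emerges(self):
        """150 default corpora: pooled accuracy within 0.02 of the population
        truth at the median cutoff, and |rho_b| > 0.5 in >= 90% of fits."""
        import dataclasses

        from scipy.special import expit

        from hbpmeta.bivariate import fit_bivariate_reml

        cfg0 = published_corpus_config()
        med = float(np.sqrt(14.96 * 92.5))
        t_sens, t_spec = true_accuracy_at_cutoff(cfg0, 0.0, 0.0, med)
        sens, spec, rhos = [], [], []
        for r in range(150):
            sim = simulate_dataset(dataclasses.replace(cfg0, seed=1000 + r))
            fit = fit_bivariate_reml(sim.dataset, seed=r)
            sens.append(float(expit(fit.mu[0])))
            spec.append(1 - float(expit(fit.mu[1])))
            rhos.append(fit.rho_b)
        assert abs(np.mean(sens) - t_sens) <= 0.02
        assert abs(np.mean(spec) - t_spec) <= 0.02
        finite = np.array([r for r in rhos if np.isfinite(r)])
        assert len(finite) / len(rhos) > 0.9
        assert np.mean(np.abs(finite) > 0.5) >= 0.90
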