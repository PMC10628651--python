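"""Haldane growth–irradiance model, fitting and reactor predictions."""

import numpy as np
import pandas as pd
import pytest

from phycofilm import (HaldaneParams, HaldaneRegressor, ReactorSpec,
                       fit_haldane, footprint_productivity, growth_yield,
                       haldane_mu_L, net_growth_intermittent,
                       productivity_scan)


class TestHaldaneCurve:
    def test_hand_evaluated_point(self, haldane_truth):
        p = HaldaneParams(1.0, 0.01, 150.0)
        assert haldane_mu_L(300.0, p) == pytest.approx(0.75)  # denom 300+100

    def test_optimum_and_origin(self, haldane_truth):
        assert haldane_mu_L(haldane_truth.i_opt, haldane_truth) == pytest.approx(
            haldane_truth.mu_max)
        assert haldane_mu_L(0.0, haldane_truth) == 0.0

    def test_shape_unimodal(self, haldane_truth):
        I = np.linspace(0.0, 1000.0, 2001)
        mu = haldane_mu_L(I, haldane_truth)
        i_pk = I[np.argmax(mu)]
        assert i_pk == pytest.approx(haldane_truth.i_opt, abs=1.0)
        below = I < haldane_truth.i_opt
        assert np.all(np.diff(mu[below]) > 0)       # rising limb
        above = I > haldane_truth.i_opt
        assert np.all(np.diff(mu[above]) < 0)       # photoinhibited limb

    def test_initial_slope_is_alpha(self, haldane_truth):
        I = haldane_truth.i_opt / 1000.0
        slope = haldane_mu_L(I, haldane_truth) / I
        assert slope == pytest.approx(haldane_truth.alpha, rel=0.01)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HaldaneParams(0.0, 0.01, 150.0)


class TestNetGrowthIntermittent:
    def test_continuous_limit(self, haldane_truth):
        assert net_growth_intermittent(200.0, 1.0, haldane_truth, 0.05) == \
            pytest.approx(haldane_mu_L(200.0, haldane_truth) - 0.05)

    def test_dark_respiration_only(self, haldane_truth):
        assert net_growth_intermittent(0.0, 0.5, haldane_truth, 0.07) == \
            pytest.approx(-0.07)

    def test_hand_arithmetic(self):
        p = HaldaneParams(1.0, 0.01, 150.0)
        assert net_growth_intermittent(300.0, 1 / 3, p, 0.05) == \
            pytest.approx(0.20)


class TestHaldaneFit:
    def test_noiseless_recovery(self, haldane_truth):
        I = np.array([25.0, 75.0, 150.0, 250.0, 350.0, 500.0])
        fit = fit_haldane(I, haldane_mu_L(I, haldane_truth))
        assert fit.mu_max_ == pytest.approx(haldane_truth.mu_max, rel=1e-3)
        assert fit.alpha_ == pytest.approx(haldane_truth.alpha, rel=1e-3)
        assert fit.i_opt_ == pytest.approx(haldane_truth.i_opt, rel=1e-3)
        assert fit.converged_ and fit.rss_ < 1e-12

    def test_order_invariance(self, haldane_truth):
        I = np.array([25.0, 75.0, 150.0, 250.0, 350.0, 500.0])
        y = haldane_mu_L(I, haldane_truth)
        perm = np.array([3, 0, 5, 1, 4, 2])
        f1, f2 = fit_haldane(I, y), fit_haldane(I[perm], y[perm])
        assert f1.mu_max_ == pytest.approx(f2.mu_max_, rel=1e-6)
        assert f1.i_opt_ == pytest.approx(f2.i_opt_, rel=1e-6)

    def test_light_unit_rescaling(self, haldane_truth):
        """Rescaling irradiance units rescales I_opt and α accordingly."""
        I = np.array([25.0, 75.0, 150.0, 250.0, 350.0, 500.0])
        y = haldane_mu_L(I, haldane_truth)
        f = fit_haldane(I * 10.0, y)
        assert f.i_opt_ == pytest.approx(haldane_truth.i_opt * 10, rel=1e-3)
        assert f.alpha_ == pytest.approx(haldane_truth.alpha / 10, rel=1e-3)
        assert f.mu_max_ == pytest.approx(haldane_truth.mu_max, rel=1e-3)

    def test_unidentifiable_single_level(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_haldane([100.0, 100.0, 100.0], [0.5, 0.51, 0.49])

    def test_noisy_recovery_median_error(self, haldane_truth):
        """σ = 0.02 d⁻¹ Gaussian noise, 8 light levels, 50 replicates:
        median relative error < 15 % per parameter."""
        I = np.array([25.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0])
        errs = {"mu_max": [], "alpha": [], "i_opt": []}
        for rep in range(50):
            rng = np.random.default_rng(2000 + rep)
            y = haldane_mu_L(I, haldane_truth) + rng.normal(0.0, 0.02, I.size)
            fit = fit_haldane(I, y)
            errs["mu_max"].append(abs(fit.mu_max_ - 1.0))
            errs["alpha"].append(abs(fit.alpha_ - 0.02) / 0.02)
            errs["i_opt"].append(abs(fit.i_opt_ - 150.0) / 150.0)
        for name, e in errs.items():
            assert np.median(e) < 0.15, name

    def test_sklearn_interface(self, haldane_truth):
        I = np.array([25.0, 75.0, 150.0, 250.0, 350.0, 500.0])
        est = HaldaneRegressor().fit(I.reshape(-1, 1), haldane_mu_L(I, haldane_truth))
        assert est.predict([150.0]) == pytest.approx([1.0], rel=1e-3)
        assert set(est.get_params()) == {"xatol", "fatol", "maxiter"}


class TestYieldAndProductivity:
    def test_growth_yield(self):
        assert growth_yield(0.5, 100.0) == pytest.approx(0.005)
        assert growth_yield(0.0, 50.0) == 0.0
        with pytest.raises(ValueError):
            growth_yield(0.5, 0.0)

    def test_footprint_productivity_hand_value(self):
        spec = ReactorSpec(epsilon=1 / 3, rho=1.4e5, h=1e-4)
        assert footprint_productivity(0.5, spec) == pytest.approx(21.0)

    def test_area_ratio_identity(self):
        assert ReactorSpec(epsilon=1 / 3).area_ratio == pytest.approx(3.0)
        assert ReactorSpec(epsilon=1.0).area_ratio == 1.0

    def test_continuous_baseline(self):
        spec = ReactorSpec(epsilon=1.0, rho=1.4e5, h=1e-4)
        assert footprint_productivity(0.5, spec) == pytest.approx(
            0.5 * 1.4e5 * 1e-4)


class TestProductivityScan:
    def test_continuous_column_matches_scalar_curve(self, haldane_truth):
        I = np.linspace(50, 500, 10)
        table = productivity_scan(haldane_truth, 0.05, I, [1.0])
        np.testing.assert_allclose(
            table["mu"], haldane_mu_L(I, haldane_truth) - 0.05)

    def test_grid_matches_scalar_ops_elementwise(self, haldane_truth):
        I = np.array([100.0, 300.0])
        eps = [1.0, 1 / 3]
        table = productivity_scan(haldane_truth, 0.05, I, eps, rho=1.4e5, h=1e-4)
        for _, row in table.iterrows():
            mu = net_growth_intermittent(row.i_peak, row.epsilon,
                                         haldane_truth, 0.05)
            assert row.mu == pytest.approx(mu)
            assert row.P_f == pytest.approx(footprint_productivity(
                mu, ReactorSpec(row.epsilon, 1.4e5, 1e-4)))

    def test_pf_monotone_in_inverse_epsilon(self, haldane_truth):
        """At fixed μ, footprint productivity rises as ε shrinks."""
        pfs = [footprint_productivity(0.5, ReactorSpec(e))
               for e in (1.0, 1 / 2, 1 / 3, 1 / 5)]
        assert np.all(np.diff(pfs) > 0)

    def test_observed_rows_appended(self, haldane_truth):
        obs = pd.DataFrame({"i_peak": [310.0], "epsilon": [1 / 3],
                            "mu": [0.4]})
        table = productivity_scan(haldane_truth, 0.05, [100.0], [1.0],
                                  observed=obs)
        assert (table["source"] == "observed").sum() == 1
        row = table[table["source"] == "observed"].iloc[0]
        assert row.mu_L == pytest.approx((0.4 + 0.05) * 3)

    def test_empty_grid_rejected(self, haldane_truth):
        with pytest.raises(ValueError):
            productivity_scan(haldane_truth, 0.05, [], [1.0])
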