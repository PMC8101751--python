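"""Joint abundance model: likelihood pieces, Laplace fit, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

import icebears as ib
from icebears.joint import (SurveyData, cell_probs, distance_nll,
                            flyover_nll, lambda_prior_nll, lognormal_ci)
from icebears.synthetic import latent_surfaces
from icebears.tracks import TrackData, TrackParams, track_nll


def _one_cell_setup(saltwater=1.0):
    grid = ib.make_grid(1, 1, 25.0, seed=0)
    grid.cells["saltwater_prop"] = saltwater
    cov = ib.CovariateField(
        ice=np.array([[0.9]]), dist_land=np.array([12.5]),
        rsf=np.array([1.0]), easting=np.array([12.5]),
        northing=np.array([12.5]))
    return grid, cov


class TestCoverageFraction:
    def test_visual_strip_formula(self):
        assert ib.coverage_fraction(10.0, 0.0, "ru", 500.0) == \
            pytest.approx(0.024)

    def test_thermal_footprint_formula(self):
        assert ib.coverage_fraction(0.0, 6.25, "us", 625.0) == \
            pytest.approx(0.01)

    def test_clipped_at_one(self):
        assert ib.coverage_fraction(600.0, 0.0, "ru", 500.0) == 1.0

    def test_effort_without_habitat_rejected(self):
        with pytest.raises(ValueError):
            ib.coverage_fraction(10.0, 0.0, "ru", 0.0)


class TestCellProbs:
    def test_flat_predictor_equal_areas_uniform(self):
        pi = cell_probs(np.ones(8), nu=np.zeros(8))
        np.testing.assert_allclose(pi, 1 / 8)

    def test_zero_area_cell_gets_zero(self):
        A = np.array([1.0, 0.0, 1.0])
        pi = cell_probs(A, nu=np.array([0.3, 5.0, -0.2]))
        assert pi[1] == 0.0
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_softmax_two_cells(self):
        pi = cell_probs(np.ones(2), nu=np.array([0.0, np.log(2.0)]))
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3], atol=1e-12)

    def test_normalization_from_smooth_spec(self, smooth_spec, grid):
        rng = np.random.default_rng(0)
        alpha = rng.normal(0, 0.5, smooth_spec.n_coef)
        A = grid.saltwater_area
        for t in (0, 5):
            pi = cell_probs(A, alpha=alpha, smooth_spec=smooth_spec, t=t)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_habitat_anywhere_rejected(self):
        with pytest.raises(ValueError):
            cell_probs(np.zeros(3), nu=np.zeros(3))


class TestAlphaPrior:
    def test_zero_coefficients_leave_only_normalizer(self, smooth_spec):
        lam = np.full(5, 2.0)
        expected = 0.0
        for lam_i, s in zip(lam, smooth_spec.smooths):
            expected += (-0.5 * (s.rank * np.log(lam_i) + s.log_pdet)
                         + 0.5 * s.rank * np.log(2 * np.pi))
        got = ib.joint.alpha_prior_nll(np.zeros(smooth_spec.n_coef), lam,
                                       smooth_spec)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_doubling_lambda_gaussian_algebra(self, smooth_spec):
        rng = np.random.default_rng(1)
        alpha = rng.normal(0, 1, smooth_spec.n_coef)
        lam = np.full(5, 3.0)
        base = ib.joint.alpha_prior_nll(alpha, lam, smooth_spec)
        doubled = ib.joint.alpha_prior_nll(alpha, 2 * lam, smooth_spec)
        quad = sum(lam_i * (alpha[blk] @ s.S @ alpha[blk])
                   for lam_i, s, blk in zip(lam, smooth_spec.smooths,
                                            smooth_spec.blocks))
        total_rank = sum(s.rank for s in smooth_spec.smooths)
        assert doubled - base == pytest.approx(
            0.5 * quad - 0.5 * total_rank * np.log(2.0), rel=1e-10)

    def test_nonpositive_lambda_rejected(self, smooth_spec):
        with pytest.raises(ValueError):
            ib.joint.alpha_prior_nll(np.zeros(smooth_spec.n_coef),
                                     np.array([1, 1, 0, 1, 1.0]),
                                     smooth_spec)


class TestCountNll:
    def _data(self, count, kind="thermal", platform="us"):
        grid, cov = _one_cell_setup()
        data = SurveyData(
            counts=pd.DataFrame([{"cell_id": 0, "day": 0,
                                  "platform": platform, "kind": kind,
                                  "count": count}]),
            effort=pd.DataFrame([{"cell_id": 0, "day": 0,
                                  "platform": platform,
                                  "length_km": 10.0,
                                  "footprint_km2": 6.25}]))
        return grid, data

    def test_zero_counts_give_total_intensity(self):
        grid, data = self._data(0)
        pi = np.array([[1.0]])
        a = 6.25 / 625.0
        nll = ib.joint.count_nll(data, grid, 100.0, pi, p_us=0.5, p_rus=0.4)
        assert nll == pytest.approx(100.0 * 0.5 * a, rel=1e-12)

    def test_unit_xi_makes_aux_match_thermal(self):
        grid, d_thermal = self._data(3, "thermal")
        _, d_aux = self._data(3, "aux")
        pi = np.array([[1.0]])
        a_nll = ib.joint.count_nll(d_aux, grid, 80.0, pi, 0.5, 0.4, xi=1.0)
        t_nll = ib.joint.count_nll(d_thermal, grid, 80.0, pi, 0.5, 0.4)
        assert a_nll == pytest.approx(t_nll, rel=1e-12)

    def test_pmf_normalizes_by_enumeration(self):
        pi = np.array([[1.0]])
        total = 0.0
        for c in range(51):
            grid, data = self._data(c, "visual", "ru")
            total += np.exp(-ib.joint.count_nll(data, grid, 400.0, pi,
                                                0.5, 0.45))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_positive_count_with_zero_rate_rejected(self):
        grid, data = self._data(2)
        with pytest.raises(ValueError):
            ib.joint.count_nll(data, grid, 100.0, np.array([[0.0]]), 0.5, 0.4)


class TestGroupSize:
    def test_mle_at_boundary_all_singletons(self):
        assert ib.groupsize_mle([1, 1, 1]) == 1.0

    def test_mle_is_sample_mean(self):
        assert ib.groupsize_mle([1, 1, 2]) == pytest.approx(4 / 3)

    def test_mle_maximizes_likelihood(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            g = 1 + rng.poisson(0.7, 40)
            if np.all(g == 1):
                continue
            mu = ib.groupsize_mle(g)
            nll = ib.groupsize_nll(g, mu)
            assert nll <= ib.groupsize_nll(g, mu + 0.01)
            assert nll <= ib.groupsize_nll(g, max(mu - 0.01, 1.0 + 1e-9))

    def test_sizes_below_one_rejected(self):
        with pytest.raises(ValueError):
            ib.groupsize_nll([0, 2], 1.5)


class TestJointNll:
    def _params(self, smooth_spec, scenario):
        return ib.AbundanceParams(
            log_N=np.log(scenario.true_N),
            beta=np.asarray(scenario.true_beta),
            alpha_tracks=scenario.true_alpha_tracks,
            log_lambda=np.log(np.full(len(smooth_spec.smooths), 10.0)),
            log_eta=np.log(scenario.true_eta),
            log_xi=np.log(scenario.true_xi),
            log_sigma=np.log(scenario.true_sigma),
            logit_p_us=special.logit(scenario.true_p_us),
            log_mu_g_m1=np.log(scenario.true_mu_g - 1.0),
            g0=scenario.g0)

    def test_additivity_of_submodel_nlls(self, grid, cov, survey,
                                         smooth_spec, scenario):
        """The joint nll equals the sum of independently computed
        submodel nlls and priors."""
        data, _ = survey
        params = self._params(smooth_spec, scenario)
        rng = np.random.default_rng(3)
        alpha = rng.normal(0, 0.3, smooth_spec.n_coef)
        total = ib.joint_nll(params, alpha, data, grid, cov, smooth_spec)

        # independent reconstruction from the public pieces
        S, T = cov.n_cells, cov.n_days
        X = ib.build_track_design(cov)
        logZ = X @ params.beta + (-50.0) * cov.water99.T.ravel()
        Z = np.exp(logZ)
        Z_std = (Z / Z.mean()).reshape(T, S).T
        A = grid.saltwater_area
        pi = np.empty((S, T))
        for t in range(T):
            off = (-50.0 * cov.water99[:, t]
                   + params.alpha_tracks * Z_std[:, t])
            pi[:, t] = cell_probs(A, alpha=alpha, smooth_spec=smooth_spec,
                                  t=t, offset=off)
        p_rus = ib.halfnormal_p(params.sigma, data.w, params.g0)
        pieces = (
            track_nll(data.track,
                      TrackParams(beta=params.beta, eta=params.eta), cov)
            + ib.joint.count_nll(data, grid, params.N, pi, params.p_us,
                                 p_rus, xi=params.xi)
            + distance_nll(params.sigma, data.distance_data)
            + flyover_nll(data.trials, params.p_us)
            + ib.groupsize_nll(data.group_sizes, params.mu_g)
            + ib.joint.alpha_prior_nll(alpha, params.lam, smooth_spec)
            + lambda_prior_nll(params.lam))
        assert total == pytest.approx(pieces, rel=1e-10, abs=1e-7)

    def test_finite_at_generating_parameters(self, small_grid, small_cov):
        spec = ib.build_smooths(small_cov)
        for seed in range(20):
            sc = ib.SimScenario(T=3, true_N=150, seed=4000 + seed)
            data = ib.simulate_survey(small_grid, small_cov, sc)
            params = self._params(spec, sc)
            val = ib.joint_nll(params, np.zeros(spec.n_coef), data,
                               small_grid, small_cov, spec)
            assert np.isfinite(val)


class TestLaplaceFit:
    def test_single_cell_poisson_mle(self):
        """With one cell, full coverage and perfect detection, the MLE of
        group abundance is the observed count."""
        grid, cov = _one_cell_setup()
        C = 17
        data = SurveyData(
            counts=pd.DataFrame([{"cell_id": 0, "day": 0, "platform": "us",
                                  "kind": "thermal", "count": C}]),
            effort=pd.DataFrame([{"cell_id": 0, "day": 0, "platform": "us",
                                  "length_km": 0.0,
                                  "footprint_km2": 625.0}]))
        fit = ib.laplace_fit(data, grid, cov, None, g0=1.0,
                             fix={"logit_p_us": 20.0})
        assert fit.N_hat == pytest.approx(C, rel=1e-6)

    def test_self_consistency_on_expected_counts(self):
        """Fitting to round(N pi) with a = theta = 1 recovers N within 5%."""
        grid = ib.make_grid(8, 8, 25.0, seed=31)
        cov = ib.make_covariates(grid, 2, seed=32)
        spec = ib.build_smooths(cov)
        sc = ib.SimScenario(T=2, true_N=600, seed=33)
        _, _, pi = latent_surfaces(grid, cov, sc)
        A = grid.saltwater_area
        counts, effort = [], []
        for t in range(2):
            for s in range(grid.n_cells):
                counts.append({"cell_id": s, "day": t, "platform": "us",
                               "kind": "thermal",
                               "count": int(round(600 * pi[s, t]))})
                effort.append({"cell_id": s, "day": t, "platform": "us",
                               "length_km": 0.0, "footprint_km2": A[s]})
        data = SurveyData(counts=pd.DataFrame(counts),
                          effort=pd.DataFrame(effort))
        fit = ib.laplace_fit(data, grid, cov, spec, g0=1.0,
                             fix={"logit_p_us": 20.0})
        assert abs(fit.N_hat - 600) / 600 < 0.05

    def test_water99_gate_in_fitted_surface(self, default_fit, cov):
        w99 = cov.water99.astype(bool)
        assert w99.any() and not w99.all()
        assert default_fit.pi_hat[w99].max() < 1e-15

    def test_fitted_occupancy_normalized(self, default_fit):
        np.testing.assert_allclose(default_fit.pi_hat.sum(axis=0), 1.0,
                                   atol=1e-12)

    def test_converged_with_finite_uncertainty(self, default_fit):
        assert default_fit.convergence["success"]
        assert np.isfinite(default_fit.se_N_star)
        assert not default_fit.convergence["hessian_singular"]

    def test_degenerate_data_rejected(self):
        grid, cov = _one_cell_setup()
        data = SurveyData(
            counts=pd.DataFrame([{"cell_id": 0, "day": 0, "platform": "us",
                                  "kind": "thermal", "count": 0}]),
            effort=pd.DataFrame([{"cell_id": 0, "day": 0, "platform": "us",
                                  "length_km": 0.0, "footprint_km2": 10.0}]))
        with pytest.raises(ValueError, match="degenerate"):
            ib.laplace_fit(data, grid, cov, None)


class TestIntervals:
    def test_log_based_ci_geometric_symmetry(self, default_fit):
        lo, hi = default_fit.ci_N_star
        assert lo * hi == pytest.approx(default_fit.N_star ** 2, rel=1e-6)
        lo, hi = default_fit.ci_N()
        assert lo * hi == pytest.approx(default_fit.N_hat ** 2, rel=1e-6)

    def test_unit_group_size_means_n_star_equals_n(self):
        grid, cov = _one_cell_setup()
        data = SurveyData(
            counts=pd.DataFrame([{"cell_id": 0, "day": 0, "platform": "us",
                                  "kind": "thermal", "count": 9}]),
            effort=pd.DataFrame([{"cell_id": 0, "day": 0, "platform": "us",
                                  "length_km": 0.0,
                                  "footprint_km2": 625.0}]),
            group_sizes=np.array([1, 1, 1, 1]))
        fit = ib.laplace_fit(data, grid, cov, None, g0=1.0,
                             fix={"logit_p_us": 20.0})
        assert fit.mu_g_hat == 1.0
        assert fit.N_star == fit.N_hat

    def test_interval_consistent_with_reported_table_row(self):
        """A point estimate of 3435 with SE 711 reproduces the published
        interval (2300, 5131) under the log-based construction."""
        lo, hi = lognormal_ci(3435.0, 711.0)
        assert lo == pytest.approx(2300, rel=1.5e-3)
        assert hi == pytest.approx(5131, rel=1.5e-3)

    def test_total_abundance_accessor(self, default_fit):
        n_star, se, ci = ib.total_abundance(default_fit)
        assert n_star == default_fit.N_star
        assert ci[0] < n_star < ci[1]
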