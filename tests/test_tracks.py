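"""Track-intensity submodel: design, closed forms, joint identifiability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import icebears as ib
from icebears.tracks import TrackData, TrackParams, track_nll


def _flat_cov(d, ice, rsf):
    """Single-cell covariate field with prescribed standardized values."""
    cov = ib.CovariateField(ice=np.array([[ice]]), dist_land=np.array([1.0]),
                            rsf=np.array([rsf]), easting=np.array([1.0]),
                            northing=np.array([1.0]))
    cov.dist_land = np.array([d])  # dist_land_std divides by the mean = d/d
    return cov


class TestDesign:
    def test_polynomial_expansion(self):
        # two cells with dist_land (0, 2): mean 1, so standardized d = (0, 2)
        cov = ib.CovariateField(
            ice=np.array([[0.0], [0.5]]), dist_land=np.array([0.0, 2.0]),
            rsf=np.array([0.0, 0.3]), easting=np.array([1.0, 2.0]),
            northing=np.array([1.0, 1.0]))
        np.testing.assert_allclose(
            ib.build_track_design(cov, cell=0, day=0), [1, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(
            ib.build_track_design(cov, cell=1, day=0),
            [1, 2, 4, 0.5, 0.25, 0.3])

    def test_full_design_shape(self, cov):
        X = ib.build_track_design(cov)
        assert X.shape == (cov.n_cells * cov.n_days, 6)

    def test_missing_covariate_errors_name_cell_day(self, cov):
        with pytest.raises(KeyError, match="cell"):
            ib.build_track_design(cov, cell=cov.n_cells + 3, day=0)


class TestIntensityAndPhotoProb:
    def test_zero_coefficients_give_unit_intensity(self):
        assert ib.track_intensity(np.ones(6), np.zeros(6)) == 1.0

    def test_log_two_gives_two(self):
        x = np.array([1.0, 0, 0, 0, 0, 0])
        b = np.array([np.log(2.0), 0, 0, 0, 0, 0])
        assert ib.track_intensity(x, b) == pytest.approx(2.0)

    def test_photo_prob_closed_form(self):
        assert ib.photo_track_prob(100.0, 0.012) == pytest.approx(
            1 - np.exp(-1.2), abs=1e-12)
        assert float(ib.photo_track_prob(100.0, 0.012)) == pytest.approx(
            0.69881, abs=5e-6)

    def test_photo_prob_limits(self):
        assert ib.photo_track_prob(0.0) == 0.0
        assert ib.photo_track_prob(1e12) == pytest.approx(1.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            ib.photo_track_prob(-1.0)

    @given(st.floats(0.01, 1e4), st.floats(1e-4, 1.0))
    def test_prob_invariant_under_intensity_area_tradeoff(self, Z, B):
        a = ib.photo_track_prob(Z, B)
        b = ib.photo_track_prob(2 * Z, B / 2)
        assert a == pytest.approx(b, rel=1e-9)

    @given(st.floats(0.01, 1e3))
    def test_prob_monotone_in_intensity(self, Z):
        assert ib.photo_track_prob(1.1 * Z) > ib.photo_track_prob(Z)


class TestTrackNll:
    def test_single_us_row_binomial_pmf(self):
        cov = _flat_cov(1.0, 0.5, 1.0)
        # intercept-only beta with B*Z = ln 2, so phi = 0.5
        Z = np.log(2) / 0.012
        params = TrackParams(beta=np.array([np.log(Z), 0, 0, 0, 0, 0]))
        data = TrackData(us=pd.DataFrame(
            [{"cell_id": 0, "day": 0, "photos": 2, "tracks": 1}]))
        assert track_nll(data, params, cov) == pytest.approx(
            -np.log(0.5), abs=1e-9)

    def test_single_ru_row_poisson_at_zero(self):
        cov = _flat_cov(1.0, 0.5, 1.0)
        params = TrackParams(beta=np.array([np.log(3.0), 0, 0, 0, 0, 0]),
                             eta=0.5)
        data = TrackData(ru=pd.DataFrame(
            [{"cell_id": 0, "day": 0, "length_km": 2.0, "tracks": 0}]))
        lam = 2.0 * 0.5 * 3.0
        assert track_nll(data, params, cov) == pytest.approx(lam, abs=1e-9)

    def test_pmfs_normalize_by_enumeration(self):
        """Summing exp(-nll) over all outcomes recovers 1 (both streams)."""
        cov = _flat_cov(1.0, 0.6, 1.2)
        params = TrackParams(beta=np.array([1.0, -0.2, 0.05, 0.5, -0.3, 0.1]),
                             eta=0.4)
        P = 6
        total_us = 0.0
        for y in range(P + 1):
            d = TrackData(us=pd.DataFrame(
                [{"cell_id": 0, "day": 0, "photos": P, "tracks": y}]))
            total_us += np.exp(-track_nll(d, params, cov))
        assert total_us == pytest.approx(1.0, abs=1e-10)
        total_ru = 0.0
        for y in range(51):
            d = TrackData(ru=pd.DataFrame(
                [{"cell_id": 0, "day": 0, "length_km": 1.0, "tracks": y}]))
            total_ru += np.exp(-track_nll(d, params, cov))
        assert total_ru == pytest.approx(1.0, abs=1e-8)

    def test_count_exceeding_photos_rejected(self):
        cov = _flat_cov(1.0, 0.5, 1.0)
        data = TrackData(us=pd.DataFrame(
            [{"cell_id": 0, "day": 0, "photos": 2, "tracks": 3}]))
        with pytest.raises(ValueError):
            track_nll(data, TrackParams(beta=np.zeros(6)), cov)


class TestIdentifiability:
    def test_eta_confounded_with_intercept_without_us_rows(self, cov):
        """RU data alone cannot separate eta from the intercept: the
        likelihood is flat along intercept + log eta = const."""
        rng = np.random.default_rng(0)
        s = rng.integers(0, cov.n_cells, 50)
        t = rng.integers(0, cov.n_days, 50)
        ru = pd.DataFrame({"cell_id": s, "day": t, "length_km": 10.0,
                           "tracks": rng.poisson(3.0, 50)})
        data = TrackData(ru=ru)
        beta = np.array([1.0, -0.3, 0.02, 0.5, -0.2, 0.1])
        base = track_nll(data, TrackParams(beta=beta, eta=0.5), cov)
        for delta in (0.5, -1.0):
            b2 = beta.copy(); b2[0] -= delta
            shifted = track_nll(
                data, TrackParams(beta=b2, eta=0.5 * np.exp(delta)), cov)
            assert shifted == pytest.approx(base, rel=1e-12)

    def test_us_rows_break_the_confounding(self, grid, cov):
        data = ib.simulate_survey(grid, cov, ib.SimScenario(seed=17))
        beta = np.array([2.0, -0.8, 0.1, 1.5, -0.75, 0.3])
        base = track_nll(data.track, TrackParams(beta=beta, eta=0.05), cov)
        b2 = beta.copy(); b2[0] -= 0.5
        shifted = track_nll(
            data.track, TrackParams(beta=b2, eta=0.05 * np.exp(0.5)), cov)
        assert abs(shifted - base) > 1.0


class TestRecovery:
    def test_mle_within_three_se_of_truth(self):
        """Across seeded replicates with S*T >= 2000 rows, the joint track
        MLE lands within 3 SE of the generating parameters >= 90% of the
        time."""
        grid = ib.make_grid(20, 10, 25.0, seed=21)
        cov = ib.make_covariates(grid, 10, seed=22)
        eff = ib.EffortConfig(ru_cells_per_day=200, us_cells_per_day=200)
        truth = ib.SimScenario(effort=eff, seed=0)
        beta_true = np.asarray(truth.true_beta)
        n_rep, n_ok = 50, 0
        for r in range(n_rep):
            sc = ib.SimScenario(effort=eff, seed=3000 + r)
            data = ib.simulate_survey(grid, cov, sc)
            assert len(data.track.us) + len(data.track.ru) >= 2000
            params, info = ib.fit_track(data.track, cov)
            z_beta = (params.beta - beta_true) / info["se_beta"]
            z_eta = (np.log(params.eta) - np.log(truth.true_eta)) \
                / info["se_log_eta"]
            if np.all(np.abs(z_beta) <= 3) and abs(z_eta) <= 3:
                n_ok += 1
        assert n_ok >= 0.9 * n_rep
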