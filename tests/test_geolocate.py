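"""Activity-state HMM, movement kernels, observation likelihoods, the
spatial HMM recursions against exhaustive oracles, and track validation."""

from __future__ import annotations

import math
from dataclasses import replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from basstrack.geo import haversine_km
from basstrack.geolocate import (
    HmmConfig,
    PosteriorTrack,
    WaterGrid,
    depth_likelihood,
    detection_likelihood,
    estimate_D,
    fit_activity_states,
    forward_backward,
    mean_and_modal_tracks,
    movement_kernel,
    temperature_likelihood,
    validate_track,
    viterbi,
)
from basstrack.preprocess import clean_series
from basstrack.synthetic import gen_detections, gen_tag_series, gen_trajectory
from basstrack.types import DailyObservation, GriddedField

from conftest import enumerate_posteriors, random_hmm_instance


def open_water_field(spacing=0.25, lat0=50.0, lat1=53.0, lon0=0.0, lon1=3.0,
                     depth=50.0, n_days=10):
    """All-water flat-bottomed field with constant temperature."""
    lats = np.arange(lat0 + spacing / 2, lat1, spacing)
    lons = np.arange(lon0 + spacing / 2, lon1, spacing)
    dates = pd.date_range("2015-06-01", periods=n_days, freq="D")
    shape = (n_days, len(lats), len(lons))
    return GriddedField(
        lats, lons, np.full((len(lats), len(lons)), depth), dates,
        np.full(shape, 12.0), np.full(shape, 12.0),
    )


def make_obs(day=date(2015, 6, 1), max_depth=10.0, med_depth=5.0,
             mean_temp=12.0, cooling=False):
    return DailyObservation(
        date=day, max_depth=max_depth, min_depth=0.0, med_depth=med_depth,
        mean_temp=mean_temp, temp_range=1.0, activity_index=100.0,
        cooling_water=cooling,
    )


# --------------------------------------------------------------------------
# activity states
# --------------------------------------------------------------------------

class TestActivityStates:
    def _daily_from_activity(self, acts):
        return [
            DailyObservation(
                date=date(2015, 6, 1) + timedelta(days=k),
                max_depth=20.0, min_depth=0.0, med_depth=10.0,
                mean_temp=12.0, temp_range=1.0, activity_index=float(a),
            )
            for k, a in enumerate(acts)
        ]

    def test_two_regimes_recovered(self):
        rng = np.random.default_rng(0)
        # sticky two-state chain with well-separated lognormal activity
        states = [0]
        for _ in range(199):
            states.append(states[-1] if rng.random() < 0.9 else 1 - states[-1])
        states = np.array(states)
        act = np.where(
            states == 1,
            np.exp(rng.normal(7.0, 0.3, 200)),
            np.exp(rng.normal(3.0, 0.3, 200)),
        )
        fit = fit_activity_states(self._daily_from_activity(act))
        assert fit.converged
        accuracy = (fit.states == states).mean()
        assert accuracy >= 0.95

    def test_high_state_has_larger_mean(self):
        rng = np.random.default_rng(1)
        act = np.concatenate(
            [np.exp(rng.normal(3, 0.3, 50)), np.exp(rng.normal(7, 0.3, 50))]
        )
        fit = fit_activity_states(self._daily_from_activity(act))
        assert fit.means[1] > fit.means[0]
        assert fit.states[:50].mean() < 0.5 < fit.states[50:].mean()

    def test_identical_regimes_not_converged(self):
        fit = fit_activity_states(self._daily_from_activity([100.0] * 60))
        assert not fit.converged

    def test_too_few_days_not_converged(self):
        fit = fit_activity_states(self._daily_from_activity([10, 2000] * 5))
        assert not fit.converged


# --------------------------------------------------------------------------
# movement kernel
# --------------------------------------------------------------------------

class TestMovementKernel:
    def test_rows_sum_to_one(self, small_field):
        grid = WaterGrid(small_field)
        for d_coef in (2.0, 10.0, 50.0):
            K = movement_kernel(d_coef, grid)
            np.testing.assert_allclose(
                np.asarray(K.sum(axis=1)).ravel(), 1.0, atol=1e-12
            )

    def test_isotropy_rook_neighbours_equal(self):
        # near-equator grid where a degree is the same length both ways
        lats = np.arange(-0.875, 1.0, 0.25)
        lons = np.arange(-0.875, 1.0, 0.25)
        n = len(lats)
        dates = pd.date_range("2015-06-01", periods=2, freq="D")
        f = GriddedField(
            lats, lons, np.full((n, n), 50.0), dates,
            np.full((2, n, n), 12.0), np.full((2, n, n), 12.0),
        )
        grid = WaterGrid(f)
        K = movement_kernel(60.0, grid).toarray()
        centre = grid.nearest_cell(0.125, 0.125)
        i0 = int(np.where(lats == 0.125)[0][0])
        j0 = int(np.where(lons == 0.125)[0][0])

        def cell(i, j):
            return int(np.where((grid.ii == i) & (grid.jj == j))[0][0])

        w = [K[centre, cell(i0 + di, j0 + dj)]
             for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        assert max(w) - min(w) <= 1e-4 * max(w)

    def test_one_step_variance_matches_diffusion(self):
        # fine open grid so discretisation error is small
        f = open_water_field(spacing=0.04, lat0=0.0, lat1=1.6, lon0=0.0, lon1=1.6)
        grid = WaterGrid(f)
        d_coef = 30.0
        K = movement_kernel(d_coef, grid).toarray()
        centre = grid.nearest_cell(0.8, 0.8)
        dy = (grid.cell_lats - grid.cell_lats[centre]) * 111.19
        var = float(K[centre] @ dy**2)
        # numeric-integration oracle: truncated-Gaussian variance
        s2 = 2.0 * d_coef
        from scipy.stats import truncnorm

        trunc = truncnorm.var(-4 * math.sqrt(2), 4 * math.sqrt(2)) * s2
        assert var == pytest.approx(trunc, rel=0.10)
        assert var == pytest.approx(2.0 * d_coef, rel=0.10)

    def test_tiny_support_degrades_to_identity(self, small_field):
        grid = WaterGrid(small_field)
        K = movement_kernel(0.5, grid)
        assert (K != sparse.identity(grid.n, format="csr")).nnz == 0


# --------------------------------------------------------------------------
# likelihoods
# --------------------------------------------------------------------------

class TestLikelihoods:
    def test_surface_day_unconstrains_depth(self, small_field):
        grid = WaterGrid(small_field)
        lik = depth_likelihood(make_obs(max_depth=0.0), grid)
        np.testing.assert_array_equal(lik, 1.0)

    def test_shallow_cell_strongly_penalised(self):
        f = open_water_field(depth=20.0)
        grid = WaterGrid(f)
        lik = depth_likelihood(make_obs(max_depth=50.0), grid, sigma_bathy=4.0)
        # every cell is 30 m too shallow: exp(-900/32)
        assert lik.max() < 1e-10

    def test_depth_likelihood_monotone_in_bathymetry(self, small_field):
        grid = WaterGrid(small_field)
        lik = depth_likelihood(make_obs(max_depth=40.0), grid)
        order = np.argsort(grid.bathy)
        assert (np.diff(lik[order]) >= -1e-12).all()

    def test_temperature_maximiser_at_matching_cell(self, small_field):
        grid = WaterGrid(small_field)
        k = 0
        c = grid.n // 2
        frac = np.clip(5.0 / grid.bathy[c], 0, 1)
        surf = small_field.temp_surface[k][grid.ii[c], grid.jj[c]]
        bot = small_field.temp_bottom[k][grid.ii[c], grid.jj[c]]
        ref = surf + (bot - surf) * frac
        obs = make_obs(day=small_field.dates[k].date(), mean_temp=float(ref))
        lik = temperature_likelihood(obs, grid)
        assert lik[c] == pytest.approx(lik.max())

    def test_cooling_water_day_uniform(self, small_field):
        grid = WaterGrid(small_field)
        lik = temperature_likelihood(
            make_obs(day=small_field.dates[0].date(), cooling=True), grid
        )
        np.testing.assert_array_equal(lik, 1.0)

    def test_likelihood_ratio_is_gaussian(self):
        f = open_water_field(depth=50.0)
        grid = WaterGrid(f)
        # hand construction: two cells with reference temps 12 and 12 +- g
        obs = make_obs(day=f.dates[0].date(), mean_temp=13.0, med_depth=0.0)
        lik = temperature_likelihood(obs, grid, sigma_temp=0.5)
        expected = math.exp(-1.0 / (2 * 0.25))
        np.testing.assert_allclose(lik, expected, rtol=1e-12)

    def test_date_outside_field_rejected(self, small_field):
        grid = WaterGrid(small_field)
        with pytest.raises(KeyError):
            temperature_likelihood(make_obs(day=date(1999, 1, 1)), grid)

    def test_detection_day_peaks_at_station(self, small_field):
        grid = WaterGrid(small_field)
        c = grid.n // 3
        stations = pd.DataFrame(
            {
                "station_id": ["s0"],
                "lat": [grid.cell_lats[c]],
                "lon": [grid.cell_lons[c]],
                "array": ["a"],
            }
        )
        det = pd.DataFrame(
            {
                "tag_id": ["t"],
                "timestamp": pd.DatetimeIndex(["2015-06-01T04:00"], tz="UTC"),
                "station_id": ["s0"],
            }
        )
        lik = detection_likelihood(date(2015, 6, 1), det, stations, grid)
        assert int(np.argmax(lik)) == c
        # matches the calibrated range curve wherever unfloored
        d = haversine_km(
            grid.cell_lats, grid.cell_lons, grid.cell_lats[c], grid.cell_lons[c]
        )
        expected = np.maximum(np.exp(-math.log(2) * (d / 0.566) ** 2), 1e-6)
        np.testing.assert_allclose(lik, expected, rtol=1e-9)

    def test_no_detections_uniform(self, small_field):
        grid = WaterGrid(small_field)
        det = pd.DataFrame(columns=["tag_id", "timestamp", "station_id"])
        lik = detection_likelihood(date(2015, 6, 1), det, pd.DataFrame(), grid)
        np.testing.assert_array_equal(lik, 1.0)

    def test_half_weight_at_detection_range(self):
        # at d = sigma_d the unfloored kernel value is exactly 0.5
        assert math.exp(-math.log(2) * 1.0**2) == pytest.approx(0.5)


# --------------------------------------------------------------------------
# recursions vs oracles
# --------------------------------------------------------------------------

class TestRecursions:
    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_smoothing_and_viterbi_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        lik, K, prior = random_hmm_instance(rng)
        post, _ = forward_backward(lik, K, prior)
        marg, best = enumerate_posteriors(lik, K, prior)
        np.testing.assert_allclose(post, marg, atol=1e-10)
        np.testing.assert_array_equal(viterbi(lik, K, prior), best)

    def test_uniform_inputs_uniform_posteriors(self):
        n, T = 6, 4
        lik = np.ones((T, n))
        K = sparse.csr_matrix(np.full((n, n), 1.0 / n))  # doubly stochastic
        prior = np.full(n, 1.0 / n)
        post, _ = forward_backward(lik, K, prior)
        np.testing.assert_allclose(post, 1.0 / n, atol=1e-12)

    def test_point_mass_likelihoods_pin_posterior(self):
        n, T = 5, 4
        cells = [1, 2, 2, 3]
        lik = np.zeros((T, n))
        for t, c in enumerate(cells):
            lik[t, c] = 1.0
        K = sparse.csr_matrix(np.full((n, n), 1.0 / n))
        prior = np.full(n, 1.0 / n)
        post, _ = forward_backward(lik, K, prior)
        assert [int(np.argmax(post[t])) for t in range(T)] == cells
        np.testing.assert_allclose(post.max(axis=1), 1.0)
        np.testing.assert_array_equal(viterbi(lik, K, prior), cells)

    def test_posteriors_normalised(self):
        rng = np.random.default_rng(3)
        lik, K, prior = random_hmm_instance(rng)
        post, _ = forward_backward(lik, K, prior)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_loglik_invariant_to_day_rescaling(self):
        from basstrack.geolocate import combine_likelihoods

        rng = np.random.default_rng(4)
        lik, K, prior = random_hmm_instance(rng)
        norm = np.array([combine_likelihoods(row) for row in lik])
        scaled = lik.copy()
        scaled[0] *= 37.5
        norm2 = np.array([combine_likelihoods(row) for row in scaled])
        _, ll1 = forward_backward(norm, K, prior)
        _, ll2 = forward_backward(norm2, K, prior)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_zero_mass_day_relaxed_with_warning(self):
        n, T = 4, 3
        lik = np.ones((T, n))
        lik[1] = 0.0
        K = sparse.csr_matrix(np.full((n, n), 1.0 / n))
        prior = np.full(n, 1.0 / n)
        warnings: list[str] = []
        post, _ = forward_backward(lik, K, prior, warnings)
        assert len(warnings) == 1
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_single_day_viterbi_is_argmax(self):
        lik = np.array([[0.1, 0.7, 0.2]])
        prior = np.array([0.2, 0.3, 0.5])
        K = sparse.identity(3, format="csr")
        assert viterbi(lik, K, prior) == [int(np.argmax(lik[0] * prior))]

    def test_viterbi_deterministic(self):
        rng = np.random.default_rng(5)
        lik, K, prior = random_hmm_instance(rng)
        p1 = viterbi(lik, K, prior)
        p2 = viterbi(lik, K, prior)
        np.testing.assert_array_equal(p1, p2)


class TestTrackSummaries:
    def test_point_mass_mean_equals_modal(self, small_field):
        grid = WaterGrid(small_field)
        post = np.zeros((3, grid.n))
        post[:, 7] = 1.0
        mean, modal = mean_and_modal_tracks(post, grid)
        np.testing.assert_allclose(mean, modal)

    def test_symmetric_bimodal(self, small_field):
        grid = WaterGrid(small_field)
        a, b = 3, 11
        post = np.zeros((1, grid.n))
        post[0, a] = post[0, b] = 0.5
        mean, modal = mean_and_modal_tracks(post, grid)
        assert mean[0, 0] == pytest.approx((grid.cell_lats[a] + grid.cell_lats[b]) / 2)
        assert modal[0, 0] == grid.cell_lats[a]  # lower index wins the tie

    def test_mean_track_inside_hull(self, small_field):
        grid = WaterGrid(small_field)
        rng = np.random.default_rng(6)
        post = rng.random((5, grid.n))
        post /= post.sum(axis=1, keepdims=True)
        mean, _ = mean_and_modal_tracks(post, grid)
        assert (mean[:, 0] >= grid.cell_lats.min()).all()
        assert (mean[:, 0] <= grid.cell_lats.max()).all()
        assert (mean[:, 1] >= grid.cell_lons.min()).all()
        assert (mean[:, 1] <= grid.cell_lons.max()).all()


# --------------------------------------------------------------------------
# fitting & validation
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted(small_config, small_field):
    cfg = replace(small_config, d_high=30.0,
                  behaviour_transitions=((0.0, 1.0), (0.0, 1.0)))
    tr = gen_trajectory(cfg, small_field, "fitme")
    s = gen_tag_series(tr, small_field, cfg)
    cs = clean_series(s, field=small_field)
    hmm = HmmConfig(switching=False, sigma_temp=0.2)
    return cs, tr, hmm, estimate_D(cs, small_field, config=hmm)


class TestEstimateD:
    def test_fit_is_local_optimum(self, fitted, small_field):
        from basstrack.geolocate import build_likelihoods, movement_kernel

        cs, _, hmm, track = fitted
        grid = track.grid
        lik, _ = build_likelihoods(cs, grid, hmm)
        prior = grid.point_mass(cs.series.release[1], cs.series.release[2])

        def ll(d_coef):
            _, v = forward_backward(lik, movement_kernel(d_coef, grid), prior)
            return v

        d_hat = track.d_fit[0]
        assert track.log_likelihood >= ll(max(d_hat * 0.5, 1.0)) - 1e-6
        assert track.log_likelihood >= ll(min(d_hat * 2.0, 100.0)) - 1e-6

    def test_switching_fit_ordered(self, small_config, small_field):
        tr = gen_trajectory(small_config, small_field, "switchy")
        s = gen_tag_series(tr, small_field, small_config)
        cs = clean_series(s, field=small_field)
        act = fit_activity_states(cs.usable_daily)
        track = estimate_D(
            cs, small_field, config=HmmConfig(sigma_temp=0.2), activity=act
        )
        assert track.d_fit[1] >= track.d_fit[0]

    def test_detections_never_hurt_on_detection_days(self, small_config, small_field):
        """Fusing the acoustic detection likelihood must not degrade the
        position estimate on days the fish was detected (on average)."""
        hmm = HmmConfig(switching=False, sigma_temp=0.2)
        errs_with, errs_without = [], []
        for k in range(4):
            tr = gen_trajectory(small_config, small_field, f"det{k}",
                                rng=small_config.rng(20, k))
            # receivers moored on the fish's path, as arrays are in practice
            stations = pd.DataFrame(
                {
                    "station_id": [f"s{d}" for d in (10, 30, 50)],
                    "lat": [tr.lats[d] for d in (10, 30, 50)],
                    "lon": [tr.lons[d] for d in (10, 30, 50)],
                    "array": ["a"] * 3,
                }
            )
            det = gen_detections(tr, stations, small_config,
                                 rng=small_config.rng(21, k))
            if det.n_detections == 0:
                continue
            s = gen_tag_series(tr, small_field, small_config,
                               rng=small_config.rng(22, k))
            cs = clean_series(s, field=small_field)
            with_det = estimate_D(cs, small_field, detections=det, config=hmm)
            without = estimate_D(cs, small_field, config=hmm)
            det_days = {
                ts.date() for ts in pd.to_datetime(det.detections["timestamp"])
            }
            for t, day in enumerate(with_det.dates):
                if day in det_days:
                    truth = (tr.lats[t], tr.lons[t])
                    errs_with.append(
                        haversine_km(*with_det.viterbi_track[t], *truth)
                    )
                    errs_without.append(
                        haversine_km(*without.viterbi_track[t], *truth)
                    )
        assert errs_with, "no detection days simulated"
        assert np.mean(errs_with) <= np.mean(errs_without) + 1e-9


class TestValidateTrack:
    def _track(self, errors):
        errors = np.asarray(errors, dtype=float)
        n = len(errors)
        dummy = np.zeros((n, 2))
        return PosteriorTrack(
            tag_id="t", dates=[date(2015, 6, 1)] * n, grid=None,
            posteriors=np.zeros((n, 1)), viterbi_track=dummy,
            mean_track=dummy, modal_track=dummy, log_likelihood=0.0,
            d_fit=(10.0, 10.0), switching=False,
            viterbi_vs_mean_km=errors, viterbi_vs_mode_km=errors,
        )

    def test_published_error_profile_is_reliable(self):
        # median 4.61 km, maximum 116.0 km
        errors = np.full(99, 4.61)
        errors[-1] = 116.0
        assert validate_track(self._track(errors)) == "reliable"

    def test_high_median_is_temporal_only(self):
        assert validate_track(self._track([60.0, 60.0, 100.0])) == "temporal_only"

    def test_max_in_band_is_temporal_only(self):
        errors = np.full(99, 4.61)
        errors[-1] = 130.0
        assert validate_track(self._track(errors)) == "temporal_only"

    def test_extreme_max_is_unreliable(self):
        assert validate_track(self._track([10.0, 20.0, 300.0])) == "unreliable"
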