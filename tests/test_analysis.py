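import math

import numpy as np
import pandas as pd
import pytest

from lymphsim import analysis, io
from lymphsim.analysis import (angle_autocorr, chi_sweep_stats,
                               confinement_ratio, detect_interactions_kinematic,
                               duration_histogram, fit_diffusion_coefficient,
                               fit_duration_distribution, fraction_below, msd,
                               rebin_tracks, speed_3d, trajectory_length,
                               velocity_autocorr)


def _track(xyz, dt=1.0, tid=0):
    xyz = np.asarray(xyz, float)
    return pd.DataFrame({
        "track_id": tid, "step": np.arange(len(xyz)),
        "t_s": np.arange(len(xyz)) * dt,
        "x_um": xyz[:, 0], "y_um": xyz[:, 1], "z_um": xyz[:, 2]})


class TestMsd:
    def test_stationary_track_zero(self):
        tracks = _track(np.zeros((50, 3)))
        curve = msd(tracks, 10)
        np.testing.assert_allclose(curve["msd_um2"], 0.0, atol=1e-20)

    def test_ballistic_track_quadratic(self):
        v = 0.5
        xyz = np.stack([v * np.arange(100), np.zeros(100), np.zeros(100)], axis=1)
        curve = msd(_track(xyz), 20)
        np.testing.assert_allclose(curve["msd_um2"],
                                   (v * curve["dt_s"]) ** 2, rtol=1e-10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            msd(pd.DataFrame(columns=["track_id", "t_s", "x_um", "y_um", "z_um"]),
                10)

    def test_free_diffusion_recovery(self):
        tracks = io.free_diffusion_tracks(d0=1.0, n_cells=100, n_steps=5000, seed=9)
        d = fit_diffusion_coefficient(msd(tracks, 100))
        assert abs(d - 1.0) < 0.01


class TestAutocorrelations:
    def test_ballistic_track_fully_correlated(self):
        xyz = np.stack([np.arange(50.0), np.zeros(50), np.zeros(50)], axis=1)
        v = velocity_autocorr(_track(xyz), 10)
        np.testing.assert_allclose(v["vacf"], 1.0, rtol=1e-12)
        a = angle_autocorr(_track(xyz), 10)
        np.testing.assert_allclose(a["cos_theta"], 1.0, rtol=1e-12)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        xyz = np.cumsum(rng.standard_normal((4000, 3)), axis=0)
        v = velocity_autocorr(_track(xyz), 5)
        assert abs(v["vacf"].iloc[1]) < 0.05
        assert v["vacf"].iloc[0] == pytest.approx(1.0)

    def test_wlc_lag1_matches_closed_form(self):
        # <cos theta> at lag 1 vs exp(-sigma^2/2), brute-force generated
        sigma = 0.3
        tracks = io.wlc_tracks(d0=1.0, sigma_theta=sigma, n_cells=60,
                               n_steps=800, seed=4)
        a = angle_autocorr(tracks, 3)
        assert a["cos_theta"].iloc[1] == pytest.approx(math.exp(-sigma**2 / 2),
                                                       abs=0.01)

    def test_wlc_geometric_decay(self):
        sigma = 0.5
        tracks = io.wlc_tracks(d0=1.0, sigma_theta=sigma, n_cells=60,
                               n_steps=800, seed=5)
        a = angle_autocorr(tracks, 4)
        c1 = math.exp(-sigma**2 / 2)
        for lag in (2, 3, 4):
            assert a["cos_theta"].iloc[lag] == pytest.approx(c1**lag, abs=0.03)


def _events(durations, censored=None):
    d = np.asarray(durations, float)
    c = np.zeros(len(d), bool) if censored is None else np.asarray(censored)
    return pd.DataFrame({
        "nk_id": np.arange(len(d)), "dc_id": 0, "t_start_s": 0.0,
        "t_end_s": d, "duration_s": d, "censored": c})


class TestDurations:
    def test_single_event_lands_in_right_bin(self):
        hist = duration_histogram(_events([100.0]), 40.0)
        assert hist.loc[hist["count"] == 1, "t_lo_s"].iloc[0] == 80.0
        assert hist["count"].sum() == 1

    def test_fraction_exact_from_events_not_bins(self):
        assert fraction_below(_events([100.0, 400.0]), 300.0) == 0.5

    def test_censored_excluded_by_default(self):
        ev = _events([100.0, 4000.0], censored=[False, True])
        assert fraction_below(ev, 300.0) == 1.0
        assert fraction_below(ev, 300.0, include_censored=True) == 0.5

    def test_round_trip_through_csv(self, tmp_path):
        ev = _events([10.0, 250.0, 700.0])
        path = tmp_path / "events.csv"
        io.write_events(ev, path)
        back = io.read_events(path)
        assert fraction_below(back, 300.0) == fraction_below(ev, 300.0)
        pd.testing.assert_frame_equal(back, ev)


class TestDurationFit:
    TRUTH = (800.0, 70.0, 78.0, 450.0, 250.0)

    def test_parameter_recovery(self):
        ev = io.synthetic_duration_events(*self.TRUTH, bin_width=40.0, seed=21)
        fit = fit_duration_distribution(duration_histogram(ev, 40.0))
        errs = (fit.A_err, fit.t1_err, fit.B_err, fit.t0_err, fit.sigma_err)
        for value, truth, err in zip(fit.as_tuple(), self.TRUTH, errs):
            assert abs(value - truth) <= 3.0 * max(err, 1e-6) + 0.05 * truth

    def test_pure_exponential_gives_negligible_gaussian(self):
        ev = io.synthetic_duration_events(800.0, 70.0, 0.0, 450.0, 250.0, seed=8)
        fit = fit_duration_distribution(duration_histogram(ev, 40.0))
        # Gaussian amplitude consistent with zero against the exponential
        assert fit.B <= max(3.0 * fit.B_err, 0.02 * fit.A)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_duration_distribution(duration_histogram(_events([50.0] * 5), 40.0))


class TestChiSweep:
    def test_counts_long_interactors(self):
        ev = _events([100.0, 700.0, 800.0])  # three distinct cells
        runs = {0.0: (_events([]), 10), 0.5: (ev, 10), 1.0: (ev, 10)}
        res = chi_sweep_stats(runs, t_th=600.0)
        row = res.table[res.table["chi"] == 0.5].iloc[0]
        assert row["pct_all"] == pytest.approx(30.0)
        assert row["pct_long"] == pytest.approx(20.0)

    def test_eventless_is_zero(self):
        runs = {c: (_events([]), 10) for c in (0.0, 0.5, 1.0)}
        res = chi_sweep_stats(runs)
        assert (res.table["pct_all"] == 0.0).all()

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            chi_sweep_stats({0.0: (_events([]), 10)})


class TestGeometry:
    def test_straight_line_cr_one(self):
        xyz = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        assert confinement_ratio(_track(xyz)) == pytest.approx(1.0)

    def test_closed_loop_cr_zero(self):
        th = np.linspace(0, 2 * np.pi, 33)
        xyz = np.stack([np.cos(th), np.sin(th), np.zeros(33)], axis=1)
        assert confinement_ratio(_track(xyz)) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_cr(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        assert confinement_ratio(_track(xyz)) == pytest.approx(math.sqrt(2) / 2)

    def test_single_point_undefined(self):
        t = _track(np.zeros((1, 3)))
        assert math.isnan(confinement_ratio(t))
        assert math.isnan(trajectory_length(t))
        assert len(speed_3d(t)) == 0

    def test_speed_and_length(self):
        xyz = np.array([[0.0, 0, 0], [3.0, 4.0, 0], [3.0, 4.0, 12.0]])
        t = _track(xyz, dt=2.0)
        np.testing.assert_allclose(speed_3d(t), [2.5, 6.0])
        assert trajectory_length(t) == pytest.approx(17.0)

    def test_invariance_under_rigid_motion(self):
        rng = np.random.default_rng(6)
        xyz = np.cumsum(rng.standard_normal((40, 3)), axis=0)
        t1 = _track(xyz)
        # random rotation (QR) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t2 = _track(xyz @ q.T + np.array([10.0, -5.0, 3.0]))
        assert confinement_ratio(t2) == pytest.approx(confinement_ratio(t1))
        assert trajectory_length(t2) == pytest.approx(trajectory_length(t1))
        np.testing.assert_allclose(speed_3d(t2), speed_3d(t1))
        np.testing.assert_allclose(msd(t2, 10)["msd_um2"], msd(t1, 10)["msd_um2"])


class TestRebin:
    def test_stride_one_identity(self):
        t = _track(np.random.default_rng(0).standard_normal((30, 3)))
        pd.testing.assert_frame_equal(rebin_tracks(t, 1), t)

    def test_stride_keeps_every_nth(self):
        t = _track(np.zeros((100, 3)))
        out = rebin_tracks(t, 25)
        assert len(out) == 4
        assert out["step"].tolist() == [0, 25, 50, 75]

    def test_cr_invariant_for_straight_track(self):
        xyz = np.stack([np.arange(100.0), np.zeros(100), np.zeros(100)], axis=1)
        t = _track(xyz)
        assert confinement_ratio(rebin_tracks(t, 25)) == pytest.approx(
            confinement_ratio(t))

    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            rebin_tracks(_track(np.zeros((10, 3))), 0)


class TestKinematicDetector:
    def test_fast_far_track_no_events(self):
        T = 60
        xyz = np.stack([2.0 * np.arange(T), np.full(T, 40.0), np.zeros(T)], axis=1)
        out = detect_interactions_kinematic(_track(xyz), np.zeros((1, 3)),
                                            speed_threshold=1.0)
        assert len(out) == 0

    def test_planted_window_detected(self):
        tracks, dcs, (t_lo, t_hi) = io.planted_interaction_tracks()
        out = detect_interactions_kinematic(tracks, dcs)
        assert len(out) >= 1
        hits = out[out["nk_id"] == 1]
        assert len(hits) >= 1
        assert hits["t_start_s"].min() >= t_lo - 10.0
        assert hits["t_end_s"].max() <= t_hi + 1e-9
        # the fast faraway track yields nothing
        assert (out["nk_id"] != 0).all()

    def test_threshold_separates_slow_near_from_fast_far(self):
        tracks, dcs, _ = io.planted_interaction_tracks()
        out = detect_interactions_kinematic(tracks, dcs)
        assert set(out["nk_id"]) == {1}
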