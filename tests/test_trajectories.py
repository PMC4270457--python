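"""MSD pooling, subdiffusion fitting, segregation detection, resampling."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from parspace.synthetic import SynthTrackSpec, generate_fbm_tracks
from parspace.trajectories import (
    MSDCurve,
    TrajectorySet,
    compute_msd,
    detect_segregation_events,
    fit_subdiffusion,
    free_diffusion_bound,
    max_msd_resampling_test,
)

COLS = ["cell", "focus", "t_s", "x_um", "y_um"]


def make_tracks(rows, dt=1.0):
    return TrajectorySet(pd.DataFrame(rows, columns=COLS), frame_interval=dt)


def brownian_tracks(n, n_frames, D, dt, seed, sigma=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for tr in range(n):
        steps = rng.normal(0, np.sqrt(2 * D * dt), (n_frames - 1, 2))
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        xy = xy + rng.normal(0, sigma, xy.shape)
        for k in range(n_frames):
            rows.append(("c", tr, k * dt, xy[k, 0], xy[k, 1]))
    return make_tracks(rows, dt)


class TestComputeMSD:
    def test_ballistic_track_is_exact(self):
        v, dt = 0.3, 2.0
        rows = [("c", 0, k * dt, v * k * dt, 0.0) for k in range(10)]
        msd = compute_msd(make_tracks(rows, dt))
        np.testing.assert_allclose(msd.msd, (v * msd.lags) ** 2, rtol=1e-12)

    def test_brownian_slope_recovers_4D(self):
        D, dt = 0.01, 1.0
        msd = compute_msd(brownian_tracks(300, 12, D, dt, seed=0))
        short = msd.lags <= 4
        slope, _ = np.polyfit(msd.lags[short], msd.msd[short], 1)
        se = np.max(msd.sem[short] / msd.lags[short])
        assert abs(slope - 4 * D) < 3 * se

    def test_gap_spanning_pairs_survive(self):
        rows = [("c", 0, t, float(t), 0.0) for t in (0, 1, 3, 4)]  # frame 2 lost
        msd = compute_msd(make_tracks(rows, 1.0))
        assert 2.0 in msd.lags  # the (1, 3) pair spans the gap
        k = np.where(msd.lags == 2.0)[0][0]
        assert msd.n[k] == 1

    def test_permutation_invariance(self):
        a = brownian_tracks(20, 8, 0.01, 1.0, seed=3)
        shuffled = a.records.sample(frac=1.0, random_state=1).sort_values("t_s")
        b = TrajectorySet(shuffled, frame_interval=1.0)
        ma, mb = compute_msd(a), compute_msd(b)
        np.testing.assert_allclose(ma.msd, mb.msd)
        np.testing.assert_allclose(ma.sem, mb.sem)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            compute_msd(make_tracks([("c", 0, 0.0, 0.0, 0.0)]))


class TestFitSubdiffusion:
    def test_pure_brownian_gives_alpha_one_beta_zero(self):
        msd = compute_msd(brownian_tracks(400, 15, 0.01, 1.0, seed=1))
        fit = fit_subdiffusion(msd)
        lo, hi = fit.alpha_ci(3.0)
        assert lo <= 1.0 <= hi
        assert abs(fit.beta) <= max(3 * fit.beta_se, 1e-3)

    def test_localization_noise_raises_beta_by_4_sigma_sq(self):
        sigma = 0.05
        clean = compute_msd(brownian_tracks(400, 15, 0.01, 1.0, seed=2))
        noisy = compute_msd(brownian_tracks(400, 15, 0.01, 1.0, seed=2,
                                            sigma=sigma))
        f0, f1 = fit_subdiffusion(clean), fit_subdiffusion(noisy)
        delta = f1.beta - f0.beta
        expect = 4 * sigma ** 2
        assert abs(delta - expect) < 3 * np.hypot(f0.beta_se, f1.beta_se) + 0.3 * expect

    def test_combined_dataset_parameters_recovered(self):
        # fBm ensemble generated at the reference fit values and the
        # reference study structure (short 4-s and long 30-s time lapses):
        # the weighted fit must recover alpha = 0.73 within the bootstrap
        # confidence interval (pooled-MSD points are correlated, so the
        # trajectory bootstrap carries the honest uncertainty)
        from parspace.synthetic import generate_mobility_dataset
        from parspace.trajectories import bootstrap_subdiffusion
        tracks = generate_mobility_dataset(seed=0)
        fit, (lo, hi), _ = bootstrap_subdiffusion(tracks, n_boot=60, seed=1)
        assert lo <= 0.73 <= hi
        assert abs(fit.alpha - 0.73) < 0.08

    @pytest.mark.parametrize("alpha", [0.5, 0.73, 1.0])
    def test_alpha_estimator_unbiased(self, alpha):
        ests = []
        for seed in range(5):
            spec = SynthTrackSpec(n_tracks=500, duration=60.0,
                                  frame_interval=4.0, alpha=alpha, D=9.7e-4,
                                  sigma=0.0, pixel=0.0, seed=seed)
            tracks, _ = generate_fbm_tracks(spec)
            ests.append(fit_subdiffusion(compute_msd(tracks)).alpha)
        assert abs(np.mean(ests) - alpha) < 0.03

    def test_too_few_lags_rejected(self):
        msd = MSDCurve(lags=np.array([1.0, 2.0, 3.0]),
                       msd=np.array([1.0, 2.0, 3.0]),
                       sem=np.array([0.1, 0.1, 0.1]), n=np.array([5, 5, 5]))
        with pytest.raises(ValueError):
            fit_subdiffusion(msd)


def test_free_diffusion_upper_bound_on_fitted_subdiffusion():
    # the reference-fit subdiffusive MSD lies below free diffusion with
    # D_f = 10e-4 µm²/s at every lag >= 4 s (analytic curves)
    tau = np.arange(4.0, 900.0, 2.0)
    sub = 4 * 9.7e-4 * tau ** 0.73 + 1.6e-3
    assert np.all(sub < free_diffusion_bound(tau, D_f=10e-4))


class TestSegregationEvents:
    @staticmethod
    def pair(seps, dt=4.0):
        rows = []
        for k, s in enumerate(seps):
            rows.append(("c", 0, k * dt, 0.0, 0.0))
            rows.append(("c", 1, k * dt, s, 0.0))
        return make_tracks(rows, dt)

    def test_close_pair_moving_apart_is_event(self):
        tracks = self.pair([0.2, 0.5, 0.9, 1.1])  # +0.9 within 12 s
        ev = detect_segregation_events(tracks)
        assert len(ev) == 1
        assert ev.iloc[0]["init_separation"] == pytest.approx(0.2)
        assert ev.iloc[0]["max_extra_separation"] == pytest.approx(0.9)

    def test_initially_distant_pair_is_not_event(self):
        tracks = self.pair([0.5, 1.2, 2.0, 2.5])
        assert len(detect_segregation_events(tracks)) == 0

    def test_slow_separation_needs_relaxed_window(self):
        # +0.8 µm reached only at t = 44 s: no event in 20 s, one in 60 s
        seps = [0.1] + [0.1 + 0.08 * k for k in range(1, 12)]
        tracks = self.pair(seps, dt=4.0)
        assert len(detect_segregation_events(tracks, window=20.0)) == 0
        assert len(detect_segregation_events(tracks, window=60.0)) == 1

    def test_merged_then_split_counts_from_zero(self):
        rows = [("c", 0, t, 0.0, 0.0) for t in (0.0, 4.0, 8.0, 12.0)]
        rows += [("c", 1, t, x, 0.0) for t, x in ((8.0, 0.0), (12.0, 0.9))]
        ev = detect_segregation_events(make_tracks(rows, 4.0))
        assert len(ev) == 1
        assert ev.iloc[0]["init_separation"] == pytest.approx(0.0)


class TestMaxMSDResampling:
    @staticmethod
    def dataset(seed=0, n=40):
        return brownian_tracks(n, 10, 0.01, 1.0, seed=seed)

    def test_top_k_event_set_is_maximally_significant(self):
        full = self.dataset()
        from parspace.trajectories import _max_msd_per_track
        ranked = sorted(_max_msd_per_track(full).items(),
                        key=lambda kv: -kv[1])
        top = full.subset([k for k, _ in ranked[:5]])
        p, obs, null = max_msd_resampling_test(top, full, n_resample=999,
                                               seed=1)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_whole_dataset_gives_p_one(self):
        full = self.dataset()
        p, _, _ = max_msd_resampling_test(full, full, n_resample=200, seed=2)
        assert p == 1.0

    def test_null_calibration_uniform_p(self):
        full = self.dataset(seed=7, n=60)
        from parspace.trajectories import _max_msd_per_track
        keys = list(_max_msd_per_track(full).keys())
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(200):
            pick = [keys[i] for i in rng.choice(len(keys), 8, replace=False)]
            p, _, _ = max_msd_resampling_test(full.subset(pick), full,
                                              n_resample=199, seed=rep)
            ps.append(p)
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.005

    def test_oversized_event_set_rejected(self):
        full = self.dataset(n=5)
        big = self.dataset(seed=1, n=8)
        with pytest.raises(ValueError):
            max_msd_resampling_test(big, full)
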