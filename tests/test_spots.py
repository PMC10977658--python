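"""Spot detection, calibration, counting, tracking and trace analytics."""

import warnings

import numpy as np
import pytest

from otsforce import (IntensityCalibration, Spot, SpotTrack,
                      align_traces_to_peak, count_molecules, delta_stack,
                      detect_movie, detect_spots, estimate_unit_intensity,
                      fit_lifetime, link_tracks, make_scenario, region_total,
                      render_movie, simulate_activation_events)
from otsforce.spots import MovieStack
from otsforce.synthetic import GroundTruth, _pixel_gaussian

import pandas as pd


def _frame_with_spots(positions, intensity=1000.0, bg=100.0, size=64,
                      sigma=1.2, seed=None):
    img = np.full((size, size), bg)
    for x, y in positions:
        img += intensity * _pixel_gaussian(x, y, sigma, 0, size, 0, size)
    if seed is not None:
        img = np.random.default_rng(seed).poisson(img).astype(float)
    return img


class TestDetectSpots:
    def test_blank_frame_gives_no_spots(self):
        assert detect_spots(np.zeros((32, 32)), psf_sigma=1.2) == []

    def test_noise_only_frame_gives_no_spots(self):
        img = np.random.default_rng(0).poisson(100.0, (64, 64)).astype(float)
        assert detect_spots(img, psf_sigma=1.2, min_snr=5) == []

    def test_single_spot_position_and_intensity(self):
        # average the intensity estimate over independent noise draws
        ints, xs, ys = [], [], []
        for seed in range(20):
            img = _frame_with_spots([(30.3, 24.7)], seed=seed)
            spots = detect_spots(img, psf_sigma=1.2, min_snr=5)
            assert len(spots) == 1
            ints.append(spots[0].integrated_intensity)
            xs.append(spots[0].x)
            ys.append(spots[0].y)
        assert abs(np.mean(xs) - 30.3) < 0.5
        assert abs(np.mean(ys) - 24.7) < 0.5
        assert abs(np.mean(ints) - 1000.0) / 1000.0 < 0.05

    def test_two_spots_ten_pixels_apart_resolved(self):
        img = _frame_with_spots([(20.0, 20.0), (30.0, 20.0)], seed=1)
        assert len(detect_spots(img, psf_sigma=1.2, min_snr=5)) == 2

    def test_recall_and_false_discovery_on_rendered_movie(self):
        cfg = make_scenario("u2os_basal", {"n_events": 40})
        truth = simulate_activation_events(cfg, seed=11)
        movie = render_movie(truth, cfg, seed=12)
        spots = detect_spots(movie.pixels[-1, 0], cfg.psf_sigma, min_snr=5)
        found = np.array([[s.x, s.y] for s in spots])
        tp = 0
        for _, ev in truth.events.iterrows():
            d = np.hypot(found[:, 0] - ev.x_px, found[:, 1] - ev.y_px)
            if d.min() < 1.0:
                tp += 1
        recall = tp / len(truth.events)
        fdr = (len(found) - tp) / max(len(found), 1)
        assert recall >= 0.90
        assert fdr <= 0.05

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((16, 16)), psf_sigma=0.0)


class TestUnitIntensity:
    def _spots(self, values):
        return [Spot(frame=0, channel="dp30", x=5, y=5,
                     integrated_intensity=v, background=100.0)
                for v in values]

    def test_identical_spots_give_exact_unit(self):
        cal = estimate_unit_intensity(self._spots([1000.0] * 30))
        assert cal.unit_intensity == 1000.0

    def test_mixture_mode_robust_to_doubles(self):
        rng = np.random.default_rng(2)
        singles = rng.normal(1000, 100, 400)
        doubles = rng.normal(2000, 140, 100)
        cal = estimate_unit_intensity(self._spots(np.r_[singles, doubles]))
        assert abs(cal.unit_intensity - 1000.0) / 1000.0 < 0.10

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError):
            estimate_unit_intensity(self._spots([1000.0] * 5))


class TestCountMolecules:
    cal = IntensityCalibration(channel="dp30", unit_intensity=1000.0,
                               uncertainty=100.0, n_spots=100)

    def test_zero_and_multiples(self):
        assert count_molecules(0.0, self.cal) == 0
        assert count_molecules(5000.0, self.cal) == 5

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert count_molecules(-50.0, self.cal) == 0

    def test_exactly_linear_for_integer_multiples(self):
        for k in range(1, 51):
            assert count_molecules(k * 1000.0, self.cal) == k


def _movie_from_frames(frames, interval=1.0):
    arr = np.stack(frames)[:, None]
    return MovieStack(pixels=arr, pixel_size=100.0, frame_interval=interval,
                      channel_names=["dp30"])


class TestDeltaStack:
    def test_static_movie_gives_zero_increments(self):
        movie = _movie_from_frames([np.full((16, 16), 5.0)] * 4)
        inc = delta_stack(movie, 0)
        assert np.all(inc.pixels == 0)

    def test_single_activation_appears_once(self):
        base = np.zeros((32, 32))
        lit = _frame_with_spots([(16.0, 16.0)], bg=0.0, size=32)
        movie = _movie_from_frames([base, base, lit, lit])
        inc = delta_stack(movie, 0)
        sums = inc.pixels[:, 0].sum(axis=(1, 2))
        assert sums[1] == pytest.approx(1000.0, rel=1e-3)
        assert sums[0] == 0 and sums[2] == pytest.approx(0, abs=1e-9)

    def test_median_radius_zero_is_identity_on_differences(self):
        rng = np.random.default_rng(3)
        frames = [rng.poisson(100, (16, 16)).astype(float) for _ in range(3)]
        movie = _movie_from_frames(frames)
        inc = delta_stack(movie, 0, median_radius=0, clamp_negative=False)
        assert np.array_equal(inc.pixels[:, 0], np.diff(np.stack(frames),
                                                        axis=0))

    def test_unclamped_increments_conserve_signal(self):
        rng = np.random.default_rng(4)
        frames = [rng.poisson(100, (16, 16)).astype(float) for _ in range(6)]
        movie = _movie_from_frames(frames)
        inc = delta_stack(movie, 0, clamp_negative=False)
        total = inc.pixels[:, 0].sum(axis=0)
        assert np.allclose(total, frames[-1] - frames[0])

    def test_single_frame_rejected(self):
        movie = _movie_from_frames([np.zeros((8, 8))])
        with pytest.raises(ValueError):
            delta_stack(movie, 0)


class TestRegionTotal:
    def test_zero_frame_gives_zero(self):
        movie = _movie_from_frames([np.zeros((16, 16))])
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        assert region_total(movie, mask, 0) == 0.0

    def test_one_pixel_mask_returns_bg_subtracted_value(self):
        img = np.full((16, 16), 10.0)
        img[5, 5] = 250.0
        movie = _movie_from_frames([img])
        mask = np.zeros((16, 16), bool)
        mask[5, 5] = True
        assert region_total(movie, mask, 0) == pytest.approx(240.0)

    def test_quench_erases_signal(self):
        # quencher-strand refresh modeled as an intensity reset
        pre = _frame_with_spots([(8.0, 8.0), (20.0, 20.0)], bg=10.0, size=32)
        post = np.full((32, 32), 10.0)
        movie = _movie_from_frames([pre, post])
        mask = np.zeros((32, 32), bool)
        mask[2:26, 2:26] = True
        before = region_total(movie, mask, 0)
        after = region_total(movie, mask, 1)
        assert after < 0.1 * before

    def test_empty_mask_warns(self):
        movie = _movie_from_frames([np.zeros((8, 8))])
        with pytest.warns(UserWarning):
            assert region_total(movie, np.zeros((8, 8), bool), 0) == 0.0


def _stationary_spot(frame, x=10.0, y=10.0):
    return Spot(frame=frame, channel="a", x=x, y=y,
                integrated_intensity=1000.0, background=100.0)


class TestLinkTracks:
    def test_single_stationary_spot_single_track(self):
        per_frame = [[_stationary_spot(f)] for f in range(5)] + [[], []]
        tracks = link_tracks(per_frame, max_disp=2.0, frame_interval=2.0)
        assert len(tracks) == 1
        assert tracks[0].duration == pytest.approx(5 * 2.0)
        assert not tracks[0].open

    def test_track_alive_at_movie_end_is_open(self):
        per_frame = [[], [], [_stationary_spot(2)]]
        tracks = link_tracks(per_frame, max_disp=2.0, frame_interval=1.0)
        assert len(tracks) == 1 and tracks[0].open

    def test_distant_spots_stay_separate(self):
        per_frame = [[_stationary_spot(f, 5.0, 5.0),
                      _stationary_spot(f, 25.0, 25.0)] for f in range(4)]
        tracks = link_tracks(per_frame, max_disp=3.0, frame_interval=1.0)
        assert len(tracks) == 2

    def test_gap_closing_bridges_missed_frame(self):
        per_frame = [[_stationary_spot(0)], [], [_stationary_spot(2)], []]
        tracks = link_tracks(per_frame, max_disp=2.0, max_gap=1,
                             frame_interval=1.0)
        assert len(tracks) == 1
        tracks = link_tracks(per_frame, max_disp=2.0, max_gap=0,
                             frame_interval=1.0)
        assert len(tracks) == 2


class TestFitLifetime:
    def _tracks(self, durations, open_flags=None):
        open_flags = open_flags or [False] * len(durations)
        return [SpotTrack(track_id=i, spots=[], t_on=0.0, t_off=d, open=o)
                for i, (d, o) in enumerate(zip(durations, open_flags))]

    def test_exact_durations_mle_is_sample_mean(self):
        fit = fit_lifetime(self._tracks([2.0, 4.0, 6.0] * 4),
                           frame_interval=0.0, n_boot=50, rng=0)
        assert fit.decay_time == pytest.approx(4.0, abs=1e-12)

    def test_censored_closed_form_identity(self):
        durations = [2.0, 4.0, 6.0, 8.0] * 3 + [10.0] * 4
        flags = [False] * 12 + [True] * 4
        fit = fit_lifetime(self._tracks(durations, flags),
                           frame_interval=0.0, n_boot=50, rng=0)
        assert fit.decay_time == pytest.approx(sum(durations) / 12, abs=1e-12)

    def test_recovers_lifetime_from_coarse_stride(self):
        from otsforce.pipeline import lifetime_recovery
        fit = lifetime_recovery(9.0, 10.0, 300, seed=1, n_boot=200)
        assert abs(fit.decay_time - 9.0) <= 1.5

    def test_all_open_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime(self._tracks([5.0] * 12, [True] * 12),
                         frame_interval=0.0)

    def test_too_few_closed_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime(self._tracks([5.0] * 5), frame_interval=0.0)


class TestAlignTraces:
    def test_self_reference_peak_at_lag_zero(self):
        trace = np.array([[0.0, 1.0, 3.0, 1.0, 0.0]])
        out = align_traces_to_peak(trace, trace)
        assert out.mean[out.lags == 0] == pytest.approx(3.0)

    def test_shifted_pulses_average_to_centered_pulse(self):
        rng = np.random.default_rng(5)
        n_t, n_pix = 40, 100
        pulse = np.exp(-0.5 * ((np.arange(n_t) - 20.0) / 2.0) ** 2)
        traces, refs = [], []
        for _ in range(n_pix):
            shift = rng.integers(-8, 9)
            traces.append(np.roll(pulse, shift))
            refs.append(np.roll(pulse, shift))
        out = align_traces_to_peak(np.array(traces), np.array(refs))
        assert out.mean[out.lags == 0] == pytest.approx(1.0, abs=1e-9)
        center = out.mean[np.abs(out.lags) <= 4]
        expected = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
        assert np.allclose(center, expected, atol=1e-9)

    def test_flat_reference_excluded_and_tie_flagged(self):
        traces = np.array([[1.0, 2.0, 1.0], [1.0, 2.0, 1.0],
                           [0.0, 5.0, 5.0]])
        refs = np.array([[0.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 3.0, 3.0]])
        out = align_traces_to_peak(traces, refs)
        assert out.n_excluded == 1
        assert out.n_ties == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_traces_to_peak(np.zeros((2, 5)), np.zeros((3, 5)))
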