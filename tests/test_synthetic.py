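"""Generators: presets, pull/kymograph simulation, events, movies, lifetimes."""

import numpy as np
import pytest
from scipy import stats

from otsforce import (ForceExtensionModel, make_scenario, render_kymograph,
                      render_movie, simulate_activation_events,
                      simulate_lifetimes, simulate_pull)
from otsforce.synthetic import PRESETS, RuptureModel, _pixel_gaussian


class TestMakeScenario:
    def test_u2os_basal_carries_measured_parameters(self):
        cfg = make_scenario("u2os_basal")
        assert cfg.delay_decay_time == 13.4
        assert cfg.delta_F == 13.2
        assert cfg.frame_interval == 5.0

    def test_thp1_basal_decay_from_measured_rate(self):
        cfg = make_scenario("thp1_basal")
        assert cfg.delay_decay_time == pytest.approx(13.2 / 2.7)
        assert cfg.frame_interval == 2.5
        assert cfg.loading_rate == pytest.approx(2.7)

    @pytest.mark.parametrize("name,rate", [
        ("u2os_blebbistatin", 0.74), ("u2os_ck666", 0.56),
        ("thp1_hypertonic", 1.9), ("thp1_hypotonic", 4.0),
        ("thp1_cytochalasinD", 1.8)])
    def test_inhibitor_presets_encode_measured_rates(self, name, rate):
        assert make_scenario(name).loading_rate == pytest.approx(rate)

    def test_custom_missing_field_rejected(self):
        with pytest.raises(ValueError, match="delta_F"):
            make_scenario("custom", {"delay_decay_time": 10.0,
                                     "frame_interval": 5.0,
                                     "movie_duration": 100.0})

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_scenario("hela_basal")

    def test_unknown_override_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            make_scenario("u2os_basal", {"exposure": 0.2})

    def test_invalid_value_names_the_field(self):
        with pytest.raises(ValueError, match="delay_decay_time"):
            make_scenario("u2os_basal", {"delay_decay_time": -1.0})


class TestSimulatePull:
    fe = ForceExtensionModel()
    gauss = RuptureModel(kind="gaussian_threshold", mean_force=44.0,
                         sd_force=3.9)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            simulate_pull(self.fe, 0.0, self.gauss, 10, seed=1)

    def test_force_nondecreasing(self):
        pull, _ = simulate_pull(self.fe, 100.0, self.gauss, 5, seed=1)
        assert np.all(np.diff(pull.force) >= 0)

    def test_gaussian_threshold_sample_mean(self):
        _, truth = simulate_pull(self.fe, 100.0, self.gauss, 96, seed=2)
        forces = truth.ruptures.loc[~truth.ruptures.censored,
                                    "rupture_force_pN"]
        assert abs(forces.mean() - 44.0) < 1.0

    def test_bell_evans_force_increases_with_speed(self):
        rup = RuptureModel(kind="bell_evans", k0=3e-10, x_dagger=2.0)
        means = []
        for i, v in enumerate((20.0, 300.0)):
            _, truth = simulate_pull(self.fe, v, rup, 200, seed=10 + i)
            means.append(truth.ruptures.loc[~truth.ruptures.censored,
                                            "rupture_force_pN"].mean())
        assert means[1] > means[0]

    def test_out_of_range_draws_censored_not_dropped(self):
        high = RuptureModel(kind="gaussian_threshold", mean_force=69.5,
                            sd_force=3.0)
        _, truth = simulate_pull(self.fe, 100.0, high, 200, seed=3)
        r = truth.ruptures
        assert len(r) == 200  # censoring bookkeeping
        assert r.censored.sum() > 0
        assert r.loc[r.censored, "rupture_force_pN"].isna().all()

    def test_reproducible_given_seed(self):
        a = simulate_pull(self.fe, 100.0, self.gauss, 20, seed=5)[1]
        b = simulate_pull(self.fe, 100.0, self.gauss, 20, seed=5)[1]
        assert a.ruptures.equals(b.ruptures)


class TestRenderKymograph:
    def test_noiseless_step_at_rupture_frame(self):
        fe = ForceExtensionModel()
        rup = RuptureModel(kind="gaussian_threshold", mean_force=44.0,
                           sd_force=3.9)
        pull, truth = simulate_pull(fe, 100.0, rup, 3, seed=4)
        traces = render_kymograph(pull, truth.ruptures, noise_sd=0.0, seed=0)
        for tr, (_, row) in zip(traces, truth.ruptures.iterrows()):
            post = tr.frame_times >= row.rupture_time_s
            assert np.all(tr.intensity[post] == 0.0)
            assert np.all(tr.intensity[~post] == 1.0)

    def test_censored_probe_gives_constant_trace(self):
        import pandas as pd
        fe = ForceExtensionModel()
        rup = RuptureModel(kind="gaussian_threshold", mean_force=44.0,
                           sd_force=3.9)
        pull, _ = simulate_pull(fe, 100.0, rup, 1, seed=4)
        ruptures = pd.DataFrame({"probe_id": ["c"], "rupture_time_s": [np.nan],
                                 "rupture_force_pN": [np.nan],
                                 "censored": [True]})
        tr, = render_kymograph(pull, ruptures, noise_sd=0.0, seed=0)
        assert np.ptp(tr.intensity) == 0


class TestActivationEvents:
    def test_delay_mean_matches_preset_within_10pct(self):
        cfg = make_scenario("u2os_basal",
                            {"n_events": 1000, "movie_duration": 10000.0,
                             "field_size_px": 512, "min_separation_px": 2.0})
        truth = simulate_activation_events(cfg, seed=1)
        ev = truth.events.dropna(subset=["t_on_B_s"])
        delays = ev.t_on_B_s - ev.t_on_A_s
        assert abs(delays.mean() - 13.4) / 13.4 < 0.10

    def test_near_zero_decay_gives_zero_delays(self):
        cfg = make_scenario("u2os_basal", {"delay_decay_time": 1e-12,
                                           "n_events": 50})
        truth = simulate_activation_events(cfg, seed=1)
        assert truth.events.censored.sum() == 0
        delays = truth.events.t_on_B_s - truth.events.t_on_A_s
        assert np.all(delays < 1e-6)

    def test_tiny_movie_fully_censored(self):
        cfg = make_scenario("u2os_basal", {"movie_duration": 1e-6,
                                           "n_events": 30})
        truth = simulate_activation_events(cfg, seed=1)
        assert truth.events.censored.all()
        assert truth.events.t_on_B_s.isna().all()

    def test_censoring_bookkeeping_sums_to_n(self):
        cfg = make_scenario("thp1_basal")
        truth = simulate_activation_events(cfg, seed=2)
        ev = truth.events
        assert len(ev) == cfg.n_events
        assert ev.censored.sum() + ev.t_on_B_s.notna().sum() == cfg.n_events

    def test_exponential_delays_pass_ks_at_large_n(self):
        cfg = make_scenario("u2os_basal",
                            {"n_events": 10_000, "movie_duration": 1e9,
                             "field_size_px": 4096,
                             "min_separation_px": 0.0})
        truth = simulate_activation_events(cfg, seed=3)
        delays = truth.events.t_on_B_s - truth.events.t_on_A_s
        p = stats.kstest(delays, "expon", args=(0, 13.4)).pvalue
        assert p > 0.01

    def test_reproducible_given_seed(self):
        cfg = make_scenario("thp1_basal")
        a = simulate_activation_events(cfg, seed=7).events
        b = simulate_activation_events(cfg, seed=7).events
        assert a.equals(b)


class TestRenderMovie:
    def test_zero_events_gives_background_only(self):
        cfg = make_scenario("thp1_basal", {"n_events": 0,
                                           "movie_duration": 10.0,
                                           "field_size_px": 64})
        truth = simulate_activation_events(cfg, seed=1)
        movie = render_movie(truth, cfg, seed=2)
        assert movie.pixels.shape[1] == 2
        assert abs(movie.pixels.mean() - cfg.background_mean) < 1.0

    def test_single_event_integrates_to_unit_intensity(self):
        cfg = make_scenario("thp1_basal", {"n_events": 1,
                                           "movie_duration": 10.0,
                                           "field_size_px": 64})
        truth = simulate_activation_events(cfg, seed=1)
        movie = render_movie(truth, cfg, shot_noise=False)
        ev = truth.events.iloc[0]
        last = movie.pixels[-1, 0] - cfg.background_mean
        yy, xx = np.mgrid[0:64, 0:64]
        aperture = ((yy - ev.y_px) ** 2 + (xx - ev.x_px) ** 2
                    <= (5 * cfg.psf_sigma) ** 2)
        total = last[aperture].sum()
        assert total == pytest.approx(cfg.unit_intensity, rel=1e-3)

    def test_pixel_gaussian_sums_to_one(self):
        prof = _pixel_gaussian(10.3, 12.7, 1.2, 0, 24, 0, 24)
        assert prof.sum() == pytest.approx(1.0, abs=1e-6)

    def test_event_absent_before_onset_frame(self):
        cfg = make_scenario("thp1_basal", {"n_events": 1,
                                           "movie_duration": 20.0,
                                           "field_size_px": 64})
        truth = simulate_activation_events(cfg, seed=5)
        movie = render_movie(truth, cfg, shot_noise=False)
        ev = truth.events.iloc[0]
        first_frame = int(np.ceil(ev.t_on_A_s / cfg.frame_interval))
        if first_frame > 0:
            before = movie.pixels[first_frame - 1, 0] - cfg.background_mean
            assert np.abs(before).max() < 1e-9


class TestSimulateLifetimes:
    def test_empty_for_n_zero(self):
        truth = simulate_lifetimes(9.0, 10.0, 0, seed=1)
        assert len(truth.tracks) == 0

    def test_zero_interval_returns_continuous_lifetimes(self):
        truth = simulate_lifetimes(9.0, 0.0, 500, seed=2)
        t = truth.tracks
        closed = t[~t.censored]
        assert np.allclose(closed.duration_obs_s, closed.lifetime_true_s)

    def test_observed_durations_are_multiples_of_stride(self):
        truth = simulate_lifetimes(9.0, 10.0, 200, seed=3)
        obs = truth.tracks.duration_obs_s
        assert np.allclose(np.round(obs / 10.0) * 10.0, obs)

    def test_censoring_bookkeeping_sums_to_n(self):
        truth = simulate_lifetimes(9.0, 10.0, 300, seed=4, duration=50.0)
        t = truth.tracks
        assert len(t) == 300
        assert t.censored.sum() + (~t.censored).sum() == 300
        assert t.censored.sum() > 0

    def test_lifetimes_pass_ks_at_large_n(self):
        truth = simulate_lifetimes(9.0, 0.0, 10_000, seed=5, duration=1e9)
        p = stats.kstest(truth.tracks.lifetime_true_s, "expon",
                         args=(0, 9.0)).pvalue
        assert p > 0.01

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            simulate_lifetimes(-1.0, 10.0, 10, seed=1)
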