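"""End-to-end analysis chains used by the drivers, CLI and tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rates, spots, synthetic, tweezers
from .exponential import ExponentialFit


@dataclass
class MoviePipelineResult:
    config: synthetic.ScenarioConfig
    truth: synthetic.GroundTruth
    n_tracks_a: int
    n_tracks_b: int
    pairs: list
    fit: ExponentialFit
    estimate: rates.LoadingRateEstimate


def movie_loading_rate(cfg: synthetic.ScenarioConfig, seed: int,
                       min_snr: float = 5.0, max_disp: float = 2.0,
                       max_gap: int = 1, radius: float = 2.0,
                       delta_F: float | None = None,
                       n_boot: int = 1000) -> MoviePipelineResult:
    """Full imaging chain: simulate, render, detect, track, pair, fit.

    Seeds for event generation, rendering and the bootstrap are derived
    from ``seed`` so the whole chain is reproducible from one integer.
    """
    truth = synthetic.simulate_activation_events(cfg, seed=seed)
    movie = synthetic.render_movie(truth, cfg, seed=seed + 1)
    tracks = {}
    for ch in (0, 1):
        per_frame = spots.detect_movie(movie, ch, cfg.psf_sigma, min_snr)
        tracks[ch] = spots.link_tracks(per_frame, max_disp=max_disp,
                                       max_gap=max_gap,
                                       frame_interval=cfg.frame_interval)
    movie_end = (movie.n_frames - 1) * cfg.frame_interval
    pairs = rates.colocalize(tracks[0], tracks[1], radius=radius,
                             movie_end=movie_end)
    fit = rates.fit_delay_exponential(pairs, cfg.frame_interval,
                                      quantization="difference",
                                      n_boot=n_boot, rng=seed + 2)
    est = rates.compute_loading_rate(
        cfg.delta_F if delta_F is None else delta_F, fit)
    return MoviePipelineResult(config=cfg, truth=truth,
                               n_tracks_a=len(tracks[0]),
                               n_tracks_b=len(tracks[1]),
                               pairs=pairs, fit=fit, estimate=est)


def tweezers_force_recovery(mean_force: float, sd_force: float, n_probes: int,
                            speed: float, seed: int,
                            noise_fraction: float = 0.1,
                            kymo_interval: float = 0.1,
                            fe_model: tweezers.ForceExtensionModel | None = None,
                            ) -> tweezers.ForceDistributionFit:
    """Full calibration chain on one simulated pull.

    Simulates ``n_probes`` Gaussian-threshold ruptures on a constant-speed
    pull, renders unit-intensity kymographs at the given read-noise
    fraction (SNR = 1/noise_fraction), detects the disappearance steps,
    interpolates forces and fits the Gaussian force distribution.  The
    kymograph stride is kept short (0.1 s) because the step detector
    localizes the rupture at the first post-step frame, a late bias of up
    to half a stride times the loading rate.
    """
    fe = fe_model or tweezers.ForceExtensionModel()
    rupture = synthetic.RuptureModel(kind="gaussian_threshold",
                                     mean_force=mean_force, sd_force=sd_force)
    pull, truth = synthetic.simulate_pull(fe, speed, rupture, n_probes,
                                          seed=seed)
    traces = synthetic.render_kymograph(pull, truth.ruptures,
                                        noise_sd=noise_fraction, seed=seed + 1,
                                        frame_interval=kymo_interval)
    events = tweezers.calibrate_pull(pull, traces, fe_model=fe)
    return tweezers.fit_force_distribution(events)


def bell_evans_speed_series(speeds, k0: float, x_dagger: float,
                            n_probes: int, seed: int,
                            fe_model: tweezers.ForceExtensionModel | None = None,
                            ) -> dict[float, float]:
    """Mean simulated rupture force at each stretching speed."""
    fe = fe_model or tweezers.ForceExtensionModel()
    rupture = synthetic.RuptureModel(kind="bell_evans", k0=k0,
                                     x_dagger=x_dagger, kBT=fe.kBT)
    out = {}
    for i, v in enumerate(speeds):
        _, truth = synthetic.simulate_pull(fe, v, rupture, n_probes,
                                           seed=seed + i)
        forces = truth.ruptures.loc[~truth.ruptures.censored,
                                    "rupture_force_pN"]
        out[float(v)] = float(forces.mean())
    return out


def lifetime_recovery(mean_lifetime: float, frame_interval: float, n: int,
                      seed: int, method: str = "mle_censored",
                      n_boot: int = 1000) -> ExponentialFit:
    """Generate stroboscopically observed lifetimes and fit them back."""
    truth = synthetic.simulate_lifetimes(mean_lifetime, frame_interval, n,
                                         seed=seed)
    tracks = synthetic.tracks_to_spottracks(truth)
    return spots.fit_lifetime(tracks, frame_interval, method=method,
                              n_boot=n_boot, rng=seed + 1)


def delay_recovery(cfg: synthetic.ScenarioConfig, n: int, seed: int,
                   n_boot: int = 1000) -> ExponentialFit:
    """Directly sampled (uncensored) delays, stride-quantized, refit.

    Draws ``n`` exponential delays with the scenario's decay time,
    quantizes them up to the acquisition stride and fits the censored
    interval-aware MLE.
    """
    rng = np.random.default_rng(seed)
    delays = rng.exponential(cfg.delay_decay_time, n)
    T = cfg.frame_interval
    quantized = np.ceil(np.maximum(delays, 1e-12) / T) * T
    pairs = [rates.ActivationPair(x=0.0, y=0.0, t_on_A=0.0, t_on_B=d,
                                  delay=d, pair_distance=0.0)
             for d in quantized]
    return rates.fit_delay_exponential(pairs, T, quantization="ceil",
                                       n_boot=n_boot, rng=seed + 1)
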