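"""Serial-sensor loading-rate estimation.

Two serially connected sensors with different force thresholds light up
in sequence as the force on one receptor-ligand bond ramps up; the delay
between the low-threshold (channel A) and high-threshold (channel B)
activations at one diffraction-limited spot is exponential with decay
time tau, and the loading rate is delta_F / tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exponential import ExponentialFit, fit_exponential
from .spots import SpotTrack


@dataclass
class ActivationPair:
    """A matched (or censored) two-channel activation at one spot."""

    x: float
    y: float
    t_on_A: float
    t_on_B: float | None         # None when censored
    delay: float                 # s; censoring time when censored
    pair_distance: float         # px; nan when censored
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class LoadingRateEstimate:
    delta_F: float               # pN
    decay_time: float            # s
    rate: float                  # pN/s
    ci90: tuple[float, float]    # pN/s
    n_pairs: int
    n_censored: int

    def __post_init__(self) -> None:
        if abs(self.rate - self.delta_F / self.decay_time) > 1e-9 * self.rate:
            raise ValueError("rate must equal delta_F / decay_time")
        if self.ci90[0] > self.ci90[1]:
            raise ValueError("ci90 must be ordered")


def colocalize(tracksA: list[SpotTrack], tracksB: list[SpotTrack],
               radius: float, movie_end: float) -> list[ActivationPair]:
    """Match channel-B onsets to channel-A onsets within a radius.

    Greedy matching ordered by pair distance (ties broken by earlier B
    onset); each track is used at most once and a valid pair requires
    the B onset not to precede the A onset.  A-channel onsets that never
    acquire a B partner become right-censored pairs with censoring time
    ``movie_end - t_on_A``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    cands = []
    for ai, ta in enumerate(tracksA):
        ax, ay = ta.position
        for bi, tb in enumerate(tracksB):
            bx, by = tb.position
            if tb.t_on < ta.t_on:
                continue
            dist = float(np.hypot(bx - ax, by - ay))
            if dist <= radius:
                cands.append((dist, tb.t_on, ai, bi))
    cands.sort(key=lambda c: (c[0], c[1]))
    used_a, used_b = set(), set()
    pairs = []
    for dist, _, ai, bi in cands:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        ta, tb = tracksA[ai], tracksB[bi]
        ax, ay = ta.position
        pairs.append(ActivationPair(
            x=ax, y=ay, t_on_A=ta.t_on, t_on_B=tb.t_on,
            delay=tb.t_on - ta.t_on, pair_distance=dist))
    for ai, ta in enumerate(tracksA):
        if ai in used_a:
            continue
        ax, ay = ta.position
        pairs.append(ActivationPair(
            x=ax, y=ay, t_on_A=ta.t_on, t_on_B=None,
            delay=max(movie_end - ta.t_on, 0.0),
            pair_distance=float("nan"), censored=True))
    return pairs


def fit_delay_exponential(pairs: list[ActivationPair], frame_interval: float,
                          method: str = "mle_censored",
                          quantization: str = "difference",
                          n_boot: int = 1000, rng=None) -> ExponentialFit:
    """Single-exponential fit of A-to-B activation delays.

    The default censored MLE accounts for the stroboscopic acquisition:
    movie-derived delays are differences of two onsets each rounded up
    to the stride (``quantization="difference"``); directly stride-
    quantized delays use ``quantization="ceil"``.  Censored pairs
    contribute survival terms.  ``histogram_lsq`` bins the uncensored
    delays at the stride and fits A*exp(-t/tau) for parity with
    delay-histogram figures.  The 90% CI is a seeded percentile
    bootstrap.
    """
    delays = np.array([p.delay for p in pairs], float)
    censored = np.array([p.censored for p in pairs], bool)
    n_obs = int(np.sum(~censored))
    if n_obs < 20:
        raise ValueError(f"need >= 20 uncensored pairs, got {n_obs}")
    return fit_exponential(delays, censored, interval=frame_interval,
                           quantization=quantization, method=method,
                           n_boot=n_boot, rng=rng)


def compute_loading_rate(delta_F: float,
                         fit: ExponentialFit) -> LoadingRateEstimate:
    """Loading rate delta_F / tau with the CI transformed from tau's."""
    if delta_F <= 0:
        raise ValueError("delta_F must be > 0")
    lo_tau, hi_tau = fit.ci90
    rate_ci = (delta_F / hi_tau, delta_F / lo_tau)
    return LoadingRateEstimate(
        delta_F=delta_F, decay_time=fit.decay_time,
        rate=delta_F / fit.decay_time, ci90=rate_ci,
        n_pairs=fit.n, n_censored=fit.n_censored)


def chance_pairing_rate(labeled_fraction: float,
                        activation_prob_per_timepoint: float,
                        n_timepoints: int) -> float:
    """Probability of a coincidental second activation on one sensor.

    With a fraction ``labeled_fraction`` of sensors carrying a dye and a
    per-timepoint activation probability, the chance that an independent
    second activation lands on an already-activated labeled sensor
    within ``n_timepoints`` observations is
    ``1 - (1 - labeled_fraction * p)**n``.
    """
    for name, v in (("labeled_fraction", labeled_fraction),
                    ("activation_prob_per_timepoint",
                     activation_prob_per_timepoint)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_timepoints < 0:
        raise ValueError("n_timepoints must be >= 0")
    p = labeled_fraction * activation_prob_per_timepoint
    return float(-np.expm1(n_timepoints * np.log1p(-p))) if p < 1 else 1.0
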