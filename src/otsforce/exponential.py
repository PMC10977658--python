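"""Exponential dwell-time fitting under right- and interval censoring.

Shared statistical core for spot-lifetime and channel-delay analysis.
Dwell times here are exponential waiting times observed stroboscopically:
a movie samples the field every ``interval`` seconds, so a duration is
only known up to the acquisition stride, and waiting times still running
when the movie ends are right-censored.

Three observation models are supported for an uncensored duration ``d``:

``none``
    ``d`` is exact (continuous observation).  The MLE is then the
    classic closed form sum(all durations) / n(uncensored).
``ceil``
    ``d`` is a continuous waiting time rounded *up* to the stride, so
    the true value lies in ``(d - interval, d]``.
``difference``
    ``d`` is the difference of two onset times that were each rounded up
    to the stride (the two-channel movie case).  The quantization error
    is then triangular on ``(d - interval, d + interval)`` and the exact
    marginal probability of observing ``d = j*interval`` under an
    exponential with decay ``tau`` is

        j = 0:  1 - (tau/T) * (1 - rho)
        j >= 1: (tau/T) * rho**(j-1) * (1 - rho)**2,   rho = exp(-T/tau)

Right-censored entries contribute the survival term exp(-c/tau) in every
mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

_LOG_EPS = 1e-300


@dataclass
class ExponentialFit:
    """Result of a single-exponential dwell-time fit."""

    decay_time: float            # s
    ci90: tuple[float, float]    # s, 5th-95th bootstrap percentiles
    n: int                       # uncensored observations
    method: str                  # mle_censored | histogram_lsq | cumulative_lsq
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.decay_time <= 0:
            raise ValueError("decay_time must be > 0")
        lo, hi = self.ci90
        if not (lo <= self.decay_time <= hi):
            raise ValueError("decay_time must lie inside ci90")


def _neg_loglik(tau: float, durations: np.ndarray, censored: np.ndarray,
                interval: float, quantization: str) -> float:
    obs = durations[~censored]
    cens = durations[censored]
    ll = -np.sum(cens) / tau
    if obs.size == 0:
        return -ll
    if quantization == "none" or interval == 0:
        ll += -len(obs) * np.log(tau) - np.sum(obs) / tau
    elif quantization == "ceil":
        lo = np.maximum(obs - interval, 0.0)
        p = np.exp(-lo / tau) - np.exp(-obs / tau)
        ll += np.sum(np.log(np.maximum(p, _LOG_EPS)))
    elif quantization == "difference":
        T = interval
        rho = np.exp(-T / tau)
        j = np.rint(obs / T)
        zero = j <= 0
        p = np.where(
            zero,
            1.0 - (tau / T) * (1.0 - rho),
            (tau / T) * rho ** np.maximum(j - 1, 0) * (1.0 - rho) ** 2,
        )
        ll += np.sum(np.log(np.maximum(p, _LOG_EPS)))
    else:
        raise ValueError(f"unknown quantization {quantization!r}")
    return -ll


def _mle(durations: np.ndarray, censored: np.ndarray, interval: float,
         quantization: str) -> float:
    obs = durations[~censored]
    if quantization == "none" or interval == 0:
        # closed-form censored-exponential MLE
        return float(np.sum(durations) / max(len(obs), 1))
    mean0 = max(float(np.mean(obs)) if obs.size else interval, 1e-6)
    res = minimize_scalar(
        lambda log_tau: _neg_loglik(np.exp(log_tau), durations, censored,
                                    interval, quantization),
        bracket=(np.log(mean0) - 2.0, np.log(mean0) + 0.5),
        method="brent", options={"xtol": 1e-10},
    )
    return float(np.exp(res.x))


def fit_exponential(durations, censored=None, interval: float = 0.0,
                    quantization: str = "none", method: str = "mle_censored",
                    n_boot: int = 1000, rng=None) -> ExponentialFit:
    """Fit a single-exponential decay time to (possibly censored) durations.

    Parameters
    ----------
    durations
        Observed durations (s).  For censored entries this is the
        censoring time.
    censored
        Boolean mask, True where the duration is right-censored.
    interval
        Acquisition stride (s); 0 means exact continuous observation.
    quantization
        Observation model for uncensored durations: "none", "ceil" or
        "difference" (see module docstring).
    method
        "mle_censored" (default), "histogram_lsq" (bin at the stride and
        fit A*exp(-t/tau) to the counts) or "cumulative_lsq" (fit
        N*(1-exp(-t/tau)) to the empirical cumulative count).
    n_boot
        Bootstrap resamples for the 90% CI (percentile method).
    """
    durations = np.asarray(durations, float)
    if censored is None:
        censored = np.zeros(len(durations), bool)
    censored = np.asarray(censored, bool)
    if len(censored) != len(durations):
        raise ValueError("durations and censored must have equal length")
    n_obs = int(np.sum(~censored))
    if n_obs < 1:
        raise ValueError("no uncensored durations to fit")

    if method == "mle_censored":
        def estimator(d, c):
            return _mle(d, c, interval, quantization)
    elif method == "histogram_lsq":
        def estimator(d, c):
            return _histogram_lsq(d[~c], interval)
    elif method == "cumulative_lsq":
        def estimator(d, c):
            return _cumulative_lsq(d[~c])
    else:
        raise ValueError(f"unknown method {method!r}")

    tau = estimator(durations, censored)
    rng = np.random.default_rng(rng)
    boots = []
    n = len(durations)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        c = censored[idx]
        if np.sum(~c) < 2:
            continue
        try:
            boots.append(estimator(durations[idx], c))
        except (RuntimeError, ValueError):
            continue
    if boots:
        lo, hi = np.percentile(boots, [5, 95])
        lo, hi = min(lo, tau), max(hi, tau)
    else:
        lo = hi = tau
    return ExponentialFit(decay_time=float(tau), ci90=(float(lo), float(hi)),
                          n=n_obs, method=method,
                          n_censored=int(np.sum(censored)))


def _histogram_lsq(obs: np.ndarray, interval: float) -> float:
    """Least-squares A*exp(-t/tau) fit to stride-binned counts."""
    obs = np.round(obs, 9)
    if interval <= 0:
        interval = max(np.ptp(obs) / 15.0, 1e-9)
    edges = np.arange(0.0, obs.max() + 2 * interval, interval)
    counts, edges = np.histogram(obs, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 2:
        # all mass in one bin: decay unresolved below the stride
        return float(max(np.mean(obs), 1e-9))

    def model(t, a, tau):
        return a * np.exp(-t / np.abs(tau))

    p0 = (counts.max(), max(np.mean(obs), interval / 2))
    popt, _ = curve_fit(model, centers[keep], counts[keep], p0=p0,
                        maxfev=10000)
    return float(abs(popt[1]))


def _cumulative_lsq(obs: np.ndarray) -> float:
    """Least-squares N*(1-exp(-t/tau)) fit to the cumulative count."""
    t, counts = np.unique(np.round(obs, 9), return_counts=True)
    cum = np.cumsum(counts).astype(float)

    def model(x, n_inf, tau):
        return n_inf * (1.0 - np.exp(-x / np.abs(tau)))

    p0 = (float(len(t)), max(float(np.mean(obs)), 1e-9))
    popt, _ = curve_fit(model, t, cum, p0=p0, maxfev=10000)
    return float(abs(popt[1]))
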