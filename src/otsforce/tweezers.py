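"""Optical-tweezers dehybridization-force calibration.

Maps probe disappearance in kymographs to dehybridization force, fits
Gaussian force distributions, and converts constant stretching speed to a
force loading rate through a single-stranded-DNA force-extension model.

The force-extension model is an extensible freely-jointed chain (FJC):

    x(F) = n_bases * contour_per_base * [coth(u) - 1/u] * (1 + F/S),
    u = F * kuhn_length / kBT

The default parameters are *effective* template elasticity constants:
they lump the template polymer with series instrument compliance and are
calibrated so that stretching speeds of 20-300 nm/s convert to loading
rates of a few tenths to a few pN/s over the 16-55 pN range probed by the
sensors, matching the rates observed in calibration experiments.  They
are configuration, not physical constants of ssDNA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

KBT_25C = 4.11  # pN nm at 25 degC
KBT_37C = 4.28  # pN nm at 37 degC


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceExtensionModel:
    """Extensible freely-jointed chain for a stretched ssDNA template.

    Parameters are effective: ``stretch_modulus`` absorbs enthalpic
    stretching *and* series compliance of the instrument, and ``n_bases``
    sets the overall contour scale.
    """

    kind: str = "extensible_FJC"
    contour_per_base: float = 0.56   # nm per base
    kuhn_length: float = 2.0         # nm
    stretch_modulus: float = 60.0    # pN (effective)
    n_bases: int = 6500
    kBT: float = KBT_25C             # pN nm

    def __post_init__(self) -> None:
        if self.kind != "extensible_FJC":
            raise ValueError(f"unknown force-extension model kind {self.kind!r}")
        for name in ("contour_per_base", "kuhn_length", "stretch_modulus",
                     "n_bases", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def contour_length(self) -> float:
        return self.n_bases * self.contour_per_base


@dataclass
class PullRecord:
    """One constant-speed pull: synchronous (time, extension, force)."""

    time: np.ndarray        # s, strictly increasing
    extension: np.ndarray   # nm
    force: np.ndarray       # pN
    speed: float            # nm/s
    temperature: float = 25.0  # degC

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.extension = np.asarray(self.extension, float)
        self.force = np.asarray(self.force, float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time, extension and force must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class KymographTrace:
    """Per-probe intensity trace along the stretched template."""

    probe_id: str
    frame_times: np.ndarray  # s
    intensity: np.ndarray    # photons (arbitrary units)
    position: float = 0.0    # nm along template

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, float)
        self.intensity = np.asarray(self.intensity, float)
        if len(self.frame_times) != len(self.intensity):
            raise ValueError("frame_times and intensity must have equal length")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")


@dataclass
class RuptureEvent:
    probe_id: str
    rupture_time: float | None      # s; None when censored
    rupture_force: float | None     # pN; None when censored
    loading_rate_at_rupture: float | None = None  # pN/s
    censored: bool = False

    def __post_init__(self) -> None:
        if self.censored:
            if self.rupture_force is not None:
                raise ValueError("censored events carry no force")
        elif self.rupture_force is not None and self.rupture_force < 0:
            raise ValueError("rupture_force must be >= 0")


@dataclass
class ForceDistributionFit:
    mean: float   # pN
    sd: float     # pN
    n: int        # uncensored events used
    fit_kind: str = "gaussian_mle"
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.n < 3:
            raise ValueError("n must be >= 3")


# ---------------------------------------------------------------------------
# Calibration table
# ---------------------------------------------------------------------------

_CAL_COLUMNS = ["sensor", "duplex_length_bp", "gc_fraction", "chemistry",
                "temperature_C", "speed_nm_s", "force_mean_pN", "force_sd_pN"]

#: Measured force increment between the two serial sensors (dp16 -> dp30),
#: preferred over the difference of nominal thresholds for loading-rate math.
DELTA_F_DP16_DP30 = 13.2  # pN

#: Mean lifetime of transient force-signal subclusters in mature focal
#: adhesions, from refreshed-sensor time-lapse imaging.
SUBCLUSTER_LIFETIME_S = 9.0


def builtin_calibration() -> "CalibrationTable":
    """Dehybridization-force calibration measured by tweezers pulling.

    Room-temperature (25 C) rows for the 18 bp ladder at 100 nm/s, the
    GC-61% speed series, short/long probes and the PNA-DNA hybrid; 37 C
    rows for the sensors used on cells.  SD is NA where not measured.
    """
    rows = [
        # sensor, bp, GC, chemistry, T, speed, mean, sd
        ("18bp_gc39",  18, 0.39, "DNA",     25, 100, 32.0, np.nan),
        ("18bp_gc50",  18, 0.50, "DNA",     25, 100, 35.0, np.nan),
        ("18bp_gc61",  18, 0.61, "DNA",     25, 100, 44.0, 3.9),
        ("18bp_gc83",  18, 0.83, "DNA",     25, 100, 55.0, np.nan),
        # speed series for the GC-61% probe
        ("18bp_gc61",  18, 0.61, "DNA",     25,  20, 43.1, 3.3),
        ("18bp_gc61",  18, 0.61, "DNA",     25,  50, 43.0, 2.9),
        ("18bp_gc61",  18, 0.61, "DNA",     25, 300, 45.5, 4.0),
        # shorter probes: 11 pN below their 18 bp counterparts
        ("15bp_gc40",  15, 0.40, "DNA",     25, 100, 21.0, np.nan),
        ("15bp_gc60",  15, 0.60, "DNA",     25, 100, 24.0, np.nan),
        ("25bp_gc84",  25, 0.84, "DNA",     25, 100, 60.0, np.nan),
        ("pna18_gc83", 18, 0.83, "PNA_DNA", 25, 100, 95.0, np.nan),
        # 37 C sensors (cell-experiment conditions, 100 nm/s)
        ("dp16",       15, 0.40, "DNA",     37, 100, 16.0, np.nan),
        ("dp30",       18, 0.50, "DNA",     37, 100, 30.0, np.nan),
        ("dp46",       18, 0.61, "DNA",     37, 100, 46.0, np.nan),
        ("dp58",       25, 0.84, "DNA",     37, 100, 58.0, np.nan),
    ]
    return CalibrationTable(pd.DataFrame(rows, columns=_CAL_COLUMNS))


class CalibrationTable:
    """Per-sensor dehybridization force at stated temperature and speed."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(_CAL_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"calibration table missing columns: {sorted(missing)}")
        keys = frame[["sensor", "temperature_C", "speed_nm_s"]]
        if keys.duplicated().any():
            raise ValueError("(sensor, temperature, speed) keys must be unique")
        if (frame["force_mean_pN"] <= 0).any():
            raise ValueError("force_mean_pN must be > 0")
        self.frame = frame.reset_index(drop=True)

    def lookup(self, sensor: str, temperature_C: float = 25,
               speed_nm_s: float = 100) -> pd.Series:
        sel = self.frame[
            (self.frame.sensor == sensor)
            & (self.frame.temperature_C == temperature_C)
            & (self.frame.speed_nm_s == speed_nm_s)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"no calibration row for ({sensor!r}, {temperature_C} C, "
                f"{speed_nm_s} nm/s)")
        return sel.iloc[0]

    def delta_F(self, low_sensor: str = "dp16", high_sensor: str = "dp30") -> float:
        """Force increment between two serial sensors.

        For the dp16/dp30 pair the directly measured increment (13.2 pN)
        takes precedence over the difference of nominal thresholds.
        """
        if (low_sensor, high_sensor) == ("dp16", "dp30"):
            return DELTA_F_DP16_DP30
        lo = self.lookup(low_sensor, 37, 100)["force_mean_pN"]
        hi = self.lookup(high_sensor, 37, 100)["force_mean_pN"]
        return float(hi - lo)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Force-extension model evaluation
# ---------------------------------------------------------------------------

def model_extension(model: ForceExtensionModel, force) -> np.ndarray | float:
    """Extension (nm) of the template at the given force (pN).

    Continuous at F -> 0 with limit 0; raises for negative force.
    """
    F = np.asarray(force, float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    u = F * model.kuhn_length / model.kBT
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        lang = np.where(u > 1e-4, 1.0 / np.tanh(np.minimum(u, 500.0)) - 1.0 / u,
                        u / 3.0)  # Langevin function, series for small u
    ext = model.contour_length * lang * (1.0 + F / model.stretch_modulus)
    if np.ndim(force) == 0:
        return float(ext)
    return ext


def model_stiffness(model: ForceExtensionModel, force) -> np.ndarray | float:
    """dF/dx (pN/nm) of the template at the given force, analytic."""
    F = np.asarray(force, float)
    if np.any(F <= 0):
        raise ValueError("force must be > 0")
    b, kBT, S, Lc = (model.kuhn_length, model.kBT,
                     model.stretch_modulus, model.contour_length)
    u = F * b / kBT
    u_safe = np.minimum(u, 500.0)
    lang = np.where(u > 1e-4, 1.0 / np.tanh(u_safe) - 1.0 / u, u / 3.0)
    dlang = np.where(u > 1e-4, 1.0 / u ** 2 - 1.0 / np.sinh(u_safe) ** 2,
                     1.0 / 3.0)
    dxdF = Lc * (dlang * (b / kBT) * (1.0 + F / S) + lang / S)
    if np.any(dxdF <= 0) or not np.all(np.isfinite(dxdF)):
        raise FloatingPointError("flat force-extension region: stiffness undefined")
    out = 1.0 / dxdF
    if np.ndim(force) == 0:
        return float(out)
    return out


def invert_extension(model: ForceExtensionModel, extension: float,
                     f_max: float = 200.0) -> float:
    """Force (pN) at which the model reaches the given extension (nm)."""
    if extension <= 0:
        return 0.0
    hi = f_max
    while model_extension(model, hi) < extension:
        hi *= 2
        if hi > 1e6:
            raise ValueError("extension beyond model range")
    return brentq(lambda F: model_extension(model, F) - extension, 0.0, hi,
                  xtol=1e-9)


def loading_rate_at_force(model: ForceExtensionModel, speed: float,
                          force: float):
    """Loading rate dF/dt = speed * dF/dx (pN/s) at the given force.

    ``speed = 0`` is permitted as the explicit zero-rate limit.
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if np.any(np.asarray(force) <= 0):
        raise ValueError("force must be > 0")
    if speed == 0:
        return 0.0 if np.ndim(force) == 0 else np.zeros(np.shape(force))
    return speed * model_stiffness(model, force)


# ---------------------------------------------------------------------------
# Rupture detection and force assignment
# ---------------------------------------------------------------------------

def step_fit_changepoint(y: np.ndarray) -> tuple[int, float]:
    """Best two-segment (high -> low) step fit of a 1-D trace.

    Minimizes the summed squared error over all changepoints 1..n-1 and
    returns ``(changepoint, sse)`` where the changepoint is the index of
    the first post-step sample.  Vectorized exact search.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 2:
        raise ValueError("trace too short")
    c = np.arange(1, n)
    s1 = np.cumsum(y)[:-1]
    s2 = s1[-1] + y[-1] - s1
    ss_tot = float(np.sum(y ** 2))
    sse = ss_tot - s1 ** 2 / c - s2 ** 2 / (n - c)
    best = int(np.argmin(sse))
    return int(c[best]), float(sse[best])


def detect_rupture(trace: KymographTrace,
                   threshold_fraction: float = 0.5) -> float | None:
    """Rupture time from a kymograph trace, or None when censored.

    The changepoint is the exhaustive least-squares two-segment step fit;
    the step is accepted only when the drop (pre-step median minus
    post-step mean) exceeds ``threshold_fraction`` of the pre-step median.
    """
    if len(trace.intensity) < 5:
        raise ValueError("trace must have at least 5 frames")
    if not 0 < threshold_fraction:
        raise ValueError("threshold_fraction must be > 0")
    y = trace.intensity
    if np.allclose(y, y[0]):
        return None
    cp, _ = step_fit_changepoint(y)
    pre_med = float(np.median(y[:cp]))
    post_mean = float(np.mean(y[cp:]))
    drop = pre_med - post_mean
    if pre_med <= 0 or drop <= threshold_fraction * pre_med:
        return None
    return float(trace.frame_times[cp])


def rupture_force(pull: PullRecord, rupture_time: float) -> float:
    """Force (pN) at the rupture time, linearly interpolated."""
    if not (pull.time[0] <= rupture_time <= pull.time[-1]):
        raise ValueError(
            f"rupture_time {rupture_time} outside pull record "
            f"[{pull.time[0]}, {pull.time[-1]}]")
    return float(np.interp(rupture_time, pull.time, pull.force))


def fit_force_distribution(events: Sequence[RuptureEvent],
                           fit_kind: str = "gaussian_mle",
                           bins: int = 15) -> ForceDistributionFit:
    """Gaussian fit of rupture forces; censored events excluded and counted.

    ``gaussian_mle`` (default) fits mean and SD directly on the raw
    forces; ``gaussian_lsq_histogram`` least-squares fits a Gaussian to a
    binned histogram for parity with histogram-based figure fits.
    """
    forces = np.array([e.rupture_force for e in events if not e.censored],
                      float)
    n_cens = sum(e.censored for e in events)
    if len(forces) < 10:
        raise ValueError(
            f"need >= 10 uncensored events to fit a force distribution, "
            f"got {len(forces)}; collect more pulls")
    if fit_kind == "gaussian_mle":
        mean = float(np.mean(forces))
        sd = float(np.std(forces, ddof=1))
    elif fit_kind == "gaussian_lsq_histogram":
        counts, edges = np.histogram(forces, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, a, mu, sigma):
            return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        p0 = (counts.max(), forces.mean(), forces.std(ddof=1))
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        mean, sd = float(popt[1]), float(abs(popt[2]))
    else:
        raise ValueError(f"unknown fit_kind {fit_kind!r}")
    return ForceDistributionFit(mean=mean, sd=sd, n=len(forces),
                                fit_kind=fit_kind, n_censored=n_cens)


# ---------------------------------------------------------------------------
# Dynamic force spectroscopy summary fit
# ---------------------------------------------------------------------------

def fit_bell_evans(fits: Sequence[tuple[ForceDistributionFit, float]],
                   kBT: float = KBT_25C):
    """Fit mean rupture force vs loading rate to the Bell-Evans prediction.

    F*(r) = (kBT/x_dagger) * ln(r * x_dagger / (k0 * kBT)); a linear
    least-squares fit of mean force against ln(rate).  Returns
    ``(k0, x_dagger, residuals)``; a non-positive slope (no rate
    dependence) is flagged as degenerate.
    """
    if len(fits) < 3:
        raise ValueError("need fits at >= 3 distinct loading rates")
    rates = np.array([r for _, r in fits], float)
    if np.any(rates <= 0):
        raise ValueError("loading rates must be > 0")
    if len(np.unique(rates)) < 3:
        raise ValueError("need >= 3 distinct loading rates")
    means = np.array([f.mean for f, _ in fits], float)
    slope, intercept = np.polyfit(np.log(rates), means, 1)
    resid = means - (slope * np.log(rates) + intercept)
    if slope <= 0:
        raise ValueError(
            "non-positive force-vs-ln(rate) slope: x_dagger diverges "
            "(degenerate, no measurable rate dependence)")
    x_dagger = kBT / slope
    # intercept = slope * ln(x_dagger / (k0 kBT))
    k0 = x_dagger / (kBT * math.exp(intercept / slope))
    return float(k0), float(x_dagger), resid


def calibrate_pull(pull: PullRecord, traces: Sequence[KymographTrace],
                   threshold_fraction: float = 0.5,
                   fe_model: ForceExtensionModel | None = None,
                   ) -> list[RuptureEvent]:
    """Full per-pull chain: detect ruptures and assign forces and rates."""
    events = []
    for tr in traces:
        t = detect_rupture(tr, threshold_fraction)
        if t is None:
            events.append(RuptureEvent(tr.probe_id, None, None, censored=True))
            continue
        F = rupture_force(pull, t)
        rate = (loading_rate_at_force(fe_model, pull.speed, F)
                if fe_model is not None and F > 0 else None)
        events.append(RuptureEvent(tr.probe_id, t, F, rate))
    return events
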