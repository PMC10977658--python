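"""Synthetic data generation for the full sensor-analysis chain.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: constant-speed template
stretching with stochastic probe rupture, kymograph intensity traces,
sparse two-channel activation movies whose channel-B-after-channel-A
delays are exponential, and exponentially distributed spot lifetimes.

Named scenario presets carry the measured cell-condition parameters
(force increment between the serial sensors, delay decay time,
acquisition stride) so that recovery tests run against the values the
measurements produced.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .spots import MovieStack, SpotTrack
from .tweezers import (DELTA_F_DP16_DP30, ForceExtensionModel, KymographTrace,
                       PullRecord, model_extension)

# ---------------------------------------------------------------------------
# Scenario configuration and presets
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "delay_decay_time", "delta_F", "frame_interval", "movie_duration",
    "sensor_density", "labeled_fraction", "unit_intensity",
    "background_mean", "psf_sigma", "pixel_size",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative preset for a two-channel force-activation movie.

    ``delta_F / delay_decay_time`` is the scenario's generative loading
    rate (pN/s).  ``n_events`` is the pooled number of force-activated,
    fluorescently labeled sensors analysed for the condition (the
    per-field density of labeled sensors,
    ``sensor_density * labeled_fraction``, is far below one per field,
    so events are pooled across fields/cells exactly as the per-condition
    delay histograms are).
    """

    name: str
    delay_decay_time: float      # s, exponential decay of the A->B delay
    delta_F: float               # pN between the two serial thresholds
    frame_interval: float        # s, acquisition stride
    movie_duration: float        # s
    sensor_density: float = 0.7      # sensors / um^2
    labeled_fraction: float = 0.006  # fraction of sensors carrying a dye
    unit_intensity: float = 1000.0   # photons per single fluorophore
    background_mean: float = 100.0   # photons / px
    psf_sigma: float = 1.2           # px
    pixel_size: float = 100.0        # nm
    seed: int = 0
    n_events: int = 150
    field_size_px: int = 192
    min_separation_px: float = 8.0

    def __post_init__(self) -> None:
        checks = {
            "delay_decay_time": self.delay_decay_time > 0,
            "delta_F": self.delta_F > 0,
            "frame_interval": self.frame_interval > 0,
            "movie_duration": self.movie_duration > 0,
            "labeled_fraction": 0 <= self.labeled_fraction <= 1,
            "sensor_density": self.sensor_density > 0,
            "unit_intensity": self.unit_intensity > 0,
            "background_mean": self.background_mean >= 0,
            "psf_sigma": self.psf_sigma > 0,
            "pixel_size": self.pixel_size > 0,
            "n_events": self.n_events >= 0,
            "field_size_px": self.field_size_px > 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid value for field {name!r}: "
                                 f"{getattr(self, name)}")

    @property
    def loading_rate(self) -> float:
        """Generative loading rate delta_F / decay time (pN/s)."""
        return self.delta_F / self.delay_decay_time

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.movie_duration / self.frame_interval)) + 1

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


#: Measured per-condition parameters.  Decay times not printed directly are
#: delta_F / measured loading rate.  Epithelial (U2-OS) movies use a 5 s
#: stride, monocyte (THP-1) movies a 2.5 s stride.
PRESETS: dict[str, dict] = {
    "u2os_basal": dict(delay_decay_time=13.4, frame_interval=5.0,
                       movie_duration=300.0),
    "u2os_blebbistatin": dict(delay_decay_time=DELTA_F_DP16_DP30 / 0.74,
                              frame_interval=5.0, movie_duration=300.0),
    "u2os_ck666": dict(delay_decay_time=DELTA_F_DP16_DP30 / 0.56,
                       frame_interval=5.0, movie_duration=300.0),
    "thp1_basal": dict(delay_decay_time=DELTA_F_DP16_DP30 / 2.7,
                       frame_interval=2.5, movie_duration=75.0),
    "thp1_hypertonic": dict(delay_decay_time=DELTA_F_DP16_DP30 / 1.9,
                            frame_interval=2.5, movie_duration=75.0),
    "thp1_hypotonic": dict(delay_decay_time=DELTA_F_DP16_DP30 / 4.0,
                           frame_interval=2.5, movie_duration=75.0),
    "thp1_cytochalasinD": dict(delay_decay_time=DELTA_F_DP16_DP30 / 1.8,
                               frame_interval=2.5, movie_duration=75.0),
}


def make_scenario(name: str, overrides: dict | None = None) -> ScenarioConfig:
    """Build a validated scenario config from a preset name.

    ``name="custom"`` requires every generative field in ``overrides``.
    Unknown preset names and unknown override keys raise ValueError.
    """
    overrides = dict(overrides or {})
    valid = {f.name for f in dataclasses.fields(ScenarioConfig)} - {"name"}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if name == "custom":
        missing = [f for f in _REQUIRED_FIELDS if f not in overrides]
        if missing:
            raise ValueError(f"custom scenario missing fields: {missing}")
        return ScenarioConfig(name="custom", **overrides)
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; known presets: "
                         f"{sorted(PRESETS)} or 'custom'")
    params = {"delta_F": DELTA_F_DP16_DP30, **PRESETS[name], **overrides}
    return ScenarioConfig(name=name, **params)


# ---------------------------------------------------------------------------
# Rupture model and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuptureModel:
    """Stochastic rupture mechanism for the pulling simulator.

    ``gaussian_threshold`` draws each probe's rupture force directly from
    a normal distribution (the empirical description of the measured
    distributions).  ``bell_evans`` samples first passage of the
    force-dependent hazard k(F) = k0 * exp(F * x_dagger / kBT) along the
    actual simulated ramp, which reproduces the increase of mean rupture
    force with loading rate.
    """

    kind: str
    mean_force: float = float("nan")  # pN (gaussian_threshold)
    sd_force: float = float("nan")    # pN (gaussian_threshold)
    k0: float = float("nan")          # 1/s (bell_evans)
    x_dagger: float = float("nan")    # nm (bell_evans)
    kBT: float = 4.11                 # pN nm

    def __post_init__(self) -> None:
        if self.kind == "gaussian_threshold":
            if not self.sd_force > 0:
                raise ValueError("sd_force must be > 0 for gaussian_threshold")
            if not self.mean_force > 0:
                raise ValueError("mean_force must be > 0")
        elif self.kind == "bell_evans":
            if not self.k0 > 0:
                raise ValueError("k0 must be > 0 for bell_evans")
            if not self.x_dagger > 0:
                raise ValueError("x_dagger must be > 0 for bell_evans")
        else:
            raise ValueError(f"unknown rupture model kind {self.kind!r}")


@dataclass
class GroundTruth:
    """Generative truth: activation events, spot tracks, probe ruptures."""

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    tracks: pd.DataFrame = field(default_factory=pd.DataFrame)
    ruptures: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.events):
            both = self.events.dropna(subset=["t_on_B_s"])
            if (both["t_on_B_s"] < both["t_on_A_s"]).any():
                raise ValueError("t_on_B must be >= t_on_A")
        if len(self.tracks):
            if (self.tracks["t_off_s"] < self.tracks["t_on_s"]).any():
                raise ValueError("t_off must be >= t_on")

    @property
    def n_censored_events(self) -> int:
        return int(self.events["censored"].sum()) if len(self.events) else 0


# ---------------------------------------------------------------------------
# Tweezers pull + kymograph simulation
# ---------------------------------------------------------------------------

def simulate_pull(fe_model: ForceExtensionModel, speed: float,
                  rupture: RuptureModel, n_probes: int, seed: int,
                  f_start: float = 5.0, f_max: float = 70.0,
                  dt: float = 0.05) -> tuple[PullRecord, GroundTruth]:
    """Simulate one constant-speed pull with stochastic probe ruptures.

    The template starts under ``f_start`` (the low hybridization tension)
    and is stretched at ``speed`` until the force reaches ``f_max``.
    Each probe's rupture force is drawn from the rupture model evaluated
    along the actual ramp; draws beyond the simulated range are flagged
    censored, never dropped.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    rng = np.random.default_rng(seed)

    f_grid = np.linspace(f_start, f_max, 4000)
    x_grid = model_extension(fe_model, f_grid)
    t_end = (x_grid[-1] - x_grid[0]) / speed
    time = np.arange(0.0, t_end + dt, dt)
    ext = x_grid[0] + speed * time
    force = np.interp(ext, x_grid, f_grid)
    pull = PullRecord(time=time, extension=ext, force=force, speed=speed)

    rows = []
    if rupture.kind == "gaussian_threshold":
        draws = rng.normal(rupture.mean_force, rupture.sd_force, n_probes)
        for i, f in enumerate(draws):
            f = max(f, f_start)
            if f > force[-1]:
                rows.append((f"probe{i:03d}", np.nan, np.nan, True))
            else:
                t = float(np.interp(f, force, time))
                rows.append((f"probe{i:03d}", t, f, False))
    else:  # bell_evans: inversion on the integrated hazard along the ramp
        hazard = rupture.k0 * np.exp(force * rupture.x_dagger / rupture.kBT)
        cumhaz = np.concatenate(
            [[0.0], np.cumsum(0.5 * (hazard[1:] + hazard[:-1]) * np.diff(time))])
        draws = rng.exponential(1.0, n_probes)
        for i, e in enumerate(draws):
            if e > cumhaz[-1]:
                rows.append((f"probe{i:03d}", np.nan, np.nan, True))
            else:
                t = float(np.interp(e, cumhaz, time))
                f = float(np.interp(t, time, force))
                rows.append((f"probe{i:03d}", t, f, False))
    truth = GroundTruth(ruptures=pd.DataFrame(
        rows, columns=["probe_id", "rupture_time_s", "rupture_force_pN",
                       "censored"]))
    return pull, truth


def render_kymograph(pull: PullRecord, ruptures: pd.DataFrame,
                     noise_sd: float, seed: int,
                     frame_interval: float = 0.25,
                     unit: float = 1.0) -> list[KymographTrace]:
    """Per-probe kymograph intensity traces for a simulated pull.

    Each trace is at the unit level before its rupture frame and at
    background (zero) after, with Gaussian read noise of ``noise_sd``.
    Censored probes give constant traces.
    """
    t_ok = ruptures["rupture_time_s"].dropna()
    if len(t_ok) and ((t_ok < pull.time[0]).any() or (t_ok > pull.time[-1]).any()):
        raise ValueError("rupture times must lie within the pull record")
    frame_times = np.arange(pull.time[0], pull.time[-1] + frame_interval,
                            frame_interval)
    rng = np.random.default_rng(seed)
    traces = []
    for _, row in ruptures.iterrows():
        if row["censored"] or not np.isfinite(row["rupture_time_s"]):
            y = np.full(len(frame_times), unit)
        else:
            y = np.where(frame_times < row["rupture_time_s"], unit, 0.0)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, len(y))
        traces.append(KymographTrace(probe_id=str(row["probe_id"]),
                                     frame_times=frame_times, intensity=y))
    return traces


# ---------------------------------------------------------------------------
# Two-channel activation events and movie rendering
# ---------------------------------------------------------------------------

def _draw_positions(rng, n: int, field: int, margin: float,
                    min_sep: float) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (rejection)."""
    lo, hi = margin, field - 1 - margin
    if hi <= lo:
        raise ValueError("field too small for the PSF margin")
    pos = np.empty((0, 2))
    attempts = 0
    while len(pos) < n:
        cand = rng.uniform(lo, hi, 2)
        if len(pos) == 0 or np.all(
                np.hypot(*(pos - cand).T) >= min_sep):
            pos = np.vstack([pos, cand])
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError(
                "could not place events: field too crowded for "
                "min_separation_px")
    return pos


def simulate_activation_events(cfg: ScenarioConfig,
                               seed: int | None = None) -> GroundTruth:
    """Ground-truth two-channel activation events for a scenario.

    Positions are uniform over the field (kept one minimum separation
    apart so spots stay diffraction-resolvable, and 5 PSF sigma away from
    the borders).  Channel-A onsets are uniform over the movie; the
    channel-B onset follows after an exponential delay with the preset's
    decay time.  Events whose B onset falls beyond the movie end keep it
    absent (right-censored).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_events
    margin = 5.0 * cfg.psf_sigma
    pos = _draw_positions(rng, n, cfg.field_size_px, margin,
                          cfg.min_separation_px)
    t_on_a = rng.uniform(0.0, cfg.movie_duration, n)
    delays = rng.exponential(cfg.delay_decay_time, n) \
        if cfg.delay_decay_time > 0 else np.zeros(n)
    t_on_b = t_on_a + delays
    censored = t_on_b > cfg.movie_duration
    events = pd.DataFrame({
        "x_px": pos[:, 0], "y_px": pos[:, 1],
        "t_on_A_s": t_on_a,
        "t_on_B_s": np.where(censored, np.nan, t_on_b),
        "censored": censored,
    })
    return GroundTruth(events=events)


def _pixel_gaussian(x0: float, y0: float, sigma: float,
                    xlo: int, xhi: int, ylo: int, yhi: int) -> np.ndarray:
    """Pixel-integrated unit 2-D Gaussian on [ylo,yhi) x [xlo,xhi)."""
    xs = np.arange(xlo, xhi)
    ys = np.arange(ylo, yhi)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    return np.outer(fy, fx)


def render_movie(truth: GroundTruth, cfg: ScenarioConfig,
                 seed: int | None = None,
                 shot_noise: bool = True) -> MovieStack:
    """Render the two-channel movie for simulated activation events.

    Each active sensor contributes a pixel-integrated 2-D Gaussian of
    integrated intensity ``unit_intensity`` from its onset frame on;
    overlapping events sum.  Poisson shot noise is applied to signal
    plus uniform background.  Channel 0 is the low-threshold sensor
    (A, dp16), channel 1 the high-threshold sensor (B, dp30).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    nf, fs = cfg.n_frames, cfg.field_size_px
    clean = np.zeros((nf, 2, fs, fs))
    frame_times = np.arange(nf) * cfg.frame_interval
    half = int(np.ceil(6 * cfg.psf_sigma))
    for _, ev in truth.events.iterrows():
        x0, y0 = float(ev["x_px"]), float(ev["y_px"])
        xlo, xhi = max(int(x0) - half, 0), min(int(x0) + half + 1, fs)
        ylo, yhi = max(int(y0) - half, 0), min(int(y0) + half + 1, fs)
        prof = cfg.unit_intensity * _pixel_gaussian(
            x0, y0, cfg.psf_sigma, xlo, xhi, ylo, yhi)
        for ch, t_on in ((0, ev["t_on_A_s"]), (1, ev["t_on_B_s"])):
            if not np.isfinite(t_on):
                continue
            j0 = int(np.searchsorted(frame_times, t_on))
            if j0 < nf:
                clean[j0:, ch, ylo:yhi, xlo:xhi] += prof
    if shot_noise:
        pixels = rng.poisson(clean + cfg.background_mean).astype(float)
    else:
        pixels = clean + cfg.background_mean
    return MovieStack(pixels=pixels, pixel_size=cfg.pixel_size,
                      frame_interval=cfg.frame_interval,
                      channel_names=["dp16", "dp30"])


# ---------------------------------------------------------------------------
# Spot lifetimes
# ---------------------------------------------------------------------------

def simulate_lifetimes(mean_lifetime: float, frame_interval: float, n: int,
                       seed: int, duration: float | None = None,
                       ) -> GroundTruth:
    """Exponential spot lifetimes observed with a stroboscopic stride.

    True lifetimes are exponential with the given mean and on-times are
    uniform over the observation window (default 30 mean lifetimes).
    The observed duration is quantized up to the frame interval (a spot
    alive for any fraction of a stride is seen for that whole stride);
    spots still alive at the window end are right-censored.  With
    ``frame_interval = 0`` the continuous lifetimes are returned as is.
    """
    if mean_lifetime <= 0:
        raise ValueError("mean_lifetime must be > 0")
    if duration is None:
        duration = 30.0 * mean_lifetime
    rng = np.random.default_rng(seed)
    if n == 0:
        return GroundTruth(tracks=pd.DataFrame(
            columns=["x_px", "y_px", "t_on_s", "t_off_s", "lifetime_true_s",
                     "duration_obs_s", "censored"]))
    t_on = rng.uniform(0.0, duration, n)
    life = rng.exponential(mean_lifetime, n)
    t_off = t_on + life
    censored = t_off > duration
    if frame_interval > 0:
        obs = np.ceil(np.maximum(life, 1e-12) / frame_interval) \
            * frame_interval
        obs_cens = np.floor((duration - t_on) / frame_interval) \
            * frame_interval
        obs = np.where(censored, np.maximum(obs_cens, 0.0), obs)
    else:
        obs = np.where(censored, duration - t_on, life)
    tracks = pd.DataFrame({
        "x_px": np.zeros(n), "y_px": np.zeros(n),
        "t_on_s": t_on, "t_off_s": np.minimum(t_off, duration),
        "lifetime_true_s": life,
        "duration_obs_s": obs,
        "censored": censored,
    })
    return GroundTruth(tracks=tracks)


def tracks_to_spottracks(truth: GroundTruth) -> list[SpotTrack]:
    """Convert lifetime ground-truth rows to SpotTrack records."""
    out = []
    for i, row in truth.tracks.iterrows():
        out.append(SpotTrack(track_id=int(i), spots=[],
                             t_on=float(row["t_on_s"]),
                             t_off=float(row["t_on_s"] + row["duration_obs_s"]),
                             open=bool(row["censored"])))
    return out


# ---------------------------------------------------------------------------
# CSV export of ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    """Events as CSV: x_px, y_px, t_on_A_s, t_on_B_s (NA if absent), censored."""
    truth.events.to_csv(path, index=False, na_rep="NA")


def read_ground_truth(path) -> GroundTruth:
    events = pd.read_csv(path, na_values=["NA"])
    return GroundTruth(events=events)
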