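"""Single-molecule image analytics for force-activation movies.

Spot detection, single-fluorophore intensity calibration, molecule
counting, frame-difference (signal-increase) stacks, trajectory linking,
lifetime fitting, region totals and peak-aligned trace averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde
from skimage.feature import peak_local_max
from skimage.filters import gaussian as gaussian_filter
from skimage.morphology import disk

from .exponential import ExponentialFit, fit_exponential

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MovieStack:
    """T x C x Y x X intensity stack with physical metadata."""

    pixels: np.ndarray
    pixel_size: float       # nm
    frame_interval: float   # s
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be a T x C x Y x X array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in
                                  range(self.pixels.shape[1])]
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def channel_index(self, channel) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)


@dataclass
class Spot:
    """One detected diffraction-limited spot."""

    frame: int
    channel: str
    x: float                    # subpixel, pixel-center convention
    y: float
    integrated_intensity: float  # photons, background-subtracted
    background: float            # photons / px

    def __post_init__(self) -> None:
        if self.integrated_intensity <= 0:
            raise ValueError("integrated_intensity must be > 0")


@dataclass
class SpotTrack:
    """Time-ordered linked spot trajectory."""

    track_id: int
    spots: list
    t_on: float
    t_off: float
    open: bool = False  # still alive at movie end (right-censored)
    x: float | None = None  # mean position override (for spot-free tracks)
    y: float | None = None

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frames must be strictly increasing within track")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on

    @property
    def position(self) -> tuple[float, float]:
        if self.x is not None and self.y is not None:
            return (self.x, self.y)
        if not self.spots:
            return (np.nan, np.nan)
        return (float(np.mean([s.x for s in self.spots])),
                float(np.mean([s.y for s in self.spots])))


@dataclass
class IntensityCalibration:
    channel: str
    unit_intensity: float  # photons per single fluorophore
    uncertainty: float
    n_spots: int

    def __post_init__(self) -> None:
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be > 0")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _robust_noise(img: np.ndarray) -> float:
    med = np.median(img)
    return float(1.4826 * np.median(np.abs(img - med)))


def detect_spots(frame: np.ndarray, psf_sigma: float,
                 min_snr: float = 5.0, channel: str = "",
                 frame_index: int = 0) -> list[Spot]:
    """Detect diffraction-limited spots in one 2-D frame.

    Band-pass by difference of Gaussians (sigma and 2 sigma), local
    maxima, background-subtracted aperture sum within 3 sigma, threshold
    at ``min_snr`` times the aperture-propagated background noise, then
    subpixel centroid refinement.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    img = np.asarray(frame, float)
    if img.ndim != 2:
        raise ValueError("frame must be 2-D")
    bg = float(np.median(img))
    noise = _robust_noise(img)
    if noise == 0 and np.ptp(img) == 0:
        return []

    dog = gaussian_filter(img, psf_sigma, preserve_range=True) \
        - gaussian_filter(img, 2 * psf_sigma, preserve_range=True)
    dog_noise = _robust_noise(dog)
    peaks = peak_local_max(
        dog, min_distance=max(int(round(2 * psf_sigma)), 1),
        threshold_abs=max(2.0 * dog_noise, 1e-12), exclude_border=False)

    r_ap = 3.0 * psf_sigma
    w = int(np.ceil(r_ap))
    oy, ox = np.mgrid[-w:w + 1, -w:w + 1]
    disk_mask = oy ** 2 + ox ** 2 <= r_ap ** 2
    sub = img - bg
    spots = []
    for py, px in peaks:
        ylo, yhi = max(py - w, 0), min(py + w + 1, img.shape[0])
        xlo, xhi = max(px - w, 0), min(px + w + 1, img.shape[1])
        local = disk_mask[ylo - py + w:yhi - py + w,
                          xlo - px + w:xhi - px + w]
        npix = int(local.sum())
        intensity = float(sub[ylo:yhi, xlo:xhi][local].sum())
        if intensity <= min_snr * noise * np.sqrt(npix):
            continue
        # centroid refinement on the positive part of the local window
        win = np.clip(sub[ylo:yhi, xlo:xhi], 0, None)
        tot = win.sum()
        if tot <= 0:
            continue
        cy = float((win * np.arange(ylo, yhi)[:, None]).sum() / tot)
        cx = float((win * np.arange(xlo, xhi)[None, :]).sum() / tot)
        spots.append(Spot(frame=frame_index, channel=channel, x=cx, y=cy,
                          integrated_intensity=intensity, background=bg))
    return spots


def detect_movie(movie: MovieStack, channel, psf_sigma: float,
                 min_snr: float = 5.0) -> list[list[Spot]]:
    """Run detect_spots on every frame of one channel."""
    ci = movie.channel_index(channel)
    name = movie.channel_names[ci]
    return [detect_spots(movie.pixels[t, ci], psf_sigma, min_snr,
                         channel=name, frame_index=t)
            for t in range(movie.n_frames)]


# ---------------------------------------------------------------------------
# Intensity calibration and counting
# ---------------------------------------------------------------------------

def estimate_unit_intensity(spots: list[Spot]) -> IntensityCalibration:
    """Single-fluorophore unit intensity from a spot population.

    The unit is the mode of the intensity distribution (kernel-density
    peak), which is robust to a multi-molecule tail; the uncertainty is
    the half-width of the density at 80% of its peak.
    """
    if len(spots) < 20:
        raise ValueError(f"need >= 20 spots, got {len(spots)}")
    vals = np.array([s.integrated_intensity for s in spots])
    if np.ptp(vals) == 0:
        return IntensityCalibration(channel=spots[0].channel,
                                    unit_intensity=float(vals[0]),
                                    uncertainty=0.0, n_spots=len(spots))
    kde = gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), 2000)
    dens = kde(grid)
    ipk = int(np.argmax(dens))
    unit = float(grid[ipk])
    above = dens >= 0.8 * dens[ipk]
    # contiguous run containing the peak
    lo = ipk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(grid) - 1 and above[hi + 1]:
        hi += 1
    half_width = 0.5 * (grid[hi] - grid[lo])
    channel = spots[0].channel
    return IntensityCalibration(channel=channel, unit_intensity=unit,
                                uncertainty=float(half_width),
                                n_spots=len(spots))


def count_molecules(region_intensity: float,
                    calib: IntensityCalibration) -> int:
    """Molecule count = region intensity / single-fluorophore unit."""
    if region_intensity < 0:
        warnings.warn("negative region intensity clamped to 0 molecules")
        return 0
    return int(round(region_intensity / calib.unit_intensity))


# ---------------------------------------------------------------------------
# Signal-increase stacks and region totals
# ---------------------------------------------------------------------------

def delta_stack(movie: MovieStack, channel, median_radius: int = 0,
                clamp_negative: bool = True) -> MovieStack:
    """Per-frame forward-difference (signal increase) stack.

    Negative increments are clamped to zero by default (the quantity is
    a signal *increase*); an optional spatial median filter of the given
    radius suppresses pixel noise.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames for increments")
    ci = movie.channel_index(channel)
    diffs = np.diff(movie.pixels[:, ci].astype(float), axis=0)
    if clamp_negative:
        diffs = np.clip(diffs, 0.0, None)
    if median_radius > 0:
        foot = disk(median_radius)
        diffs = np.stack([ndimage.median_filter(f, footprint=foot)
                          for f in diffs])
    name = movie.channel_names[ci]
    return MovieStack(pixels=diffs[:, None], pixel_size=movie.pixel_size,
                      frame_interval=movie.frame_interval,
                      channel_names=[f"delta_{name}"])


def region_total(movie: MovieStack, mask: np.ndarray, frame: int,
                 channel=0) -> float:
    """Background-subtracted total intensity over a binary mask."""
    ci = movie.channel_index(channel)
    img = movie.pixels[frame, ci].astype(float)
    mask = np.asarray(mask, bool)
    if mask.shape != img.shape:
        raise ValueError("mask must match the frame shape")
    if not mask.any():
        warnings.warn("empty mask: region total is 0")
        return 0.0
    outside = img[~mask]
    bg = float(np.median(outside)) if outside.size else 0.0
    return float(np.sum(img[mask] - bg))


# ---------------------------------------------------------------------------
# Track linking
# ---------------------------------------------------------------------------

def link_tracks(spots_per_frame: list[list[Spot]], max_disp: float,
                max_gap: int = 0,
                frame_interval: float = 1.0) -> list[SpotTrack]:
    """Nearest-neighbour linking with gap closing.

    Greedy distance-ordered assignment between open trajectories and the
    detections of each frame; a trajectory stays linkable across up to
    ``max_gap`` missed frames.  ``t_on`` is the first detection's frame
    time and ``t_off`` the last detection's frame time plus one interval;
    trajectories alive in the final frame are flagged open (censored).
    """
    n_frames = len(spots_per_frame)
    active: list[dict] = []
    done: list[dict] = []
    for f in range(n_frames):
        dets = spots_per_frame[f]
        # retire trajectories that exceeded the gap allowance
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if dets:
            cands = []
            for ti, tr in enumerate(active):
                lx, ly = tr["x"], tr["y"]
                for di, d in enumerate(dets):
                    dist = np.hypot(d.x - lx, d.y - ly)
                    if dist <= max_disp:
                        cands.append((dist, ti, di))
            cands.sort(key=lambda c: c[0])
            used_t, used_d = set(), set()
            for dist, ti, di in cands:
                if ti in used_t or di in used_d:
                    continue
                used_t.add(ti)
                used_d.add(di)
                tr = active[ti]
                tr["spots"].append(dets[di])
                tr["last_frame"] = f
                tr["x"], tr["y"] = dets[di].x, dets[di].y
            for di, d in enumerate(dets):
                if di not in used_d:
                    active.append({"spots": [d], "last_frame": f,
                                   "x": d.x, "y": d.y})
    done.extend(active)
    tracks = []
    for i, tr in enumerate(sorted(done,
                                  key=lambda t: t["spots"][0].frame)):
        first, last = tr["spots"][0].frame, tr["spots"][-1].frame
        tracks.append(SpotTrack(
            track_id=i, spots=tr["spots"],
            t_on=first * frame_interval,
            t_off=(last + 1) * frame_interval,
            open=(last == n_frames - 1)))
    return tracks


# ---------------------------------------------------------------------------
# Lifetime fitting
# ---------------------------------------------------------------------------

def fit_lifetime(tracks: list[SpotTrack], frame_interval: float,
                 method: str = "mle_censored", n_boot: int = 1000,
                 rng=None) -> ExponentialFit:
    """Single-exponential fit of spot lifetimes.

    The default is the interval-aware censored exponential MLE: an
    observed duration of k frame intervals places the true lifetime in
    ``((k-1)*T, k*T]`` and open tracks contribute right-censoring
    survival terms.  With ``frame_interval = 0`` durations are treated
    as exact, reducing to the closed form sum(durations)/n(closed).
    ``cumulative_lsq`` fits ``N*(1-exp(-t/tau))`` to the cumulative count
    of closed lifetimes.
    """
    durations = np.array([t.duration for t in tracks], float)
    censored = np.array([t.open for t in tracks], bool)
    n_closed = int(np.sum(~censored))
    if n_closed < 10:
        raise ValueError(f"need >= 10 closed tracks, got {n_closed}")
    quant = "ceil" if frame_interval > 0 else "none"
    return fit_exponential(durations, censored, interval=frame_interval,
                           quantization=quant, method=method,
                           n_boot=n_boot, rng=rng)


# ---------------------------------------------------------------------------
# Peak-aligned trace averaging
# ---------------------------------------------------------------------------

@dataclass
class AlignedTrace:
    lags: np.ndarray        # frames relative to the reference peak
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray           # pixels contributing per lag
    n_excluded: int = 0     # flat reference traces
    n_ties: int = 0         # reference traces with tied maxima


def align_traces_to_peak(traces: np.ndarray,
                         reference: np.ndarray) -> AlignedTrace:
    """Average per-pixel traces after aligning to the reference peak.

    Each pixel's target trace is shifted so that the frame of its
    reference-channel maximum sits at lag 0, then averaged across pixels
    (mean and standard error per lag).  Pixels with a flat reference are
    excluded; ties take the earliest peak and are counted.
    """
    traces = np.asarray(traces, float)
    reference = np.asarray(reference, float)
    if traces.shape != reference.shape:
        raise ValueError("traces and reference must have the same shape")
    if traces.ndim != 2:
        raise ValueError("expected (n_pixels, n_timepoints) arrays")
    n_pix, n_t = traces.shape
    lags = np.arange(-(n_t - 1), n_t)
    sums = np.zeros(len(lags))
    sums2 = np.zeros(len(lags))
    counts = np.zeros(len(lags), int)
    n_excluded = n_ties = 0
    for i in range(n_pix):
        ref = reference[i]
        if np.ptp(ref) == 0:
            n_excluded += 1
            continue
        mx = ref.max()
        peaks = np.flatnonzero(ref == mx)
        if len(peaks) > 1:
            n_ties += 1
        pk = int(peaks[0])
        idx = np.arange(n_t) - pk + (n_t - 1)  # position in lag axis
        sums[idx] += traces[i]
        sums2[idx] += traces[i] ** 2
        counts[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1,
                       (sums2 - counts * mean ** 2) / np.maximum(counts - 1, 1),
                       np.nan)
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1))
    return AlignedTrace(lags=lags, mean=mean, se=se, n=counts,
                        n_excluded=n_excluded, n_ties=n_ties)
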