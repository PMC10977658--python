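"""File formats, run configuration and the staged pipeline runner.

Movies travel as multi-page TIFF (axis order T, C, Y, X) with a YAML
sidecar carrying the physical metadata; tabular outputs are CSV with a
header comment naming units; every artifact records the seed and the
full parameter set that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import pipeline, synthetic, tweezers
from .spots import MovieStack, Spot, SpotTrack

log = logging.getLogger("otsforce")

_SIDECAR_KEYS = ("pixel_size_nm", "frame_interval_s", "channel_names", "axes")


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_movie(movie: MovieStack, path) -> None:
    """Write a movie as TIFF (T,C,Y,X) plus a YAML metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.pixels.astype(np.float32))
    meta = {
        "pixel_size_nm": float(movie.pixel_size),
        "frame_interval_s": float(movie.frame_interval),
        "channel_names": list(movie.channel_names),
        "axes": "TCYX",
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_movie(path) -> MovieStack:
    """Read a TIFF movie with its YAML sidecar; axis order normalized."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {side}; required keys: "
            f"{list(_SIDECAR_KEYS)}")
    meta = yaml.safe_load(side.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {side} missing required keys: {missing}")
    pixels = tifffile.imread(path)
    axes = meta["axes"]
    if pixels.ndim == 3 and axes == "TYX":
        pixels = pixels[:, None]
    elif pixels.ndim != 4 or axes != "TCYX":
        raise ValueError(
            f"cannot interpret axes {axes!r} for a {pixels.ndim}-D stack; "
            "expected TCYX (or TYX for single channel)")
    if pixels.shape[1] != len(meta["channel_names"]):
        raise ValueError("channel axis does not match channel_names")
    return MovieStack(pixels=pixels, pixel_size=meta["pixel_size_nm"],
                      frame_interval=meta["frame_interval_s"],
                      channel_names=list(meta["channel_names"]))


def _write_csv(frame: pd.DataFrame, path, units_comment: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {units_comment}\n")
        frame.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_spots(spots_per_frame: list[list[Spot]], path) -> None:
    rows = [(s.frame, s.channel, s.x, s.y, s.integrated_intensity,
             s.background)
            for frame in spots_per_frame for s in frame]
    frame = pd.DataFrame(rows, columns=["frame", "channel", "x_px", "y_px",
                                        "intensity", "background"])
    _write_csv(frame, path,
               "x_px/y_px: pixels; intensity: photons (bg-subtracted); "
               "background: photons/px")


def write_tracks(tracks: list[SpotTrack], path) -> None:
    rows = []
    for t in tracks:
        x, y = t.position
        rows.append((t.track_id, x, y, t.t_on, t.t_off, t.open))
    frame = pd.DataFrame(rows, columns=["track_id", "x_px", "y_px",
                                        "t_on_s", "t_off_s", "censored"])
    _write_csv(frame, path, "t_on_s/t_off_s: seconds; censored: open at "
                            "movie end")


def read_tracks(path) -> list[SpotTrack]:
    frame = read_csv(path)
    out = []
    for _, r in frame.iterrows():
        out.append(SpotTrack(track_id=int(r.track_id), spots=[],
                             t_on=float(r.t_on_s), t_off=float(r.t_off_s),
                             open=bool(r.censored),
                             x=float(r.x_px), y=float(r.y_px)))
    return out


def write_pairs(pairs, path) -> None:
    rows = [(p.x, p.y, p.t_on_A, p.t_on_B if p.t_on_B is not None else "NA",
             p.delay, p.censored) for p in pairs]
    frame = pd.DataFrame(rows, columns=["x_px", "y_px", "t_on_A_s",
                                        "t_on_B_s", "delay_s", "censored"])
    _write_csv(frame, path, "delay_s: seconds (censoring time when censored)")


# ---------------------------------------------------------------------------
# Run configuration and staged runner
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "detect", "track", "loadrate")


@dataclass
class RunConfig:
    """Validated configuration for a staged pipeline run."""

    scenario: str = "u2os_basal"
    out_dir: str = "results/run"
    seed: int = 1
    log_level: str = "INFO"
    stages: tuple = _STAGES
    psf_sigma: float | None = None   # defaults to the scenario value
    min_snr: float = 5.0
    max_disp: float = 2.0
    max_gap: int = 1
    radius: float = 2.0
    delta_F: float | None = None
    n_boot: int = 1000
    method: str = "mle_censored"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stage names: {unknown}; "
                             f"valid stages: {list(_STAGES)}")
        for name, needs in (("track", "detect"), ("loadrate", "track")):
            if name in self.stages and needs not in self.stages:
                raise ValueError(f"stage {name!r} requires stage {needs!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls.from_mapping(data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write a manifest of the outputs.

    Deterministic for a fixed seed: rerunning the same config reproduces
    identical numerical outputs.
    """
    from . import __version__

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.make_scenario(config.scenario, config.overrides)
    psf = config.psf_sigma if config.psf_sigma is not None else cfg.psf_sigma
    manifest = {
        "seed": config.seed,
        "scenario": config.scenario,
        "parameters": dataclasses.asdict(cfg),
        "run_config": {k: v for k, v in dataclasses.asdict(config).items()},
        "version": __version__,
        "outputs": {},
        "timings_s": {},
    }

    def stage(name):
        if name not in config.stages:
            return False
        manifest["timings_s"][name] = time.perf_counter()
        log.info("stage %s", name)
        return True

    def done(name):
        manifest["timings_s"][name] = round(
            time.perf_counter() - manifest["timings_s"][name], 3)

    try:
        if stage("simulate"):
            truth = synthetic.simulate_activation_events(cfg, seed=config.seed)
            movie = synthetic.render_movie(truth, cfg, seed=config.seed + 1)
            write_movie(movie, out / "movie.tif")
            synthetic.write_ground_truth(truth, out / "ground_truth.csv")
            manifest["outputs"]["movie"] = str(out / "movie.tif")
            manifest["outputs"]["ground_truth"] = str(out / "ground_truth.csv")
            done("simulate")
        else:
            movie = read_movie(out / "movie.tif")

        from . import rates, spots as spots_mod

        if stage("detect"):
            per_frame = {ch: spots_mod.detect_movie(movie, ch, psf,
                                                    config.min_snr)
                         for ch in (0, 1)}
            for ch in (0, 1):
                p = out / f"spots_ch{ch}.csv"
                write_spots(per_frame[ch], p)
                manifest["outputs"][f"spots_ch{ch}"] = str(p)
            done("detect")

        if stage("track"):
            tracks = {}
            for ch in (0, 1):
                tracks[ch] = spots_mod.link_tracks(
                    per_frame[ch], max_disp=config.max_disp,
                    max_gap=config.max_gap,
                    frame_interval=cfg.frame_interval)
                p = out / f"tracks_ch{ch}.csv"
                write_tracks(tracks[ch], p)
                manifest["outputs"][f"tracks_ch{ch}"] = str(p)
            done("track")

        if stage("loadrate"):
            movie_end = (movie.n_frames - 1) * cfg.frame_interval
            pairs = rates.colocalize(tracks[0], tracks[1],
                                     radius=config.radius,
                                     movie_end=movie_end)
            fit = rates.fit_delay_exponential(
                pairs, cfg.frame_interval, method=config.method,
                n_boot=config.n_boot, rng=config.seed + 2)
            est = rates.compute_loading_rate(
                config.delta_F if config.delta_F is not None else cfg.delta_F,
                fit)
            write_pairs(pairs, out / "pairs.csv")
            estimate = {
                "seed": config.seed,
                "delta_F_pN": est.delta_F,
                "tau_s": est.decay_time,
                "rate_pN_per_s": est.rate,
                "ci90_pN_per_s": list(est.ci90),
                "n_pairs": est.n_pairs,
                "n_censored": est.n_censored,
            }
            (out / "estimate.json").write_text(json.dumps(estimate, indent=2))
            manifest["outputs"]["pairs"] = str(out / "pairs.csv")
            manifest["outputs"]["estimate"] = str(out / "estimate.json")
            done("loadrate")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage failed (scenario={config.scenario}, "
            f"seed={config.seed}): {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
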