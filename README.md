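# otsforce

Single-molecule force analysis for DNA **overstretching tension sensors
(OTS)** — rupturable DNA duplexes that dehybridize, unquenching a
fluorophore, once the force across a receptor–ligand bond exceeds a
sequence-programmed threshold. The package implements the three analysis
workflows such sensors require, plus a synthetic-data generator that
emulates every input so the whole chain can be verified end to end
without laboratory data:

1. **Tweezers calibration** (`otsforce.tweezers`): map the disappearance
   of probe fluorescence in kymographs of a stretched ssDNA template to a
   dehybridization force, fit Gaussian force distributions, and convert
   stretching speed to a loading rate through an extensible freely-jointed
   chain (FJC) force–extension model,
   `r = v · (dx/dF)⁻¹`.
2. **Single-molecule imaging analytics** (`otsforce.spots`): spot
   detection (difference-of-Gaussians band-pass + aperture photometry),
   single-fluorophore unit-intensity calibration, molecule counting,
   frame-difference "signal increase" stacks, trajectory linking with gap
   closing, and exponential lifetime fitting under right- and
   interval-censoring.
3. **Serial-sensor loading-rate estimation** (`otsforce.rates`): two
   serially connected sensors with thresholds 16 and 30 pN light up in
   sequence as force ramps; the delay Δt between the two channel onsets at
   one diffraction-limited spot is exponential with decay time τ, and the
   single-bond loading rate is

   `r = ΔF / τ`,  ΔF = 13.2 pN for the dp16/dp30 pair,

   with a stride-aware censored maximum-likelihood fit for τ and a seeded
   bootstrap 90% CI.

The statistical core (`otsforce.exponential`) fits exponential dwell
times when observation is stroboscopic: an observed duration of *k*
strides places the true value in ((k−1)T, kT], and movie-derived onset
differences carry a triangular quantization kernel on (D−T, D+T). Both
exact marginal likelihoods are implemented; ignoring them biases τ by up
to half a stride, which matters because the measured decay times are only
a few strides long.

## Worked example

```python
from otsforce import make_scenario
from otsforce.pipeline import movie_loading_rate

cfg = make_scenario("u2os_basal")        # τ = 13.4 s, ΔF = 13.2 pN, 5 s stride
res = movie_loading_rate(cfg, seed=1)
e = res.estimate
print(f"rate {e.rate:.2f} pN/s (90% CI {e.ci90[0]:.2f}-{e.ci90[1]:.2f}), "
      f"{e.n_pairs} pairs, {e.n_censored} censored")
```

prints

```
rate 0.94 pN/s (90% CI 0.81-1.10), 145 pairs, 5 censored
```

i.e. the full chain — 150 simulated two-channel activation events,
rendered as a Poisson-noise movie, detected, tracked, colocalized and
fitted — recovers the scenario's generative loading rate of
0.99 pN/s (= 13.2 pN / 13.4 s) within its confidence interval.

The numbered drivers under `analysis/` run the same computations as
narrative scripts and write their tables under `results/`:

```sh
python analysis/01_calibrate_tweezers.py     # force ladder + speed series
python analysis/02_loading_rate_conversion.py
python analysis/03_spot_lifetimes.py         # 9 s lifetimes at a 10 s stride
python analysis/04_delay_fit.py
python analysis/05_movie_loading_rates.py    # all seven cell presets
```

A thin CLI exposes the stages (`otsforce simulate | calibrate | detect |
track | lifetime | loadrate | run`); e.g.

```sh
otsforce run --scenario thp1_basal --seed 1 --out results/thp1
```

## Scenario presets

| preset | τ (s) | stride (s) | generative rate (pN/s) |
|---|---|---|---|
| `u2os_basal` | 13.4 | 5 | 0.99 |
| `u2os_blebbistatin` | 17.8 | 5 | 0.74 |
| `u2os_ck666` | 23.6 | 5 | 0.56 |
| `thp1_basal` | 4.89 | 2.5 | 2.7 |
| `thp1_hypertonic` | 6.95 | 2.5 | 1.9 |
| `thp1_hypotonic` | 3.30 | 2.5 | 4.0 |
| `thp1_cytochalasinD` | 7.33 | 2.5 | 1.8 |

Each preset carries the measured decay time (or ΔF divided by the
measured rate), the acquisition stride of the condition, and the default
imaging parameters (100 nm pixels, PSF σ = 1.2 px, 1000-photon unit
intensity, 100 photons/px background). See `docs/methods.md` for the
model assumptions, numerical choices and limitations.
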