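#!/usr/bin/env python
"""Lifetime of transient force-signal subclusters, recovered from
stroboscopic observation.

Simulates exponential spot lifetimes (mean 9 s) observed at a 10 s
acquisition stride — coarser than the lifetime itself — and shows that
both the interval-aware censored MLE and the cumulative-count
least-squares fit recover the mean, while the naive duration average
would not.

Writes results/lifetimes.json.
"""

import json
from pathlib import Path

import numpy as np

from otsforce import simulate_lifetimes
from otsforce.pipeline import lifetime_recovery
from otsforce.tweezers import SUBCLUSTER_LIFETIME_S

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1


def main() -> None:
    mean, stride, n = SUBCLUSTER_LIFETIME_S, 10.0, 300
    out = {"true_mean_s": mean, "stride_s": stride, "n": n, "seed": SEED}
    for method in ("mle_censored", "cumulative_lsq"):
        fit = lifetime_recovery(mean, stride, n, seed=SEED, method=method)
        out[method] = {"lifetime_s": round(fit.decay_time, 2),
                       "ci90_s": [round(c, 2) for c in fit.ci90],
                       "n_closed": fit.n, "n_censored": fit.n_censored}
        print(f"{method}: {fit.decay_time:.2f} s "
              f"(90% CI {fit.ci90[0]:.2f}-{fit.ci90[1]:.2f})")
    truth = simulate_lifetimes(mean, stride, n, seed=SEED)
    naive = float(truth.tracks.loc[~truth.tracks.censored,
                                   "duration_obs_s"].mean())
    out["naive_duration_mean_s"] = round(naive, 2)
    print(f"naive mean of quantized durations: {naive:.2f} s "
          f"(biased high: every lifetime is rounded up to the stride)")
    (OUT / "lifetimes.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
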