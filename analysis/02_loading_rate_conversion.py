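#!/usr/bin/env python
"""Speed-to-loading-rate conversion through the force-extension model.

Converts the tested stretching speeds (20-300 nm/s) into loading rates
over the 16-55 pN range probed by the sensors, using the effective
extensible-FJC template elasticity.  Writes the conversion table and
prints the overall bracket.

Writes results/loading_rate_conversion.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from otsforce import ForceExtensionModel, loading_rate_at_force

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    model = ForceExtensionModel()
    speeds = (20.0, 50.0, 100.0, 300.0)
    forces = np.arange(16.0, 56.0, 1.0)
    rows = [(v, f, loading_rate_at_force(model, v, f))
            for v in speeds for f in forces]
    frame = pd.DataFrame(rows, columns=["speed_nm_s", "force_pN",
                                        "loading_rate_pN_s"])
    frame.to_csv(OUT / "loading_rate_conversion.csv", index=False)

    print("loading-rate conversion (effective extensible FJC):")
    for v in speeds:
        sub = frame[frame.speed_nm_s == v]
        print(f"  {v:>5.0f} nm/s: {sub.loading_rate_pN_s.min():.2f} - "
              f"{sub.loading_rate_pN_s.max():.2f} pN/s over 16-55 pN")
    print(f"overall bracket: {frame.loading_rate_pN_s.min():.2f} - "
          f"{frame.loading_rate_pN_s.max():.2f} pN/s")


if __name__ == "__main__":
    main()
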