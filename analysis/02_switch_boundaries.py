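"""Regime boundaries of the switch in the positive-feedback strength gamma1.

For each Lin28-inhibition efficiency gamma3, two critical gamma1 values
bracket the bistable regime: the cusp (folds appear) and the one-way
boundary (the on-state fold reaches alpha = 0; beyond it switching is
irreversible).  Writes results/switch_boundaries.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from let7switch.equilibria import cusp_gamma1, oneway_boundary_gamma1

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for gamma3 in np.arange(0.0, 2.51, 0.25):
        cusp = cusp_gamma1(0.1, 1.0, float(gamma3))
        oneway = oneway_boundary_gamma1(0.1, 1.0, float(gamma3))
        rows.append((float(gamma3), cusp, oneway, oneway - cusp))
    df = pd.DataFrame(rows, columns=["gamma3", "cusp_gamma1",
                                     "oneway_gamma1", "bistable_width"])
    df.to_csv(OUT / "switch_boundaries.csv", index=False,
              float_format="%.12g")

    print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    key = df[df["gamma3"].isin([0.0, 0.5, 1.0])]
    print("\nkey one-way boundaries (gamma=0.1, gamma2=1):")
    for _, r in key.iterrows():
        print(f"  gamma3={r['gamma3']:.1f}: gamma1* = {r['oneway_gamma1']:.4f}")
    print("\nthe bistable gamma1 interval widens monotonically with gamma3:",
          bool(df["bistable_width"].is_monotonic_increasing))


if __name__ == "__main__":
    sys.exit(main())
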