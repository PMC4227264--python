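"""Steady-state structure at the reference operating geometry.

Computes the S-shaped stimulus-response branch alpha(psi) at gamma = 0.1,
gamma2 = 1, gamma3 = 0.5 for a few feedback strengths gamma1, locates the
fold points, and tabulates the steady states at representative stimuli.

Writes results/branch_gamma1_<g1>.csv (+ _folds.csv) and
results/steady_states.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from let7switch.equilibria import bifurcation_branch, steady_states
from let7switch.model_core import DimensionlessParams
from let7switch.runio import write_branch_csv, write_folds_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for gamma1 in (2.0, 2.3, 2.482, 3.0):
        p = DimensionlessParams(alpha=0.0, gamma=0.1, gamma1=gamma1,
                                gamma2=1.0, gamma3=0.5, epsilon=0.02)
        br = bifurcation_branch(p, psi_min=1e-3, psi_max=10.0, n=2001)
        tag = f"{gamma1:g}".replace(".", "p")
        write_branch_csv(br, OUT / f"branch_gamma1_{tag}.csv")
        write_folds_csv(br, OUT / f"branch_gamma1_{tag}_folds.csv")
        if br.folds:
            a_on = min(f.alpha_fold for f in br.folds)
            a_off = max(f.alpha_fold for f in br.folds)
            print(f"gamma1={gamma1}: bistable stimulus window "
                  f"alpha in ({a_on:.4f}, {a_off:.4f})"
                  + ("  -> one-way (on state survives alpha=0)"
                     if a_on <= 0 else ""))
        else:
            print(f"gamma1={gamma1}: no folds (monostable)")

        for alpha in (0.05, 0.1, 0.2):
            for s in steady_states(p.with_alpha(alpha)):
                rows.append((gamma1, alpha, s.psi_s, s.phi_s, s.stability))

    df = pd.DataFrame(rows, columns=["gamma1", "alpha", "psi_s", "phi_s",
                                     "stability"])
    df.to_csv(OUT / "steady_states.csv", index=False, float_format="%.12g")
    print(f"\nwrote {len(df)} steady states to {OUT / 'steady_states.csv'}")
    n_bi = df.groupby(["gamma1", "alpha"]).size()
    print("operating points with three coexisting states:",
          int((n_bi == 3).sum()), "of", len(n_bi))


if __name__ == "__main__":
    sys.exit(main())
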