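"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's solution paths: steady states come
from a dense sign-change scan of the scalar steady-state equation followed
by bisection, and Jacobians from central finite differences of the
right-hand side.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from let7switch.model_core import DimensionlessParams, State, rhs_dimensionless


def oracle_alpha_of_psi(psi: np.ndarray, p: DimensionlessParams) -> np.ndarray:
    Ds = p.gamma2 + psi ** 2 + p.gamma3 * (psi + p.gamma) / psi
    return psi - p.gamma1 * psi ** 2 / Ds


def oracle_steady_psis(p: DimensionlessParams, lo: float = 1e-6,
                       hi: float = 50.0, n: int = 20001) -> list[float]:
    """Positive steady-state psi values by grid scan + bisection."""
    grid = np.geomspace(lo, hi, n)
    vals = oracle_alpha_of_psi(grid, p) - p.alpha

    def f(x: float) -> float:
        return float(oracle_alpha_of_psi(np.array([x]), p)[0] - p.alpha)

    roots: list[float] = []
    for i in range(n - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1],
                                xtol=1e-13, rtol=8.9e-16))
    return roots


def fd_jacobian(state: State, p: DimensionlessParams,
                h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the dimensionless RHS."""
    out = np.empty((2, 2))
    for j, name in enumerate(("phi", "psi")):
        base = getattr(state, name)
        step = h * max(1.0, abs(base))
        hi_state = State(**{**{"phi": state.phi, "psi": state.psi},
                            name: base + step})
        lo_state = State(**{**{"phi": state.phi, "psi": state.psi},
                            name: max(base - step, 0.0)})
        denom = getattr(hi_state, name) - getattr(lo_state, name)
        hi_val = rhs_dimensionless(hi_state, p)
        lo_val = rhs_dimensionless(lo_state, p)
        out[0, j] = (hi_val[0] - lo_val[0]) / denom
        out[1, j] = (hi_val[1] - lo_val[1]) / denom
    return out
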