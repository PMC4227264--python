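"""Steady states, fold (saddle-node) points and switch boundaries.

At steady state the Lin28 equation forces the reciprocal relation
psi_s (phi_s - 1) = gamma, so phi can be eliminated and the whole branch of
equilibria is parameterized by psi:

    alpha(psi) = psi - gamma1 psi^2 / D_s(psi),
    D_s(psi)   = gamma2 + psi^2 + gamma3 (psi + gamma) / psi.

Folds of the S-shaped response curve are the roots of d alpha/d psi = 0;
the switch is *bistable* when the on-state fold sits at alpha > 0 and
*one-way* (irreversible) when it sits at alpha <= 0, i.e. the on state
survives complete withdrawal of the stimulus.  Both regime boundaries in
gamma1 reduce to scalar root-finding problems solved here in closed or
near-closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model_core import DimensionlessParams, State, jacobian, rhs_dimensionless

__all__ = [
    "SteadyState",
    "FoldPoint",
    "BifurcationBranch",
    "phi_at_steady_state",
    "alpha_of_psi",
    "steady_states",
    "bifurcation_branch",
    "find_folds",
    "oneway_boundary_gamma1",
    "cusp_gamma1",
]

RESIDUAL_TOL = 1e-9
TANGENCY_TOL = 1e-8
# eigenvalue real parts smaller than this are treated as zero (fold-degenerate)
EIG_TOL = 1e-8


@dataclass(frozen=True)
class SteadyState:
    psi_s: float
    phi_s: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "saddle" | "unstable" | "degenerate"


@dataclass(frozen=True)
class FoldPoint:
    """Saddle-node point of the branch alpha(psi).

    kind is "off_state_end" for the local maximum of alpha(psi) (the upper
    switching threshold where the off state is lost) and "on_state_end" for
    the local minimum (the lower threshold where the on state is lost).
    """

    psi_fold: float
    alpha_fold: float
    kind: str


@dataclass(frozen=True)
class BifurcationBranch:
    psi_grid: np.ndarray
    alpha_values: np.ndarray
    stability: list[str] = field(default_factory=list)
    folds: list[FoldPoint] = field(default_factory=list)


def phi_at_steady_state(psi: float, gamma: float) -> float:
    """Steady Lin28 level forced by the Lin28 balance: phi = (psi+gamma)/psi."""
    if psi <= 0:
        raise ValueError(f"psi must be strictly positive, got {psi}")
    return (psi + gamma) / psi


def _Ds(psi: float, p: DimensionlessParams) -> float:
    return p.gamma2 + psi * psi + p.gamma3 * (psi + p.gamma) / psi


def alpha_of_psi(psi: float, p: DimensionlessParams) -> float:
    """Stimulus alpha at which psi is a steady state (phi on its nullcline)."""
    if psi <= 0:
        raise ValueError(f"psi must be strictly positive, got {psi}")
    return psi - p.gamma1 * psi * psi / _Ds(psi, p)


def _dalpha_dpsi(psi: float, p: DimensionlessParams) -> float:
    # d/dpsi [psi - g1 psi^2 / Ds]; the numerator 2 psi Ds - psi^2 Ds'
    # simplifies to 2 (g2+g3) psi + 3 g3 g.
    Ds = _Ds(psi, p)
    num = 2.0 * (p.gamma2 + p.gamma3) * psi + 3.0 * p.gamma3 * p.gamma
    return 1.0 - p.gamma1 * num / (Ds * Ds)


def _classify(psi: float, p: DimensionlessParams) -> SteadyState:
    phi = phi_at_steady_state(psi, p.gamma)
    J = jacobian(State(phi=phi, psi=psi), p)
    eigs = np.linalg.eigvals(J)
    eigs = tuple(sorted((complex(e) for e in eigs), key=lambda z: z.real))
    re = [e.real for e in eigs]
    if abs(max(re)) < EIG_TOL:
        stability = "degenerate"
    elif max(re) < 0:
        stability = "stable"
    elif min(re) < 0 < max(re) and all(abs(e.imag) < EIG_TOL for e in eigs):
        stability = "saddle"
    else:
        stability = "unstable"
    return SteadyState(psi_s=psi, phi_s=phi, eigenvalues=eigs, stability=stability)


def steady_states(p: DimensionlessParams,
                  residual_tol: float = RESIDUAL_TOL) -> list[SteadyState]:
    """All steady states with psi_s > 0, sorted by psi_s.

    Clearing denominators in alpha(psi) = alpha turns the steady-state
    condition into the quartic

        (psi - alpha)(psi^3 + (gamma2+gamma3) psi + gamma3 gamma) = gamma1 psi^3

    whose real positive roots are kept after verifying the (un-cleared)
    residuals of both right-hand sides.
    """
    a, g, g1, g2, g3 = p.alpha, p.gamma, p.gamma1, p.gamma2, p.gamma3
    coeffs = [
        1.0,
        -(a + g1),
        g2 + g3,
        g3 * g - a * (g2 + g3),
        -a * g3 * g,
    ]
    roots = np.roots(coeffs)
    out: list[SteadyState] = []
    seen: list[float] = []
    for r in roots:
        if abs(r.imag) > 1e-9 or r.real <= 0:
            continue
        psi = float(r.real)
        # polish with Newton on the scalar equation alpha(psi) - alpha = 0
        for _ in range(3):
            f = alpha_of_psi(psi, p) - a
            df = _dalpha_dpsi(psi, p)
            if df != 0:
                step = f / df
                if abs(step) < 0.5 * psi:
                    psi -= step
        phi = phi_at_steady_state(psi, g)
        dphi, dpsi = rhs_dimensionless(State(phi=phi, psi=psi), p)
        if max(abs(dphi), abs(dpsi)) > residual_tol:
            continue
        if any(math.isclose(psi, s, rel_tol=1e-7, abs_tol=1e-10) for s in seen):
            continue
        seen.append(psi)
        out.append(_classify(psi, p))
    out.sort(key=lambda s: s.psi_s)
    return out


def find_folds(p: DimensionlessParams,
               psi_min: float = 1e-4, psi_max: float = 100.0,
               n_scan: int = 2000) -> list[FoldPoint]:
    """Fold points: roots of d alpha/d psi = 0, refined by bisection.

    Scans a log-spaced psi grid for sign changes of the derivative.  Returns
    an empty list below the cusp (monostable regime); generically two folds
    above it.
    """
    grid = np.geomspace(psi_min, psi_max, n_scan)
    vals = np.array([_dalpha_dpsi(x, p) for x in grid])
    folds: list[FoldPoint] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            psi_f = float(grid[i])
        elif a * b < 0:
            psi_f = brentq(_dalpha_dpsi, grid[i], grid[i + 1], args=(p,),
                           xtol=1e-12, rtol=8.9e-16)
        else:
            continue
        alpha_f = alpha_of_psi(psi_f, p)
        # local max (alpha' goes + -> -) ends the off branch; local min the on branch
        kind = "off_state_end" if a > 0 else "on_state_end"
        folds.append(FoldPoint(psi_fold=float(psi_f), alpha_fold=float(alpha_f),
                               kind=kind))
    return folds


def bifurcation_branch(p: DimensionlessParams,
                       psi_min: float = 1e-3, psi_max: float = 10.0,
                       n: int = 1001) -> BifurcationBranch:
    """The psi-parameterized steady-state branch alpha(psi) with stability.

    A point on the branch is stable iff alpha'(psi) > 0 there (the middle,
    descending segment between the folds is the saddle branch).
    """
    psi_grid = np.geomspace(psi_min, psi_max, n)
    alphas = np.array([alpha_of_psi(x, p) for x in psi_grid])
    stab = ["stable" if _dalpha_dpsi(float(x), p) > 0 else "unstable"
            for x in psi_grid]
    return BifurcationBranch(psi_grid=psi_grid, alpha_values=alphas,
                             stability=stab, folds=find_folds(p))


def _oneway_psi_star(gamma: float, gamma2: float, gamma3: float) -> float:
    # positive root of psi^3 - (gamma2+gamma3) psi - 2 gamma3 gamma = 0
    roots = np.roots([1.0, 0.0, -(gamma2 + gamma3), -2.0 * gamma3 * gamma])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-10 and r.real > 0]
    if not real:
        raise RuntimeError("no positive root for the one-way boundary cubic")
    return max(real)


def oneway_boundary_gamma1(gamma: float, gamma2: float, gamma3: float) -> float:
    """Critical gamma1 above which the switch is one-way (irreversible).

    The boundary is where the on-state fold sits exactly at alpha = 0:
    solving alpha(psi)=0 and alpha'(psi)=0 simultaneously reduces to the
    depressed cubic psi^3 - (gamma2+gamma3) psi - 2 gamma3 gamma = 0, and
    gamma1 = D_s(psi*)/psi* at its positive root.  With gamma3 = 0 this is
    exactly gamma1 = 2 sqrt(gamma2), i.e. gamma1 = 2 for gamma2 = 1.
    """
    if gamma <= 0 or gamma2 <= 0 or gamma3 < 0:
        raise ValueError("gamma, gamma2 must be positive and gamma3 >= 0")
    psi_star = _oneway_psi_star(gamma, gamma2, gamma3)
    Ds = gamma2 + psi_star * psi_star + gamma3 * (psi_star + gamma) / psi_star
    return Ds / psi_star


def cusp_gamma1(gamma: float, gamma2: float, gamma3: float) -> float:
    """gamma1 at which the two folds merge (monostable/bistable boundary).

    For fixed psi the fold condition alpha'(psi)=0 gives
    gamma1 = D_s(psi)^2 / (2 (gamma2+gamma3) psi + 3 gamma3 gamma); folds
    exist exactly for gamma1 above the minimum of this function over psi > 0,
    so the cusp is that minimum (e.g. 8 sqrt(3)/9 at gamma2=1, gamma3=0).
    """
    if gamma <= 0 or gamma2 <= 0 or gamma3 < 0:
        raise ValueError("gamma, gamma2 must be positive and gamma3 >= 0")

    def g1_of_psi(log_psi: float) -> float:
        psi = math.exp(log_psi)
        Ds = gamma2 + psi * psi + gamma3 * (psi + gamma) / psi
        return Ds * Ds / (2.0 * (gamma2 + gamma3) * psi + 3.0 * gamma3 * gamma)

    res = minimize_scalar(g1_of_psi, bounds=(math.log(1e-4), math.log(1e3)),
                          method="bounded",
                          options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError("cusp search did not converge")
    return float(res.fun)
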