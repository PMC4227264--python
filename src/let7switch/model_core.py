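"""Coarse-grained Lin28/let-7 mutual-inhibition model.

The network is reduced to two species: Lin28 protein (which blocks maturation
of the let-7 microRNA) and mature let-7 (which represses Lin28 expression and
additionally promotes its own biogenesis).  In dimensional form

    d[Lin28]/dt = alpha_P - beta_P [Lin28] [let-7] / ([let-7] + kappa_P)
    d[let-7]/dt = alpha_M + Gamma1 [let-7]^2 / (Gamma2 + [let-7]^2
                  + Gamma3 [Lin28]) - beta_M [let-7]

and after rescaling phi = beta_P [Lin28]/alpha_P, psi = beta_M [let-7]/alpha_P,
tau = beta_P t the system depends only on the dimensionless groups

    dphi/dtau = 1 - phi psi / (psi + gamma)
    dpsi/dtau = epsilon (alpha + gamma1 psi^2 / (gamma2 + psi^2 + gamma3 phi)
                - psi)

with alpha = alpha_M/alpha_P, gamma = kappa_P beta_M/alpha_P,
gamma1 = Gamma1/alpha_P, gamma2 = Gamma2 beta_M^2/alpha_P^2,
gamma3 = Gamma3 beta_M^2/(alpha_P beta_P) and epsilon = beta_M/beta_P.

This module holds the parameter/state containers, the two right-hand sides,
the analytic Jacobian, and the invertible dimensional <-> dimensionless maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "State",
    "Scales",
    "rhs_dimensionless",
    "rhs_dimensional",
    "nondimensionalize",
    "dimensionalize",
    "jacobian",
    "half_life_to_rate",
]

LN2 = math.log(2.0)


def half_life_to_rate(half_life_h: float) -> float:
    """First-order rate constant (1/h) from a half-life (h)."""
    if half_life_h <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_h}")
    return LN2 / half_life_h


@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants of the dimensional two-variable model.

    Concentrations are in arbitrary units; time is in hours.
    """

    alpha_M: float  # basal let-7 production (conc / h)
    alpha_P: float  # constitutive Lin28 production (conc / h)
    beta_M: float   # let-7 degradation rate constant (1 / h)
    beta_P: float   # Lin28 degradation rate constant (1 / h)
    kappa_P: float  # let-7 level giving half-maximal Lin28 degradation (conc)
    Gamma1: float   # maximal autocatalytic let-7 production (conc / h)
    Gamma2: float   # Hill saturation constant (conc^2)
    Gamma3: float   # Lin28-inhibition efficiency (conc^2 per Lin28 conc)

    def __post_init__(self) -> None:
        for name in ("alpha_M", "alpha_P", "beta_M", "beta_P",
                     "kappa_P", "Gamma1", "Gamma2", "Gamma3"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless groups (alpha, gamma, gamma1, gamma2, gamma3, epsilon).

    alpha is the basal let-7 production relative to Lin28 production (the
    stimulus); gamma1 the positive-feedback strength; gamma3 the efficiency
    of Lin28 inhibition of let-7 biogenesis; epsilon the ratio of let-7 to
    Lin28 degradation rates (epsilon < 1: the miRNA is the more stable
    species).
    """

    alpha: float
    gamma: float
    gamma1: float
    gamma2: float
    gamma3: float
    epsilon: float

    def __post_init__(self) -> None:
        if not (self.alpha >= 0) or not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        for name in ("gamma", "gamma1", "gamma2", "epsilon"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not (self.gamma3 >= 0) or not math.isfinite(self.gamma3):
            raise ValueError(f"gamma3 must be >= 0, got {self.gamma3}")

    def with_alpha(self, alpha: float) -> "DimensionlessParams":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class State:
    """Dimensionless state: phi (Lin28), psi (mature let-7)."""

    phi: float
    psi: float

    def __post_init__(self) -> None:
        if self.phi < 0 or self.psi < 0:
            raise ValueError(f"state must be non-negative, got {self}")


@dataclass(frozen=True)
class Scales:
    """Characteristic scales recorded so nondimensionalization is invertible.

    conc_scale_lin28 = alpha_P/beta_P, conc_scale_let7 = alpha_P/beta_M,
    time_scale = 1/beta_P.  Only two of the three are independent given
    epsilon; consistency is checked on inversion.
    """

    conc_scale_lin28: float
    conc_scale_let7: float
    time_scale: float

    def __post_init__(self) -> None:
        for name in ("conc_scale_lin28", "conc_scale_let7", "time_scale"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v}")


def rhs_dimensionless(state: State, p: DimensionlessParams) -> tuple[float, float]:
    """Time derivatives (dphi/dtau, dpsi/dtau) of the dimensionless model."""
    phi, psi = state.phi, state.psi
    dphi = 1.0 - phi * psi / (psi + p.gamma)
    denom = p.gamma2 + psi * psi + p.gamma3 * phi
    dpsi = p.epsilon * (p.alpha + p.gamma1 * psi * psi / denom - psi)
    return dphi, dpsi


def rhs_dimensional(lin28: float, let7: float,
                    p: DimensionalParams) -> tuple[float, float]:
    """Time derivatives (d[Lin28]/dt, d[let-7]/dt) of the dimensional model."""
    if lin28 < 0 or let7 < 0:
        raise ValueError("concentrations must be non-negative")
    dlin28 = p.alpha_P - p.beta_P * lin28 * let7 / (let7 + p.kappa_P)
    denom = p.Gamma2 + let7 * let7 + p.Gamma3 * lin28
    dlet7 = p.alpha_M + p.Gamma1 * let7 * let7 / denom - p.beta_M * let7
    return dlin28, dlet7


def nondimensionalize(p: DimensionalParams) -> tuple[DimensionlessParams, Scales]:
    """Map dimensional rate constants to the dimensionless groups.

    Returns the groups together with the Scales needed to invert the map.
    """
    aP, bM, bP = p.alpha_P, p.beta_M, p.beta_P
    dimless = DimensionlessParams(
        alpha=p.alpha_M / aP,
        gamma=p.kappa_P * bM / aP,
        gamma1=p.Gamma1 / aP,
        gamma2=p.Gamma2 * bM * bM / (aP * aP),
        gamma3=p.Gamma3 * bM * bM / (aP * bP),
        epsilon=bM / bP,
    )
    scales = Scales(
        conc_scale_lin28=aP / bP,
        conc_scale_let7=aP / bM,
        time_scale=1.0 / bP,
    )
    return dimless, scales


def dimensionalize(p: DimensionlessParams, s: Scales,
                   rtol: float = 1e-9) -> DimensionalParams:
    """Invert :func:`nondimensionalize` for the given scales.

    Raises ValueError if the scales are mutually inconsistent with epsilon
    (conc_scale_let7 must equal conc_scale_lin28 / epsilon).
    """
    beta_P = 1.0 / s.time_scale
    beta_M = p.epsilon * beta_P
    alpha_P = s.conc_scale_lin28 * beta_P
    expected_let7_scale = alpha_P / beta_M
    if not math.isclose(s.conc_scale_let7, expected_let7_scale, rel_tol=rtol):
        raise ValueError(
            "inconsistent Scales: conc_scale_let7 must equal "
            f"alpha_P/beta_M = {expected_let7_scale!r}, got {s.conc_scale_let7!r}"
        )
    return DimensionalParams(
        alpha_M=p.alpha * alpha_P,
        alpha_P=alpha_P,
        beta_M=beta_M,
        beta_P=beta_P,
        kappa_P=p.gamma * alpha_P / beta_M,
        Gamma1=p.gamma1 * alpha_P,
        Gamma2=p.gamma2 * alpha_P * alpha_P / (beta_M * beta_M),
        Gamma3=p.gamma3 * alpha_P * beta_P / (beta_M * beta_M),
    )


def jacobian(state: State, p: DimensionlessParams) -> np.ndarray:
    """Analytic Jacobian of the dimensionless right-hand side.

    Row/column order is (phi, psi).
    """
    phi, psi = state.phi, state.psi
    g = p.gamma
    D = p.gamma2 + psi * psi + p.gamma3 * phi
    j11 = -psi / (psi + g)
    j12 = -phi * g / ((psi + g) ** 2)
    j21 = -p.epsilon * p.gamma1 * p.gamma3 * psi * psi / (D * D)
    j22 = p.epsilon * (
        2.0 * p.gamma1 * psi * (p.gamma2 + p.gamma3 * phi) / (D * D) - 1.0
    )
    return np.array([[j11, j12], [j21, j22]], dtype=float)
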