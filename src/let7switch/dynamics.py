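"""Deterministic and extrinsic-noise time courses of the Lin28/let-7 switch.

Integration is classical fixed-step fourth-order Runge-Kutta on the
dimensionless system.  Extrinsic noise enters through the stimulus alpha,
held piecewise constant and redrawn i.i.d. from a Gaussian at a fixed
redraw interval (clipped at zero by default, production rates being
non-negative); everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import DimensionlessParams, State
from .equilibria import phi_at_steady_state, steady_states

__all__ = [
    "Trajectory",
    "NoiseSpec",
    "IntegrationError",
    "simulate",
    "simulate_noisy",
    "switch_time",
    "fluctuation_stats",
    "default_initial_state",
    "NOT_REACHED",
]

NOT_REACHED = math.inf


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at step {step}")


@dataclass(frozen=True)
class Trajectory:
    tau: np.ndarray          # time grid, length n+1
    phi: np.ndarray          # Lin28 series
    psi: np.ndarray          # let-7 series
    alpha_trace: np.ndarray  # realized stimulus per step (length n+1; last repeats)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.tau.size
        for name in ("phi", "psi", "alpha_trace"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != {n}")


@dataclass(frozen=True)
class NoiseSpec:
    """Extrinsic stimulus fluctuation: alpha ~ Gaussian(mean, variance).

    The draw is held constant for ``redraw_interval`` time units, then
    redrawn independently.  Negative draws are clipped at zero when
    ``clip_at_zero`` (default), since alpha is a production rate.
    """

    mean: float = 0.2
    variance: float = 0.05
    redraw_interval: float = 0.01
    clip_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")
        if self.redraw_interval <= 0:
            raise ValueError(
                f"redraw_interval must be > 0, got {self.redraw_interval}")


def _integrate(p: DimensionlessParams, phi0: float, psi0: float,
               dt: float, alpha_steps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RK4 with alpha held constant within each step (length of alpha_steps)."""
    g, g1, g2, g3, eps = p.gamma, p.gamma1, p.gamma2, p.gamma3, p.epsilon
    n = alpha_steps.size
    phi_out = np.empty(n + 1)
    psi_out = np.empty(n + 1)
    phi, psi = float(phi0), float(psi0)
    phi_out[0], psi_out[0] = phi, psi
    h = dt
    alphas = alpha_steps.tolist()
    for i in range(n):
        a = alphas[i]
        # k1
        d1f = 1.0 - phi * psi / (psi + g)
        den = g2 + psi * psi + g3 * phi
        d1s = eps * (a + g1 * psi * psi / den - psi)
        # k2
        f2 = phi + 0.5 * h * d1f
        s2 = psi + 0.5 * h * d1s
        d2f = 1.0 - f2 * s2 / (s2 + g)
        den = g2 + s2 * s2 + g3 * f2
        d2s = eps * (a + g1 * s2 * s2 / den - s2)
        # k3
        f3 = phi + 0.5 * h * d2f
        s3 = psi + 0.5 * h * d2s
        d3f = 1.0 - f3 * s3 / (s3 + g)
        den = g2 + s3 * s3 + g3 * f3
        d3s = eps * (a + g1 * s3 * s3 / den - s3)
        # k4
        f4 = phi + h * d3f
        s4 = psi + h * d3s
        d4f = 1.0 - f4 * s4 / (s4 + g)
        den = g2 + s4 * s4 + g3 * f4
        d4s = eps * (a + g1 * s4 * s4 / den - s4)
        phi += h * (d1f + 2.0 * d2f + 2.0 * d3f + d4f) / 6.0
        psi += h * (d1s + 2.0 * d2s + 2.0 * d3s + d4s) / 6.0
        if not (math.isfinite(phi) and math.isfinite(psi)):
            raise IntegrationError(step=i + 1)
        phi_out[i + 1], psi_out[i + 1] = phi, psi
    return phi_out, psi_out


def default_initial_state(p: DimensionlessParams,
                          alpha: float | None = None) -> State:
    """Off-branch steady state at the operating alpha when it exists.

    Falls back to psi = 0.05 with phi on its nullcline when the branch has
    no stable state at that alpha (or alpha is zero with no off state).
    """
    from .equilibria import find_folds

    a = p.alpha if alpha is None else alpha
    stable = sorted((s for s in steady_states(p.with_alpha(a))
                     if s.stability == "stable"), key=lambda s: s.psi_s)
    if len(stable) >= 2:
        return State(phi=stable[0].phi_s, psi=stable[0].psi_s)
    if len(stable) == 1:
        folds = find_folds(p)
        if folds and stable[0].psi_s <= min(f.psi_fold for f in folds):
            # the single state sits on the off branch (below both folds)
            return State(phi=stable[0].phi_s, psi=stable[0].psi_s)
    psi0 = 0.05
    return State(phi=phi_at_steady_state(psi0, p.gamma), psi=psi0)


def simulate(p: DimensionlessParams, init: State, t_end: float,
             dt: float = 0.01) -> Trajectory:
    """Deterministic time course under constant stimulus p.alpha."""
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n = int(round(t_end / dt))
    alpha_steps = np.full(n, p.alpha)
    phi, psi = _integrate(p, init.phi, init.psi, dt, alpha_steps)
    tau = dt * np.arange(n + 1)
    alpha_trace = np.concatenate([alpha_steps, alpha_steps[-1:]])
    meta = {"params": p, "dt": dt, "t_end": t_end, "init": init, "noise": None}
    return Trajectory(tau=tau, phi=phi, psi=psi, alpha_trace=alpha_trace, meta=meta)


def simulate_noisy(p: DimensionlessParams, init: State, t_end: float,
                   dt: float = 0.01, noise: NoiseSpec = NoiseSpec()) -> Trajectory:
    """Time course under a fluctuating stimulus (extrinsic noise).

    alpha is piecewise constant: an i.i.d. Gaussian(mean, variance) draw per
    redraw interval, clipped at zero if requested.  With variance = 0 the
    result is identical to :func:`simulate` at alpha = mean.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n = int(round(t_end / dt))
    rng = np.random.default_rng(noise.seed)
    n_draws = int(math.ceil(n * dt / noise.redraw_interval)) + 1
    draws = noise.mean + math.sqrt(noise.variance) * rng.standard_normal(n_draws)
    if noise.clip_at_zero:
        draws = np.maximum(draws, 0.0)
    step_times = dt * np.arange(n)
    idx = np.minimum((step_times / noise.redraw_interval).astype(int), n_draws - 1)
    alpha_steps = draws[idx]
    phi, psi = _integrate(p, init.phi, init.psi, dt, alpha_steps)
    tau = dt * np.arange(n + 1)
    alpha_trace = np.concatenate([alpha_steps, alpha_steps[-1:]])
    meta = {"params": p, "dt": dt, "t_end": t_end, "init": init, "noise": noise}
    return Trajectory(tau=tau, phi=phi, psi=psi, alpha_trace=alpha_trace, meta=meta)


def switch_time(traj: Trajectory, off_level: float, on_level: float,
                fraction: float = 0.95) -> float:
    """First time psi crosses off + fraction*(on - off); NOT_REACHED if never."""
    if not off_level < on_level:
        raise ValueError("off_level must be smaller than on_level")
    threshold = off_level + fraction * (on_level - off_level)
    hits = np.nonzero(traj.psi >= threshold)[0]
    if hits.size == 0:
        return NOT_REACHED
    return float(traj.tau[hits[0]])


@dataclass(frozen=True)
class FluctuationStats:
    mean: float
    variance: float
    min: float
    max: float


def fluctuation_stats(traj: Trajectory, burn_in: float) -> FluctuationStats:
    """Moments of psi over the post-burn-in segment of a trajectory."""
    if burn_in >= traj.tau[-1]:
        raise ValueError(
            f"burn_in {burn_in} must be smaller than t_end {traj.tau[-1]}")
    seg = traj.psi[traj.tau >= burn_in]
    return FluctuationStats(mean=float(np.mean(seg)),
                            variance=float(np.var(seg)),
                            min=float(np.min(seg)),
                            max=float(np.max(seg)))
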