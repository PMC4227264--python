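"""Switch-type classification over parameter grids (phase diagrams).

Three regimes are distinguished, following the fold structure of the
steady-state branch alpha(psi):

* ``monostable`` — no folds (below the cusp), or the whole fold window lies
  outside the physiological stimulus range [0, alpha_max];
* ``bistable``   — two folds with the on-state fold at alpha > 0: switching
  on requires the stimulus to exceed the off-state threshold, and the switch
  shows hysteresis but can be reversed;
* ``one_way``    — two folds with the on-state fold at alpha <= 0: once on,
  the system stays on even at zero stimulus (irreversible switch).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .equilibria import cusp_gamma1, find_folds, steady_states
from .model_core import DimensionlessParams

__all__ = [
    "ALPHA_MAX_DEFAULT",
    "PhaseDiagram",
    "classify_gamma1",
    "classify_point",
    "phase_diagram",
]

# physiological stimulus window: alpha varies in 0 - 0.4
ALPHA_MAX_DEFAULT = 0.4

SWEEPABLE = ("alpha", "gamma", "gamma1", "gamma2", "gamma3")


@dataclass(frozen=True)
class PhaseDiagram:
    x_name: str
    y_name: str
    x_values: np.ndarray
    y_values: np.ndarray
    labels: np.ndarray          # shape (len(y_values), len(x_values)), dtype object
    fixed: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j, y in enumerate(self.y_values):
            for i, x in enumerate(self.x_values):
                rows.append((x, y, self.labels[j, i]))
        return pd.DataFrame(rows, columns=[self.x_name, self.y_name, "label"])

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))


@lru_cache(maxsize=100_000)
def _fold_window(gamma: float, gamma1: float, gamma2: float,
                 gamma3: float) -> tuple[float, float] | None:
    """(alpha_on_fold, alpha_off_fold) of the bistable window, or None.

    alpha is irrelevant to the branch geometry, as is epsilon; both are set
    to arbitrary valid values here.
    """
    p = DimensionlessParams(alpha=0.0, gamma=gamma, gamma1=gamma1,
                            gamma2=gamma2, gamma3=gamma3, epsilon=1.0)
    folds = find_folds(p)
    if not folds:
        return None
    on = [f.alpha_fold for f in folds if f.kind == "on_state_end"]
    off = [f.alpha_fold for f in folds if f.kind == "off_state_end"]
    if not on or not off:
        return None
    return (min(on), max(off))


def classify_gamma1(gamma: float, gamma1: float, gamma2: float, gamma3: float,
                    alpha_max: float = ALPHA_MAX_DEFAULT) -> str:
    """Switch class of the branch geometry at fixed feedback parameters."""
    if alpha_max <= 0:
        raise ValueError(f"alpha_max must be positive, got {alpha_max}")
    window = _fold_window(gamma, gamma1, gamma2, gamma3)
    if window is None:
        return "monostable"
    alpha_on, alpha_off = window
    if min(alpha_on, alpha_off) > alpha_max:
        # fold window entirely above the physiological stimulus range
        return "monostable"
    if alpha_on <= 0.0:
        return "one_way"
    return "bistable"


def classify_point(p: DimensionlessParams) -> str:
    """Branch context of a single (alpha, params) operating point.

    Returns ``bistable_region`` when two stable states coexist at this
    alpha, otherwise ``monostable_on`` / ``monostable_off`` according to
    which side of the fold window the operating alpha lies on (for a
    fold-free branch, according to which side of the cusp psi the single
    state lies on).
    """
    states = steady_states(p)
    n_stable = sum(1 for s in states if s.stability == "stable")
    if n_stable >= 2:
        return "bistable_region"
    stable_psi = [s.psi_s for s in states if s.stability == "stable"]
    if not stable_psi:
        # only attractor candidates are on the boundary psi -> 0
        return "monostable_off"
    psi_top = max(stable_psi)
    geom = DimensionlessParams(alpha=0.0, gamma=p.gamma, gamma1=p.gamma1,
                               gamma2=p.gamma2, gamma3=p.gamma3, epsilon=1.0)
    folds = find_folds(geom)
    if folds:
        # the single stable state sits on the branch segment above or below
        # the fold pair
        psi_on_fold = max(f.psi_fold for f in folds)
        return "monostable_on" if psi_top >= psi_on_fold else "monostable_off"
    # no folds: split the monotone branch at the would-be cusp location
    psi_cusp = _cusp_psi(p.gamma, p.gamma2, p.gamma3)
    return "monostable_on" if psi_top >= psi_cusp else "monostable_off"


@lru_cache(maxsize=10_000)
def _cusp_psi(gamma: float, gamma2: float, gamma3: float) -> float:
    import math

    from scipy.optimize import minimize_scalar

    def g1_of_psi(log_psi: float) -> float:
        psi = math.exp(log_psi)
        Ds = gamma2 + psi * psi + gamma3 * (psi + gamma) / psi
        return Ds * Ds / (2.0 * (gamma2 + gamma3) * psi + 3.0 * gamma3 * gamma)

    res = minimize_scalar(g1_of_psi, bounds=(math.log(1e-4), math.log(1e3)),
                          method="bounded", options={"xatol": 1e-10})
    return math.exp(float(res.x))


def _cell_label(alpha: float, gamma: float, gamma1: float, gamma2: float,
                gamma3: float, alpha_max: float) -> str:
    """Label of one phase-diagram cell.

    When alpha is a swept axis the cell is ``bistable``/``one_way`` only if
    its alpha actually lies inside the fold window; elsewhere the cell is
    monostable at that stimulus.
    """
    window = _fold_window(gamma, gamma1, gamma2, gamma3)
    if window is None:
        return "monostable"
    alpha_on, alpha_off = window
    if alpha_on < alpha < alpha_off:
        return "one_way" if alpha_on <= 0.0 else "bistable"
    return "monostable"


def phase_diagram(x_axis: tuple[str, np.ndarray], y_axis: tuple[str, np.ndarray],
                  fixed: dict, alpha_max: float = ALPHA_MAX_DEFAULT) -> PhaseDiagram:
    """Label a 2-D parameter grid cell by cell.

    ``x_axis`` / ``y_axis`` are (parameter_name, strictly increasing values);
    ``fixed`` supplies every other parameter of (alpha, gamma, gamma1,
    gamma2, gamma3).  When ``alpha`` is not an axis, cells are labeled by the
    fold-window rule relative to [0, alpha_max]; when it is, each cell is
    labeled at its own stimulus value.
    """
    x_name, x_values = x_axis
    y_name, y_values = y_axis
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    for name, vals in ((x_name, x_values), (y_name, y_values)):
        if name not in SWEEPABLE:
            raise ValueError(f"cannot sweep unknown parameter {name!r}")
        if vals.size == 0 or np.any(np.diff(vals) <= 0):
            raise ValueError(f"{name} axis must be non-empty and strictly increasing")
    if x_name == y_name:
        raise ValueError("the two axes must sweep different parameters")
    unknown = set(fixed) - set(SWEEPABLE)
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")

    alpha_swept = "alpha" in (x_name, y_name)
    labels = np.empty((y_values.size, x_values.size), dtype=object)
    for j, y in enumerate(y_values):
        for i, x in enumerate(x_values):
            params = dict(fixed)
            params[x_name] = float(x)
            params[y_name] = float(y)
            if alpha_swept:
                labels[j, i] = _cell_label(
                    params["alpha"], params["gamma"], params["gamma1"],
                    params["gamma2"], params["gamma3"], alpha_max)
            else:
                labels[j, i] = classify_gamma1(
                    params["gamma"], params["gamma1"], params["gamma2"],
                    params["gamma3"], alpha_max=alpha_max)
    return PhaseDiagram(x_name=x_name, y_name=y_name, x_values=x_values,
                        y_values=y_values, labels=labels, fixed=dict(fixed))
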