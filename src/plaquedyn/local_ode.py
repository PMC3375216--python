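"""Mass-action ODE model of local virus-cell dynamics and outcome prediction.

The lattice model's local neighborhood (a cell plus its eight Moore
neighbors, K = 9) is treated as a well-mixed patch obeying the modified
Lotka-Volterra system

    dS/dt = R*S*(1 - (S+I)/K) - D*S - B*S*I/K
    dI/dt = B*S*I/K - A*I

with carrying capacity K.  At D = 0 its equilibria are the infection-free
state (K, 0) and the coexistence state S1 = A*K/B, I1 = R*K*(B-A)/(B*(R+B)),
the latter biologically relevant when the virus basic reproductive ratio
R0 = B/A exceeds one (A < B).  The central prediction: the global outcome of
the *spatial* system is governed by whether these local equilibrium cell
numbers exceed one cell — S1 = 1 is the lower (white-line) boundary of
uncontrolled cell growth and I1 = 1 the upper (black-line) boundary of virus
persistence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ODEParams",
    "Equilibria",
    "Stability",
    "LocalPrediction",
    "rhs",
    "equilibria",
    "integrate",
    "predict_outcome",
]


class Stability(enum.Enum):
    STABLE_NODE = "STABLE_NODE"        # monotonic approach
    STABLE_SPIRAL = "STABLE_SPIRAL"    # damped oscillations
    UNSTABLE = "UNSTABLE"
    N_A = "N_A"


class LocalPrediction(enum.Enum):
    """Three-way outcome call from the local equilibria."""

    TARGET_EXTINCTION_OR_CONTROLLED = "TARGET_EXTINCTION_OR_CONTROLLED"
    COEXISTENCE_PREDICTED = "COEXISTENCE_PREDICTED"
    VIRUS_LOSS_PREDICTED = "VIRUS_LOSS_PREDICTED"


@dataclass(frozen=True)
class ODEParams:
    R: float
    D: float
    B: float
    A: float
    K: float = 9.0

    def __post_init__(self):
        for name in ("R", "D", "B", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K <= 0:
            raise ValueError("K must be > 0")


@dataclass(frozen=True)
class Equilibria:
    S0: float
    I0: float
    S1: float | None
    I1: float | None
    R0: float
    exists_coexistence: bool
    stability: Stability


def rhs(S: float, I: float, p: ODEParams) -> tuple[float, float]:
    """(dS/dt, dI/dt) at (S, I)."""
    dS = p.R * S * (1.0 - (S + I) / p.K) - p.D * S - p.B * S * I / p.K
    dI = p.B * S * I / p.K - p.A * I
    return dS, dI


def _jacobian(S: float, I: float, p: ODEParams) -> np.ndarray:
    K = p.K
    return np.array([
        [p.R * (1.0 - (2 * S + I) / K) - p.D - p.B * I / K,
         -p.R * S / K - p.B * S / K],
        [p.B * I / K, p.B * S / K - p.A],
    ])


def equilibria(p: ODEParams) -> Equilibria:
    """Closed-form equilibria, R0 and coexistence stability (D = 0 forms).

    The printed closed forms hold at D = 0, which is the regime used for
    every phase diagram; a nonzero D shifts the equilibria and is handled
    numerically elsewhere.
    """
    R0 = np.inf if p.A == 0 else p.B / p.A
    exists = p.B > 0 and p.A < p.B
    if not exists:
        return Equilibria(S0=p.K, I0=0.0, S1=None, I1=None, R0=R0,
                          exists_coexistence=False, stability=Stability.N_A)
    S1 = p.A * p.K / p.B
    I1 = p.R * p.K * (p.B - p.A) / (p.B * (p.R + p.B))
    J = _jacobian(S1, I1, p)
    eig = np.linalg.eigvals(J)
    if np.all(eig.real < 0):
        stab = (Stability.STABLE_SPIRAL if np.any(np.abs(eig.imag) > 1e-12)
                else Stability.STABLE_NODE)
    else:
        stab = Stability.UNSTABLE
    return Equilibria(S0=p.K, I0=0.0, S1=S1, I1=I1, R0=R0,
                      exists_coexistence=True, stability=stab)


def integrate(p: ODEParams, S0: float, I0: float, t_grid: np.ndarray):
    """Numerical trajectory of the local ODE on ``t_grid``.

    Adaptive Runge-Kutta with tight tolerances; tiny negative excursions
    within solver tolerance are clipped to zero.
    """
    if S0 < 0 or I0 < 0:
        raise ValueError("initial conditions must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)

    def f(t, y):
        return rhs(y[0], y[1], p)

    sol = solve_ivp(f, (t_grid[0], t_grid[-1]), [S0, I0], t_eval=t_grid,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    return t_grid, y[0], y[1]


def predict_outcome(p: ODEParams) -> dict:
    """Local-theory outcome call with the raw equilibrium values.

    Virus loss when the virus cannot invade (A >= B) or invades but its
    local equilibrium is below one infected cell; target-cell extinction or
    controlled low-level persistence when the local uninfected equilibrium
    is below one cell; coexistence (uncontrolled cell growth with virus
    persistence) when both local equilibria exceed one.
    """
    eq = equilibria(p)
    if not eq.exists_coexistence:
        pred = LocalPrediction.VIRUS_LOSS_PREDICTED
    elif eq.S1 < 1.0:
        pred = LocalPrediction.TARGET_EXTINCTION_OR_CONTROLLED
    elif eq.I1 < 1.0:
        pred = LocalPrediction.VIRUS_LOSS_PREDICTED
    else:
        pred = LocalPrediction.COEXISTENCE_PREDICTED
    return {
        "prediction": pred,
        "S1": eq.S1,
        "I1": eq.I1,
        "R0": eq.R0,
        "stability": eq.stability,
    }
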