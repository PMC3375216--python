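"""Reaction-diffusion front speeds for the metapopulation chain.

In the continuum limit the patch chain obeys Fisher-KPP-type equations
whose invasion fronts are pulled: their speed is fixed by the linearized
dynamics at the leading edge, v = 2*sqrt(D*growth rate).  Migration at rate
m/2 per neighbor over spacing h gives diffusion coefficient D = m*h**2/2.
The target-cell wave advances into empty habitat at v_S = 2*sqrt(D_S*r);
the infection wave advances into a medium holding S_front target cells per
patch at v_I = 2*sqrt(D_I*(beta*S_front/k - a)) (zero when the argument is
negative).  Setting v_S = v_I yields the co-moving front density
H = k*(a + r*D_S/D_I)/beta — the target-cell density at the front once the
infection wave has caught the cell wave.  H < 1 cell marks the side of
parameter space where the virus destroys the cell wave outright
(virus-mediated extinction, regime MA); H > 1 the side where the two waves
travel together to the boundary (regime MB).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metapop import MetapopParams

__all__ = [
    "WaveEstimates",
    "diffusion_from_migration",
    "front_speeds",
    "co_moving_density",
    "measure_front_speed",
    "FrontSpeedMeasurement",
]


@dataclass(frozen=True)
class WaveEstimates:
    v_S: float
    v_I: float
    H: float | None
    D_S: float
    D_I: float


def diffusion_from_migration(m: float, h: float) -> float:
    """Diffusion coefficient of hopping at rate m/2 to each neighbor over
    spacing h (continuum limit of the symmetric random walk): D = m*h**2/2.
    """
    if m < 0 or h < 0:
        raise ValueError("m and h must be >= 0")
    return m * h * h / 2.0


def front_speeds(p: MetapopParams, S_front: float | None = None,
                 ) -> WaveEstimates:
    """Linear-spreading (pulled-front) speed estimates.

    ``S_front`` is the target-cell density per patch of the medium the
    infection wave advances into (default: carrying capacity k).  v_I is
    monotone increasing in S_front and vanishes at S_front = a*k/beta, the
    local coexistence equilibrium — the infection cannot advance into its
    own equilibrium wake.
    """
    if S_front is None:
        S_front = p.k
    if not (0 <= S_front <= p.k):
        raise ValueError("S_front must lie in [0, k]")
    D_S = diffusion_from_migration(p.m_S, p.h)
    D_I = diffusion_from_migration(p.m_I, p.h)
    v_S = 2.0 * np.sqrt(D_S * p.r)
    growth_I = p.beta * S_front / p.k - p.a
    v_I = 2.0 * np.sqrt(D_I * growth_I) if growth_I > 0 else 0.0
    H = None
    if p.beta > 0 and D_I > 0:
        H = p.k * (p.a + p.r * D_S / D_I) / p.beta
    return WaveEstimates(v_S=float(v_S), v_I=float(v_I), H=H,
                         D_S=D_S, D_I=D_I)


def co_moving_density(p: MetapopParams) -> tuple[float, bool]:
    """Target-cell density H of the co-moving front (root of v_S = v_I).

    Returns (H, H < 1); the H = 1 locus is the green line separating
    virus-mediated (MA) from boundary-mediated (MB) extinction.
    """
    if p.beta <= 0:
        raise ValueError("co-moving density requires beta > 0")
    D_S = diffusion_from_migration(p.m_S, p.h)
    D_I = diffusion_from_migration(p.m_I, p.h)
    if D_I <= 0:
        raise ValueError("co-moving density requires m_I > 0")
    H = p.k * (p.a + p.r * D_S / D_I) / p.beta
    return float(H), bool(H < 1.0)


@dataclass
class FrontSpeedMeasurement:
    speed: float | None
    r_squared: float | None
    positions: np.ndarray
    times: np.ndarray
    flagged: bool
    note: str = ""


def front_position(profile: np.ndarray, level: float,
                   h: float = 1.0) -> float | None:
    """Outermost (rightmost) position where the population reaches
    ``level``, linearly interpolated between patches; None if nowhere."""
    profile = np.asarray(profile, dtype=float)
    above = np.nonzero(profile >= level)[0]
    if above.size == 0:
        return None
    i = above[-1]
    if i == len(profile) - 1:
        return float(i * h)
    # interpolate toward the first sub-level patch to the right
    p0, p1 = profile[i], profile[i + 1]
    frac = (p0 - level) / (p0 - p1) if p0 > p1 else 0.0
    return float((i + frac) * h)


def measure_front_speed(profiles: np.ndarray, times: np.ndarray,
                        k: float, h: float = 1.0,
                        level_frac: float = 0.5) -> FrontSpeedMeasurement:
    """Empirical front speed from patch profiles over time.

    The front is the outermost patch where the population is at least
    ``level_frac * k`` (linear interpolation); the speed is the
    least-squares slope of position against time.  A non-monotone or
    undetectable front is flagged and no speed is reported.
    """
    profiles = np.asarray(profiles, dtype=float)
    times = np.asarray(times, dtype=float)
    if profiles.shape[0] < 3:
        raise ValueError("need >= 3 profile snapshots")
    level = level_frac * k
    pos, ts = [], []
    for prof, t in zip(profiles, times):
        x = front_position(prof, level, h=h)
        if x is not None:
            pos.append(x)
            ts.append(t)
    pos = np.asarray(pos)
    ts = np.asarray(ts)
    if len(pos) < 3:
        return FrontSpeedMeasurement(None, None, pos, ts, True,
                                     "front undetectable")
    if np.any(np.diff(pos) < -2.0 * h):
        return FrontSpeedMeasurement(None, None, pos, ts, True,
                                     "front position not monotone")
    if np.ptp(ts) == 0:
        return FrontSpeedMeasurement(None, None, pos, ts, True,
                                     "degenerate time span")
    coef = np.polyfit(ts, pos, 1)
    pred = np.polyval(coef, ts)
    ss_res = float(np.sum((pos - pred) ** 2))
    ss_tot = float(np.sum((pos - pos.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FrontSpeedMeasurement(float(coef[0]), float(r2), pos, ts, False)


def h_by_bisection(p: MetapopParams, tol: float = 1e-12) -> float:
    """Numerical root of v_S(S_front) = v_I(S_front) by bisection — the
    independent cross-check of the closed-form co-moving density."""
    from scipy.optimize import brentq

    def gap(s):
        est = front_speeds(p, S_front=s)
        return est.v_I - est.v_S

    lo, hi = 0.0, p.k
    if gap(hi) <= 0:
        raise ValueError("I-wave never faster than S-wave: no crossing in "
                         "[0, k]")
    return float(brentq(gap, lo, hi, xtol=tol))
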