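"""Monte-Carlo phase diagrams over parameter space, with analytic overlays.

Outcomes of the lattice or metapopulation simulator are tallied on a grid
of parameter ratios — log10(R/B) against log10(A/B) (lattice) or
log10(r/beta) against log10(a/beta) (metapopulation) — with the reference
transmission rate fixed; at D = 0 every analytic locus depends only on
these ratios.  Overlay curves: the white line S1 = 1 (local uninfected
equilibrium of one cell), the black line I1 = 1, the numerically determined
yellow invasion threshold, and (metapopulation) the green co-moving-density
line H = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice, metapop, patterns
from .core import OutcomeLabel, derive_seed

__all__ = [
    "ScanConfig",
    "PhaseDiagram",
    "scan",
    "analytic_lines",
    "invasion_line",
    "lattice_params_from_ratios",
    "metapop_params_from_ratios",
]

LATTICE = "LATTICE"
METAPOP = "METAPOP"


@dataclass(frozen=True)
class ScanConfig:
    model: str = LATTICE
    x_range: tuple[float, float] = (-4.0, 4.0)   # log10(R/B) or log10(r/beta)
    y_range: tuple[float, float] = (-4.0, 4.0)   # log10(A/B) or log10(a/beta)
    resolution: int = 12
    replicates: int = 10
    B_ref: float = 0.5           # lattice reference transmission weight
    beta_ref: float = 1.0        # metapop reference infection rate
    grid_N: int = 30
    max_steps: int = 4000
    metapop_n: int = 51
    metapop_k: float = 100.0
    metapop_m: float = 1.0
    metapop_t_max: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for lo, hi in (self.x_range, self.y_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("axis ranges must be finite and increasing")


@dataclass
class PhaseDiagram:
    x: np.ndarray
    y: np.ndarray
    tallies: dict                 # (i, j) -> {label_name: count}
    majority: np.ndarray          # (res, res) object array of label names
    lines: dict = field(default_factory=dict)
    config: ScanConfig | None = None


def lattice_params_from_ratios(log_rb: float, log_ab: float,
                               cfg: ScanConfig) -> lattice.LatticeParams:
    B = cfg.B_ref
    return lattice.LatticeParams(R=B * 10.0 ** log_rb, D=0.0, B=B,
                                 A=B * 10.0 ** log_ab, N=cfg.grid_N,
                                 max_steps=cfg.max_steps)


def metapop_params_from_ratios(log_rb: float, log_ab: float,
                               cfg: ScanConfig) -> metapop.MetapopParams:
    beta = cfg.beta_ref
    return metapop.MetapopParams(
        r=beta * 10.0 ** log_rb, beta=beta, a=beta * 10.0 ** log_ab,
        d=0.0, k=cfg.metapop_k, m_S=cfg.metapop_m, m_I=cfg.metapop_m,
        n=cfg.metapop_n, t_max=cfg.metapop_t_max)


_LATTICE_INIT = lattice.InitCondition(scheme=lattice.NESTED_SQUARES,
                                      infected_side=5, susceptible_side=13)


def simulate_point_lattice(log_rb: float, log_ab: float, cfg: ScanConfig,
                           seed: int) -> OutcomeLabel:
    p = lattice_params_from_ratios(log_rb, log_ab, cfg)
    p = lattice.LatticeParams(R=p.R, D=p.D, B=p.B, A=p.A, N=p.N,
                              max_steps=p.max_steps, seed=seed)
    res = lattice.run(p, _LATTICE_INIT, record_every=max(1, cfg.max_steps))
    return patterns.classify_outcome(res)


def simulate_point_metapop(log_rb: float, log_ab: float, cfg: ScanConfig,
                           seed: int) -> metapop.MetapopOutcome:
    p = metapop_params_from_ratios(log_rb, log_ab, cfg)
    p = metapop.MetapopParams(r=p.r, beta=p.beta, a=p.a, d=p.d, k=p.k,
                              m_S=p.m_S, m_I=p.m_I, n=p.n, h=p.h,
                              t_max=p.t_max, seed=seed)
    s0 = metapop.init_metapop(p, infected_mid=30, susceptible_mid=70,
                              flank_patches=5)
    res = metapop.simulate(p, s0, n_record=51,
                           snapshot_times=np.array([p.t_max]))
    return metapop.classify_metapop_outcome(res)


def scan(cfg: ScanConfig) -> PhaseDiagram:
    """Tally simulated outcomes on the configured ratio grid.

    Deterministic for a fixed ``cfg.seed``: every replicate seed derives
    from (seed, i, j, replicate).
    """
    xs = np.linspace(*cfg.x_range, cfg.resolution)
    ys = np.linspace(*cfg.y_range, cfg.resolution)
    simulate_point = (simulate_point_lattice if cfg.model == LATTICE
                      else simulate_point_metapop)
    tallies: dict = {}
    majority = np.empty((cfg.resolution, cfg.resolution), dtype=object)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            counts: dict = {}
            for rep in range(cfg.replicates):
                seed = derive_seed(cfg.seed, i, j, rep)
                label = simulate_point(x, y, cfg, seed).value
                counts[label] = counts.get(label, 0) + 1
            tallies[(i, j)] = counts
            majority[i, j] = max(sorted(counts), key=counts.get)
    diagram = PhaseDiagram(x=xs, y=ys, tallies=tallies, majority=majority,
                           config=cfg)
    K = 9.0 if cfg.model == LATTICE else cfg.metapop_k
    diagram.lines = analytic_lines(K, xs, model=cfg.model, cfg=cfg)
    return diagram


def analytic_lines(K: float, xs: np.ndarray, model: str = LATTICE,
                   cfg: ScanConfig | None = None) -> dict:
    """Analytic overlay loci in the (log10 R/B, log10 A/B) axes.

    White: S1 = 1, i.e. A/B = 1/K — horizontal at log10(A/B) = -log10(K).
    Black: I1 = 1, i.e. K*x*(1-y)/(1+x) = 1 with x = R/B, y = A/B, so
    y = 1 - (1+x)/(K*x) (only where positive).  Green (metapopulation,
    D_S = D_I): H = 1, i.e. k*(y+x) = 1, so y = 1/k - x.
    """
    xs = np.asarray(xs, dtype=float)
    white = np.full_like(xs, -np.log10(K))
    x_lin = 10.0 ** xs
    y_black = 1.0 - (1.0 + x_lin) / (K * x_lin)
    black = np.where(y_black > 0, np.log10(np.maximum(y_black, 1e-300)),
                     np.nan)
    lines = {"white_S1_eq_1": np.column_stack([xs, white]),
             "black_I1_eq_1": np.column_stack([xs, black])}
    if model == METAPOP:
        y_green = 1.0 / K - x_lin
        green = np.where(y_green > 0,
                         np.log10(np.maximum(y_green, 1e-300)), np.nan)
        lines["green_H_eq_1"] = np.column_stack([xs, green])
    return lines


def invasion_frequency(log_rb: float, log_ab: float, cfg: ScanConfig,
                       gamma: float = 4.0) -> float:
    """Fraction of replicates in which the virus invades (its count reaches
    gamma times the inoculum)."""
    th = patterns.PatternThresholds(invasion_gamma=gamma)
    hits = 0
    for rep in range(cfg.replicates):
        seed = derive_seed(cfg.seed, 0x1A7, int(round(1e6 * log_rb)),
                           int(round(1e6 * log_ab)), rep)
        p = lattice_params_from_ratios(log_rb, log_ab, cfg)
        p = lattice.LatticeParams(R=p.R, D=p.D, B=p.B, A=p.A, N=p.N,
                                  max_steps=p.max_steps, seed=seed)
        res = lattice.run(p, _LATTICE_INIT,
                          record_every=max(1, cfg.max_steps))
        I0 = max(int(res.series.I[0]), 1)
        if res.max_I >= th.invasion_gamma * I0:
            hits += 1
    return hits / cfg.replicates


def invasion_line(cfg: ScanConfig, p_inv: float = 0.05,
                  gamma: float = 4.0, bisections: int = 8,
                  y_bracket: tuple[float, float] = (-3.0, 1.5),
                  ) -> np.ndarray:
    """Numerically determined invasion threshold (the yellow line).

    For each log10(R/B) value, bisects along log10(A/B) for the smallest
    ratio at which the invasion frequency drops below ``p_inv``.  Points
    where the bracket does not straddle the threshold are skipped (NaN).
    """
    if cfg.replicates < 20:
        raise ValueError("invasion line needs >= 20 replicates per probe")
    xs = np.linspace(*cfg.x_range, cfg.resolution)
    out = np.full((len(xs), 2), np.nan)
    for idx, x in enumerate(xs):
        lo, hi = y_bracket
        f_lo = invasion_frequency(x, lo, cfg, gamma)
        f_hi = invasion_frequency(x, hi, cfg, gamma)
        out[idx, 0] = x
        if not (f_lo >= p_inv > f_hi):
            continue  # non-bracketing: skip with NaN
        for _ in range(bisections):
            mid = 0.5 * (lo + hi)
            if invasion_frequency(x, mid, cfg, gamma) >= p_inv:
                lo = mid
            else:
                hi = mid
        out[idx, 1] = 0.5 * (lo + hi)
    return out
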