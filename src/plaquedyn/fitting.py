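"""Least-squares fitting of the lattice simulator to observed plaque counts.

Observed infected-cell counts come from fluorescence-area measurements: the
mean fluorescent area of a plaque divided by the mean area of a single
infected cell gives the cell count, with the replicate spread of the area
measurements propagated into the error bars.  The simulator's averaged
infected-cell trajectory (mean over many replicate runs with fixed
per-replicate seeds — common random numbers, so the stochastic objective is
smooth and repeatable) is fitted to such a series by derivative-free
least squares over log-parameters.

The objective is typically shallow: different (R, B, A) combinations can
give similarly good fits, so the fitter runs from multiple starts and
raises a non-identifiability flag when distinct optima tie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import lattice
from .core import PopulationTimeSeries, derive_seed

__all__ = [
    "FitConfig",
    "FitResult",
    "area_to_count",
    "predicted_series",
    "fit",
]


def area_to_count(plaque_area: float, cell_area: float,
                  replicates: list[float] | None = None,
                  ) -> tuple[float, float | None]:
    """Convert a fluorescence area to an infected-cell count.

    count = mean plaque area / mean single-cell area.  When replicate area
    measurements are given, their spread propagates linearly into the count
    standard deviation (sample sd of the replicate-wise counts).  The
    result is invariant under a change of pixel units applied to both
    areas.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be > 0")
    if replicates:
        reps = np.asarray(replicates, dtype=float)
        counts = reps / cell_area
        return float(counts.mean()), float(counts.std(ddof=1))
    return float(plaque_area / cell_area), None


@dataclass(frozen=True)
class FitConfig:
    """Settings of the simulator-based least-squares fit.

    Free parameters default to (R, B, A) with D fixed at 0.  The time-scale
    factor ``steps_per_day`` maps simulation steps to experimental days; it
    is a free fit parameter when None (its mapping is not identifiable a
    priori) and pinned otherwise.  ``replicates`` simulator runs are
    averaged per objective evaluation with seeds derived once from ``seed``
    (common random numbers).
    """

    free_params: tuple[str, ...] = ("R", "B", "A")
    fixed: dict = field(default_factory=lambda: {"D": 0.0})
    replicates: int = 100
    steps_per_day: float | None = None
    grid_N: int = 100
    infected_side: int = 3
    starts: tuple[dict, ...] = (
        {"R": 0.2, "B": 0.4, "A": 0.05},
        {"R": 0.1, "B": 0.6, "A": 0.2},
    )
    max_iter: int = 200
    xatol: float = 0.02
    fatol_rel: float = 1e-6
    rss_tie_frac: float = 0.05
    param_tie_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class FitResult:
    params: dict
    rss: float
    predicted_mean: np.ndarray
    predicted_sd: np.ndarray
    days: np.ndarray
    converged: bool
    non_identifiable: bool
    flags: list = field(default_factory=list)
    starts_results: list = field(default_factory=list)
    steps_per_day: float | None = None


def predicted_series(params: dict, days: np.ndarray, cfg: FitConfig,
                     steps_per_day: float | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sd of the simulated infected-cell count at the given days.

    Runs ``cfg.replicates`` lattice simulations with per-replicate seeds
    derived from ``cfg.seed`` and maps steps to days linearly, with linear
    interpolation onto the observed days.  Runs that terminate early (virus
    extinct) contribute their absorbing count.
    """
    days = np.asarray(days, dtype=float)
    spd = steps_per_day if steps_per_day is not None else cfg.steps_per_day
    if spd is None:
        raise ValueError("steps_per_day must be resolved before simulating")
    max_steps = max(int(math.ceil(days.max() * spd)), 1)
    init = lattice.InitCondition(scheme=lattice.CENTER_SQUARE_IN_FULL,
                                 infected_side=cfg.infected_side)
    n_steps = max_steps + 1
    all_I = np.zeros((cfg.replicates, n_steps))
    merged = dict(cfg.fixed)
    merged.update(params)
    for rep in range(cfg.replicates):
        p = lattice.LatticeParams(
            R=merged.get("R", 0.0), D=merged.get("D", 0.0),
            B=merged.get("B", 0.0), A=merged.get("A", 0.0),
            N=cfg.grid_N, max_steps=max_steps,
            seed=derive_seed(cfg.seed, 0xF17, rep))
        res = lattice.run(p, init, record_every=max_steps)
        I = res.series.I
        all_I[rep, :len(I)] = I
        if len(I) < n_steps:  # absorbing tail after extinction
            all_I[rep, len(I):] = I[-1]
    steps = np.arange(n_steps, dtype=float)
    mean_steps = all_I.mean(axis=0)
    sd_steps = all_I.std(axis=0, ddof=0) if cfg.replicates > 1 else \
        np.zeros(n_steps)
    mean = np.interp(days * spd, steps, mean_steps)
    sd = np.interp(days * spd, steps, sd_steps)
    return mean, sd


def _objective(observed: PopulationTimeSeries, params: dict,
               cfg: FitConfig, spd: float) -> float:
    mean, _ = predicted_series(params, observed.t, cfg, steps_per_day=spd)
    return float(np.sum((observed.I - mean) ** 2))


def fit(observed: PopulationTimeSeries, cfg: FitConfig) -> FitResult:
    """Least-squares fit of the simulator to an observed count series.

    Nelder-Mead over log10 of the free parameters (and of the time-scale
    factor when it is free), one run per configured start.  Residuals are
    plain unweighted least squares.  Non-identifiability is flagged when
    several starts reach within ``rss_tie_frac`` of the best RSS with
    parameter sets differing by more than ``param_tie_frac``.
    """
    if len(observed) < 4:
        raise ValueError("need >= 4 observed points")
    free = list(cfg.free_params)
    fit_spd = cfg.steps_per_day is None

    def unpack(x):
        vals = {n: 10.0 ** v for n, v in zip(free, x[:len(free)])}
        spd = 10.0 ** x[len(free)] if fit_spd else cfg.steps_per_day
        return vals, spd

    runs = []
    for start in cfg.starts:
        x0 = [np.log10(max(start.get(n, 0.1), 1e-8)) for n in free]
        if fit_spd:
            x0.append(np.log10(start.get("steps_per_day", 2.0)))

        def obj(x):
            vals, spd = unpack(x)
            return _objective(observed, vals, cfg, spd)

        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"maxiter": cfg.max_iter,
                                "xatol": cfg.xatol,
                                "fatol": cfg.fatol_rel
                                * max(float(np.sum(observed.I ** 2)), 1.0)})
        vals, spd = unpack(res.x)
        runs.append({"params": vals, "steps_per_day": spd,
                     "rss": float(res.fun), "converged": bool(res.success),
                     "n_eval": int(res.nfev)})

    best = min(runs, key=lambda r: r["rss"])
    mean, sd = predicted_series(best["params"], observed.t, cfg,
                                steps_per_day=best["steps_per_day"])
    # Monte-Carlo noise floor of the objective: two independent
    # replicate-averaged curves differ by ~2*sum(sd^2)/replicates in RSS,
    # so RSS gaps below this scale carry no information
    noise_floor = 2.0 * float(np.sum(sd ** 2)) / cfg.replicates
    flags = []
    non_ident = False
    for other in runs:
        if other is best:
            continue
        if other["rss"] <= ((1.0 + cfg.rss_tie_frac)
                            * max(best["rss"], 1e-12) + noise_floor):
            rel = [abs(other["params"][n] - best["params"][n])
                   / max(best["params"][n], 1e-12) for n in free]
            if max(rel) > cfg.param_tie_frac:
                non_ident = True
                flags.append("non-identifiable: distinct parameter sets "
                             "with near-equal RSS")
                break
    if not best["converged"]:
        flags.append("optimizer did not converge within iteration budget")
    if np.all(observed.I == 0):
        flags.append("degenerate data: observed counts all zero")
    return FitResult(
        params=dict(best["params"]), rss=best["rss"], predicted_mean=mean,
        predicted_sd=sd, days=observed.t, converged=best["converged"],
        non_identifiable=non_ident, flags=flags, starts_results=runs,
        steps_per_day=best["steps_per_day"],
    )
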