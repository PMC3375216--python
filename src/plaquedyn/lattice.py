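"""Stochastic agent-based model of virus spread on a 2D grid.

Each spot of an ``N x N`` grid is empty, holds an uninfected (susceptible)
target cell, or holds an infected cell.  One time step samples the grid
``N**2`` times with replacement; a sampled susceptible cell dies with
probability ``D/L`` or divides with probability ``R/L`` into a uniformly
chosen Moore neighbor (success only if that spot is inside the grid and
empty); a sampled infected cell dies with probability ``A/L`` or attempts to
transmit the virus with probability ``B/L`` to a uniformly chosen Moore
neighbor (success only onto a susceptible cell; the source survives
transmission).  ``L = max(1, R + D, A + B)`` normalizes the weights into
probabilities while preserving every rate ratio, which is what the phase
diagrams depend on.  Updates are asynchronous on a single evolving grid;
boundaries are hard walls (an off-grid destination silently fails, so edge
cells are effectively slower).

Infected cells never divide: adenovirus infection locks the cell cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import (EMPTY, INFECTED, SUSCEPTIBLE, PopulationTimeSeries,
                   RunResult, TerminationReason, derive_seed)

__all__ = [
    "LatticeParams",
    "LatticeState",
    "InitCondition",
    "init_lattice",
    "step",
    "run",
]


@dataclass(frozen=True)
class LatticeParams:
    """Event weights and geometry of the lattice model.

    R, D: division and death weights of uninfected cells; B, A: transmission
    and death weights of infected cells (all per sampling event,
    dimensionless); N: grid side length in spots.
    """

    R: float
    D: float
    B: float
    A: float
    N: int = 300
    max_steps: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("R", "D", "B", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")

    @property
    def Lambda(self) -> float:
        """Normalization constant: probabilities are weights divided by this."""
        return max(1.0, self.R + self.D, self.A + self.B)


@dataclass
class LatticeState:
    grid: np.ndarray
    t: int = 0
    boundary_contacted: bool = False

    def counts(self) -> tuple[int, int, int]:
        """(n_empty, n_S, n_I); they always sum to N**2."""
        n_s = int(np.count_nonzero(self.grid == SUSCEPTIBLE))
        n_i = int(np.count_nonzero(self.grid == INFECTED))
        return self.grid.size - n_s - n_i, n_s, n_i


CENTER_SQUARE_IN_FULL = "CENTER_SQUARE_IN_FULL"
NESTED_SQUARES = "NESTED_SQUARES"
CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class InitCondition:
    """Initial grid layout.

    ``CENTER_SQUARE_IN_FULL``: grid full of susceptible cells with a centered
    ``infected_side**2`` square of infected cells (initial-growth setting).
    ``NESTED_SQUARES``: empty grid holding a centered ``susceptible_side**2``
    square of susceptible cells whose centered ``infected_side**2`` core is
    infected (long-run outcome setting).  When grid and square parities
    differ the square shifts one spot toward the origin.
    """

    scheme: str = CENTER_SQUARE_IN_FULL
    infected_side: int = 30
    susceptible_side: int = 0
    custom_grid: np.ndarray | None = None


def _centered_slice(N: int, side: int) -> slice:
    lo = (N - side) // 2
    return slice(lo, lo + side)


def init_lattice(params: LatticeParams, init: InitCondition) -> LatticeState:
    """Build the t=0 state for the given initial-condition scheme."""
    N = params.N
    if init.scheme == CUSTOM:
        if init.custom_grid is None:
            raise ValueError("CUSTOM scheme requires custom_grid")
        grid = np.asarray(init.custom_grid, dtype=np.int8).copy()
        if grid.shape != (N, N):
            raise ValueError("custom_grid shape must be (N, N)")
    elif init.scheme == CENTER_SQUARE_IN_FULL:
        if init.infected_side > N:
            raise ValueError("infected_side exceeds grid size")
        grid = np.full((N, N), SUSCEPTIBLE, dtype=np.int8)
        s = _centered_slice(N, init.infected_side)
        grid[s, s] = INFECTED
    elif init.scheme == NESTED_SQUARES:
        if init.infected_side > init.susceptible_side:
            raise ValueError("infected_side exceeds susceptible_side")
        if init.susceptible_side > N:
            raise ValueError("susceptible_side exceeds grid size")
        grid = np.full((N, N), EMPTY, dtype=np.int8)
        s = _centered_slice(N, init.susceptible_side)
        grid[s, s] = SUSCEPTIBLE
        s = _centered_slice(N, init.infected_side)
        grid[s, s] = INFECTED
    else:
        raise ValueError(f"unknown scheme {init.scheme!r}")
    state = LatticeState(grid=grid, t=0)
    state.boundary_contacted = _touches_boundary(grid)
    return state


def _touches_boundary(grid: np.ndarray) -> bool:
    return bool(grid[0, :].any() or grid[-1, :].any()
                or grid[:, 0].any() or grid[:, -1].any())


# Moore neighborhood offsets, fixed order (row, col)
_OFFS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@njit(cache=True)
def _step_kernel(grid, d_p, r_p, a_p, b_p, n_s, n_i, seed, offs):  # pragma: no cover
    np.random.seed(seed)
    n = grid.shape[0]
    for _ in range(n * n):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        s = grid[i, j]
        if s == 0:
            continue
        u = np.random.random()
        if s == 1:
            if u < d_p:
                grid[i, j] = 0
                n_s -= 1
            elif u < d_p + r_p:
                k = np.random.randint(0, 8)
                ni = i + offs[k, 0]
                nj = j + offs[k, 1]
                if 0 <= ni < n and 0 <= nj < n and grid[ni, nj] == 0:
                    grid[ni, nj] = 1
                    n_s += 1
        else:
            if u < a_p:
                grid[i, j] = 0
                n_i -= 1
            elif u < a_p + b_p:
                k = np.random.randint(0, 8)
                ni = i + offs[k, 0]
                nj = j + offs[k, 1]
                if 0 <= ni < n and 0 <= nj < n and grid[ni, nj] == 1:
                    grid[ni, nj] = 2
                    n_s -= 1
                    n_i += 1
    return n_s, n_i


def step(state: LatticeState, params: LatticeParams,
         rng_seed: int | None = None) -> LatticeState:
    """Advance the lattice by one time step (N**2 samplings), in place.

    ``rng_seed`` fixes the sampling stream of this step; when omitted it is
    derived from ``params.seed`` and the current step index, so repeated runs
    with identical parameters are bit-identical.
    """
    if rng_seed is None:
        rng_seed = derive_seed(params.seed, state.t)
    lam = params.Lambda
    _, n_s, n_i = state.counts()
    n_s, n_i = _step_kernel(
        state.grid,
        params.D / lam, params.R / lam, params.A / lam, params.B / lam,
        n_s, n_i, rng_seed, _OFFS,
    )
    state.t += 1
    if not state.boundary_contacted:
        state.boundary_contacted = _touches_boundary(state.grid)
    return state


@njit(cache=True)
def _run_kernel(grid, d_p, r_p, a_p, b_p, max_steps, record_every,
                seed, offs, boundary0):  # pragma: no cover
    """Full run loop.  Returns per-step counts, termination code and
    boundary-contact bookkeeping; snapshot copies are stored every
    ``record_every`` steps (plus the final step)."""
    n = grid.shape[0]
    n_s = 0
    n_i = 0
    for i in range(n):
        for j in range(n):
            if grid[i, j] == 1:
                n_s += 1
            elif grid[i, j] == 2:
                n_i += 1
    ns_out = np.empty(max_steps + 1, dtype=np.int64)
    ni_out = np.empty(max_steps + 1, dtype=np.int64)
    ns_out[0] = n_s
    ni_out[0] = n_i
    n_snaps_max = max_steps // record_every + 2
    snaps = np.empty((n_snaps_max, n, n), dtype=np.int8)
    snap_t = np.empty(n_snaps_max, dtype=np.int64)
    snaps[0] = grid
    snap_t[0] = 0
    n_snaps = 1
    boundary = boundary0
    boundary_step = 0 if boundary0 else -1
    max_i = n_i
    min_s = n_s
    had_infected = n_i > 0
    term = 0  # MAX_STEPS
    t_end = 0
    np.random.seed(seed)
    for t in range(1, max_steps + 1):
        for _ in range(n * n):
            i = np.random.randint(0, n)
            j = np.random.randint(0, n)
            s = grid[i, j]
            if s == 0:
                continue
            u = np.random.random()
            if s == 1:
                if u < d_p:
                    grid[i, j] = 0
                    n_s -= 1
                elif u < d_p + r_p:
                    k = np.random.randint(0, 8)
                    ni = i + offs[k, 0]
                    nj = j + offs[k, 1]
                    if 0 <= ni < n and 0 <= nj < n and grid[ni, nj] == 0:
                        grid[ni, nj] = 1
                        n_s += 1
                        if not boundary and (ni == 0 or nj == 0
                                             or ni == n - 1 or nj == n - 1):
                            boundary = True
                            boundary_step = t
            else:
                if u < a_p:
                    grid[i, j] = 0
                    n_i -= 1
                elif u < a_p + b_p:
                    k = np.random.randint(0, 8)
                    ni = i + offs[k, 0]
                    nj = j + offs[k, 1]
                    if 0 <= ni < n and 0 <= nj < n and grid[ni, nj] == 1:
                        grid[ni, nj] = 2
                        n_s -= 1
                        n_i += 1
        ns_out[t] = n_s
        ni_out[t] = n_i
        if n_i > max_i:
            max_i = n_i
        if n_s < min_s:
            min_s = n_s
        t_end = t
        if t % record_every == 0:
            snaps[n_snaps] = grid
            snap_t[n_snaps] = t
            n_snaps += 1
        if had_infected and n_i == 0:
            term = 2 if n_s == 0 else 1  # CELLS_EXTINCT / VIRUS_EXTINCT
            break
    if term == 0 and n_s == 0 and n_i == 0:
        term = 2
    if n_snaps == 0 or snap_t[n_snaps - 1] != t_end:
        snaps[n_snaps] = grid
        snap_t[n_snaps] = t_end
        n_snaps += 1
    return (ns_out[:t_end + 1], ni_out[:t_end + 1], term, boundary,
            boundary_step, max_i, min_s, snaps[:n_snaps], snap_t[:n_snaps],
            t_end)


_TERM_CODES = {0: TerminationReason.MAX_STEPS,
               1: TerminationReason.VIRUS_EXTINCT,
               2: TerminationReason.CELLS_EXTINCT}


def run(params: LatticeParams, init: InitCondition,
        record_every: int = 50) -> RunResult:
    """Run the lattice model until max_steps or extinction.

    Records (t, n_S, n_I) every step and full grid snapshots every
    ``record_every`` steps (the final grid is always included).  Identical
    (params, init, seed) give bit-identical results.
    """
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    state = init_lattice(params, init)
    lam = params.Lambda
    kseed = derive_seed(params.seed, 0xC0FFEE)
    (ns, ni, term, boundary, boundary_step, max_i, min_s,
     snaps, snap_t, t_end) = _run_kernel(
        state.grid, params.D / lam, params.R / lam,
        params.A / lam, params.B / lam,
        params.max_steps, record_every, kseed, _OFFS,
        state.boundary_contacted,
    )
    series = PopulationTimeSeries(
        t=np.arange(t_end + 1, dtype=float), S=ns.astype(float),
        I=ni.astype(float),
    )
    return RunResult(
        series=series,
        snapshots=[np.array(snaps[i]) for i in range(snaps.shape[0])],
        snapshot_times=[int(x) for x in snap_t],
        termination=_TERM_CODES[int(term)],
        boundary_contacted=bool(boundary),
        boundary_contact_step=(int(boundary_step)
                               if boundary_step >= 0 else None),
        max_I=int(max_i),
        min_S=int(min_s),
        seed=params.seed,
    )


def write_series_csv(result: RunResult, path, params: LatticeParams) -> None:
    """Write the per-step trajectory as CSV with a seed-stamped header."""
    n2 = params.N ** 2
    with open(path, "w") as fh:
        fh.write(f"# plaquedyn lattice run seed={params.seed} "
                 f"R={params.R} D={params.D} B={params.B} A={params.A} "
                 f"N={params.N}\n")
        fh.write("t,n_S,n_I,n_empty,boundary_contacted\n")
        bstep = result.boundary_contact_step
        for i, t in enumerate(result.series.t):
            s = int(result.series.S[i])
            inf = int(result.series.I[i])
            contacted = bstep is not None and t >= bstep
            fh.write(f"{int(t)},{s},{inf},{n2 - s - inf},"
                     f"{int(contacted)}\n")


def write_snapshot(grid: np.ndarray, path) -> None:
    """Plain-text integer matrix (0/1/2), one row per line."""
    np.savetxt(path, grid, fmt="%d")


def read_snapshot(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8)
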