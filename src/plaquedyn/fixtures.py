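"""Deterministic synthetic fixtures emulating the experimental inputs.

The wet-lab inputs (fluorescence-derived count series with quadruplicate
measurement error, plaque snapshots) are not distributed with the package;
these generators produce synthetic stand-ins: simulator-generated count
series with optional Gaussian measurement noise, and parametric geometric
snapshots (annuli, nested disks, mixtures) for exercising the pattern
classifier.  Regenerating any fixture with the same seed gives an
identical file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import lattice
from .core import EMPTY, INFECTED, SUSCEPTIBLE, derive_seed

__all__ = [
    "FIXTURE_KINDS",
    "make_fixture",
    "annulus_grid",
    "mixture_disk_grid",
    "concentric_grid",
    "synthetic_timeseries",
]

FIXTURE_KINDS = (
    "timeseries",
    "snapshot_hollow_ring",
    "snapshot_filled_ring",
    "snapshot_disperse",
    "snapshot_concentric",
    "metapop_profiles",
)


def annulus_grid(N: int, r_in: float, r_out: float,
                 core_state: int = EMPTY, ring_state: int = INFECTED,
                 outside_state: int = SUSCEPTIBLE) -> np.ndarray:
    """Grid with a centered annulus of ``ring_state`` between radii
    r_in and r_out, ``core_state`` inside and ``outside_state`` beyond."""
    c = (N - 1) / 2.0
    ii, jj = np.indices((N, N))
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    grid = np.full((N, N), outside_state, dtype=np.int8)
    grid[r < r_in] = core_state
    grid[(r >= r_in) & (r <= r_out)] = ring_state
    return grid


def mixture_disk_grid(N: int, radius: float, p_infected: float = 0.5,
                      seed: int = 0,
                      outside_state: int = SUSCEPTIBLE) -> np.ndarray:
    """Disk of randomly interspersed susceptible/infected cells in a
    uniform background — the disperse-pattern archetype."""
    rng = np.random.default_rng(seed)
    c = (N - 1) / 2.0
    ii, jj = np.indices((N, N))
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    grid = np.full((N, N), outside_state, dtype=np.int8)
    disk = r <= radius
    mix = np.where(rng.random((N, N)) < p_infected, INFECTED, SUSCEPTIBLE)
    grid[disk] = mix[disk]
    return grid


def concentric_grid(N: int, ring_radii: list[tuple[float, float]],
                    between_state: int = SUSCEPTIBLE) -> np.ndarray:
    """Two or more infected annuli separated by occupied gaps."""
    c = (N - 1) / 2.0
    ii, jj = np.indices((N, N))
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    grid = np.full((N, N), between_state, dtype=np.int8)
    for r_in, r_out in ring_radii:
        grid[(r >= r_in) & (r <= r_out)] = INFECTED
    return grid


def synthetic_timeseries(R: float = 0.18, B: float = 0.26, A: float = 0.0185,
                         D: float = 0.0, N: int = 150, infected_side: int = 4,
                         days: np.ndarray | None = None,
                         steps_per_day: float = 20.0,
                         noise: float = 0.0, seed: int = 0):
    """Simulator-generated observed-count series (day, count, sd).

    Defaults reproduce the hollow-ring fit scenario; the optional Gaussian
    noise fraction emulates quadruplicate area-measurement error, and the
    sd column carries that stated fraction of the count.
    """
    if days is None:
        days = np.arange(0.0, 13.0, 1.0)
    days = np.asarray(days, dtype=float)
    max_steps = int(np.ceil(days.max() * steps_per_day))
    p = lattice.LatticeParams(R=R, D=D, B=B, A=A, N=N, max_steps=max_steps,
                              seed=derive_seed(seed, 0x515))
    init = lattice.InitCondition(scheme=lattice.CENTER_SQUARE_IN_FULL,
                                 infected_side=infected_side)
    res = lattice.run(p, init, record_every=max_steps)
    I = res.series.I
    steps = res.series.t
    counts = np.interp(days * steps_per_day, steps, I)
    rng = np.random.default_rng(derive_seed(seed, 0x0153))
    if noise > 0:
        counts = np.clip(counts + rng.normal(0.0, noise * np.maximum(
            counts, 1.0)), 0.0, None)
    sd = noise * np.maximum(counts, 1.0)
    return days, counts, sd


def _write_timeseries_csv(path: Path, days, counts, sd, seed: int):
    with open(path, "w") as fh:
        fh.write(f"# plaquedyn synthetic timeseries seed={seed}\n")
        fh.write("day,count,sd\n")
        for d, c, s in zip(days, counts, sd):
            fh.write(f"{d:g},{c:.6g},{s:.6g}\n")


def make_fixture(kind: str, out_dir, params: dict | None = None,
                 noise: float = 0.0, seed: int = 0) -> list[Path]:
    """Write deterministic synthetic input files of the requested kind.

    Returns the list of files written.  All snapshot fixtures are
    synthetic parametric geometries, not experimental data.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or {}
    written: list[Path] = []
    if kind == "timeseries":
        days, counts, sd = synthetic_timeseries(noise=noise, seed=seed,
                                                **params)
        path = out_dir / "timeseries.csv"
        _write_timeseries_csv(path, days, counts, sd, seed)
        written.append(path)
    elif kind == "snapshot_hollow_ring":
        grid = annulus_grid(params.get("N", 120), params.get("r_in", 30),
                            params.get("r_out", 45), core_state=EMPTY)
        path = out_dir / "snap_hollow_ring.txt"
        lattice.write_snapshot(grid, path)
        written.append(path)
    elif kind == "snapshot_filled_ring":
        grid = annulus_grid(params.get("N", 120), params.get("r_in", 30),
                            params.get("r_out", 38),
                            core_state=SUSCEPTIBLE)
        path = out_dir / "snap_filled_ring.txt"
        lattice.write_snapshot(grid, path)
        written.append(path)
    elif kind == "snapshot_disperse":
        grid = mixture_disk_grid(params.get("N", 120),
                                 params.get("radius", 40),
                                 params.get("p_infected", 0.5),
                                 seed=derive_seed(seed, 0xD15))
        path = out_dir / "snap_disperse.txt"
        lattice.write_snapshot(grid, path)
        written.append(path)
    elif kind == "snapshot_concentric":
        grid = concentric_grid(params.get("N", 160),
                               params.get("rings", [(20, 28), (48, 56)]))
        path = out_dir / "snap_concentric.txt"
        lattice.write_snapshot(grid, path)
        written.append(path)
    elif kind == "metapop_profiles":
        from . import metapop

        p = metapop.MetapopParams(
            r=params.get("r", 0.1), beta=params.get("beta", 1.0),
            a=params.get("a", 0.1), k=params.get("k", 100.0),
            m_S=params.get("m", 1.0), m_I=params.get("m", 1.0),
            n=params.get("n", 101), t_max=params.get("t_max", 100.0),
            seed=derive_seed(seed, 0x3E7))
        s0 = metapop.init_metapop(p)
        snap_times = np.linspace(0.0, p.t_max, 6)
        res = metapop.simulate(p, s0, snapshot_times=snap_times)
        for i, t in enumerate(res.t_snap):
            path = out_dir / f"profile_t{t:g}.csv"
            with open(path, "w") as fh:
                fh.write(f"# plaquedyn metapop profile seed={seed} t={t:g}\n")
                fh.write("patch,S,I\n")
                for j in range(p.n):
                    fh.write(f"{j},{res.profiles_S[i, j]},"
                             f"{res.profiles_I[i, j]}\n")
            written.append(path)
    return written
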