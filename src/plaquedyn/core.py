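"""Shared containers, labels and seed plumbing.

The grid alphabet is fixed throughout the package: ``0`` empty, ``1``
susceptible (uninfected target cell), ``2`` infected.  All simulators,
classifiers and the fitter exchange population trajectories through
:class:`PopulationTimeSeries`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

EMPTY = 0
SUSCEPTIBLE = 1
INFECTED = 2

#: cap for seeds handed to numba / numpy legacy seeding
_SEED_MOD = 2**31 - 1


def derive_seed(master: int, *stream: int) -> int:
    """Deterministically derive a child seed from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning keyed by ``stream`` so
    that per-replicate / per-grid-point seeds are independent and
    reproducible.  The result is kept below 2**31 so it can seed any RNG.
    """
    ss = np.random.SeedSequence(entropy=int(master) % _SEED_MOD,
                                spawn_key=tuple(int(s) % _SEED_MOD
                                                for s in stream))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


class TerminationReason(enum.Enum):
    MAX_STEPS = "MAX_STEPS"
    VIRUS_EXTINCT = "VIRUS_EXTINCT"
    CELLS_EXTINCT = "CELLS_EXTINCT"


class OutcomeLabel(enum.Enum):
    """Long-run regime of a terminated run (colors of the phase diagrams)."""

    CELL_EXTINCTION_PRE_BOUNDARY = "CELL_EXTINCTION_PRE_BOUNDARY"    # red
    CELL_EXTINCTION_POST_BOUNDARY = "CELL_EXTINCTION_POST_BOUNDARY"  # orange
    COEXISTENCE = "COEXISTENCE"                                      # blue
    VIRUS_EXTINCTION_AFTER_INVASION = "VIRUS_EXTINCTION_AFTER_INVASION"
    VIRUS_EXTINCTION_NO_INVASION = "VIRUS_EXTINCTION_NO_INVASION"    # grey


class PatternLabel(enum.Enum):
    """Initial spatial growth morphology of a plaque."""

    HOLLOW_RING = "HOLLOW_RING"
    FILLED_RING = "FILLED_RING"
    DISPERSE = "DISPERSE"
    CONCENTRIC_RINGS = "CONCENTRIC_RINGS"
    SOLID_MASS = "SOLID_MASS"
    EXTINCT = "EXTINCT"


class GrowthLaw(enum.Enum):
    QUADRATIC = "QUADRATIC"
    LINEAR = "LINEAR"
    MIXED_QUAD_THEN_LINEAR = "MIXED_QUAD_THEN_LINEAR"
    NONE = "NONE"


@dataclass
class PopulationTimeSeries:
    """(t, S, I) trajectory with optional per-point replicate spread."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    sd_I: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sd_I is not None:
            self.sd_I = np.asarray(self.sd_I, dtype=float)
        if not (len(self.t) == len(self.S) == len(self.I)):
            raise ValueError("t, S, I must have equal length")
        if self.sd_I is not None and len(self.sd_I) != len(self.t):
            raise ValueError("sd_I length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.S < 0) or np.any(self.I < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        data = {"t": self.t, "S": self.S, "I": self.I}
        if self.sd_I is not None:
            data["sd_I"] = self.sd_I
        return pd.DataFrame(data)


@dataclass
class RunResult:
    """Outcome of a lattice run: trajectory, snapshots and bookkeeping."""

    series: PopulationTimeSeries
    snapshots: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)
    termination: TerminationReason = TerminationReason.MAX_STEPS
    boundary_contacted: bool = False
    boundary_contact_step: int | None = None
    max_I: int = 0
    min_S: int = 0
    seed: int | None = None

    @property
    def final_S(self) -> int:
        return int(self.series.S[-1])

    @property
    def final_I(self) -> int:
        return int(self.series.I[-1])
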