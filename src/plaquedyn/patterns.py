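"""Quantification and classification of emergent plaque morphologies.

The experimentally observed plaque types — hollow ring (classic plaque,
emptied core), filled ring (thin infected rim around a mass of surviving
target cells) and disperse growth (mixed cluster of infected and uninfected
cells) — are identified from the radial occupancy profile of a lattice
snapshot around the plaque's founder centroid.  The accompanying growth law
of the infected-cell count (quadratic while the infected region is a filling
disk, linear once an expanding ring has formed) is fitted by least squares
with an optional changepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (EMPTY, INFECTED, SUSCEPTIBLE, GrowthLaw, OutcomeLabel,
                   PatternLabel, PopulationTimeSeries, RunResult,
                   TerminationReason)

__all__ = [
    "PatternThresholds",
    "RadialProfile",
    "PatternResult",
    "GrowthLawResult",
    "radial_profile",
    "classify_pattern",
    "growth_law",
    "classify_outcome",
]


@dataclass(frozen=True)
class PatternThresholds:
    """Decision thresholds of the pattern classifier (occupancy fractions).

    theta_detect: minimal infected fraction for an annulus to count as part
    of the plaque; theta_hollow: maximal core occupancy (S+I) of a hollow
    ring; theta_filled: minimal core susceptible fraction of a filled ring;
    theta_sparse: maximal core infected fraction of a filled ring;
    theta_mix: minimal fraction for both populations in a disperse mixture;
    annulus_width: radial bin width in spots; core_frac / rim_frac: the
    inner and outer portions of the plaque radius treated as core and rim;
    invasion_gamma: fold-increase of the infected count over its initial
    value that counts as successful invasion.
    """

    theta_detect: float = 0.05
    theta_hollow: float = 0.2
    theta_filled: float = 0.5
    theta_sparse: float = 0.2
    theta_mix: float = 0.15
    annulus_width: int = 3
    core_frac: float = 0.4
    rim_frac: float = 0.75
    rim_contrast: float = 2.0
    invasion_gamma: float = 4.0


DEFAULT_THRESHOLDS = PatternThresholds()


@dataclass
class RadialProfile:
    """Per-annulus occupancy fractions around a center point."""

    radii: np.ndarray          # outer radius of each annulus
    frac_empty: np.ndarray
    frac_S: np.ndarray
    frac_I: np.ndarray
    counts: np.ndarray         # spots per annulus
    r_out: float | None        # outer plaque radius (None if no infected)


def radial_profile(snapshot: np.ndarray, center: tuple[float, float],
                   width: int = 3,
                   theta_detect: float = 0.05) -> RadialProfile:
    """Radial occupancy profile of a lattice snapshot.

    Spots are binned into concentric annuli of the given width around
    ``center``; annuli clipped by the grid edge simply contain fewer spots.
    ``r_out`` is the outer edge of the farthest annulus whose infected
    fraction exceeds ``theta_detect``.
    """
    snapshot = np.asarray(snapshot)
    if snapshot.size == 0:
        raise ValueError("empty snapshot")
    ci, cj = center
    n, m = snapshot.shape
    if not (0 <= ci < n and 0 <= cj < m):
        raise ValueError("center outside grid")
    ii, jj = np.indices(snapshot.shape)
    r = np.sqrt((ii - ci) ** 2 + (jj - cj) ** 2)
    bins = (r // width).astype(int)
    nbins = bins.max() + 1
    counts = np.bincount(bins.ravel(), minlength=nbins)
    fr = {}
    for state in (EMPTY, SUSCEPTIBLE, INFECTED):
        w = (snapshot == state).ravel()
        fr[state] = np.bincount(bins.ravel(), weights=w.astype(float),
                                minlength=nbins) / np.maximum(counts, 1)
    radii = (np.arange(nbins) + 1.0) * width
    infected_bins = np.nonzero(fr[INFECTED] > theta_detect)[0]
    r_out = float(radii[infected_bins[-1]]) if infected_bins.size else None
    return RadialProfile(radii=radii, frac_empty=fr[EMPTY],
                         frac_S=fr[SUSCEPTIBLE], frac_I=fr[INFECTED],
                         counts=counts, r_out=r_out)


@dataclass
class PatternResult:
    label: PatternLabel
    evidence: dict = field(default_factory=dict)


def infected_centroid(snapshot: np.ndarray) -> tuple[float, float] | None:
    pos = np.argwhere(np.asarray(snapshot) == INFECTED)
    if len(pos) == 0:
        return None
    return float(pos[:, 0].mean()), float(pos[:, 1].mean())


def _ring_bands(frac_I: np.ndarray, upto: int, theta_detect: float):
    """Contiguous runs of annuli (up to index ``upto``) whose infected
    fraction exceeds theta_detect; used for the concentric-ring test."""
    active = frac_I[:upto + 1] > theta_detect
    bands = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            bands.append((start, i - 1))
            start = None
    if start is not None:
        bands.append((start, len(active) - 1))
    return bands


def _is_concentric(prof: RadialProfile, upto: int,
                   th: PatternThresholds) -> bool:
    """Two or more infected annular bands separated by a gap of at least
    two annuli holding regrown susceptible cells.  The susceptible-gap
    requirement distinguishes genuine concentric rings (target cells
    reseeded in the wake) from patchiness of a single decaying wake."""
    bands = _ring_bands(prof.frac_I, upto, th.theta_detect)
    if len(bands) < 2:
        return False
    for (s0, e0), (s1, _) in zip(bands[:-1], bands[1:]):
        gap = np.arange(e0 + 1, s1)
        if len(gap) >= 2:
            w = np.maximum(prof.counts[gap].astype(float), 1.0)
            gap_S = float(np.average(prof.frac_S[gap], weights=w))
            if gap_S >= th.theta_mix:
                return True
    return False


def classify_pattern(snapshots: list[np.ndarray],
                     thresholds: PatternThresholds = DEFAULT_THRESHOLDS,
                     ) -> PatternResult:
    """Classify a plaque morphology from an ordered snapshot sequence.

    The call is made on the radial profile of the last snapshot that still
    contains infected cells, around the centroid of the infected cells of
    the first such snapshot (the founder region).  Rotations and
    reflections of the snapshots do not change the label.
    """
    if not snapshots:
        raise ValueError("no snapshots provided")
    th = thresholds
    with_I = [s for s in snapshots if np.any(np.asarray(s) == INFECTED)]
    if not with_I:
        return PatternResult(PatternLabel.EXTINCT, {"reason": "no infected"})
    center = infected_centroid(with_I[0])
    snap = np.asarray(with_I[-1])
    prof = radial_profile(snap, center, width=th.annulus_width,
                          theta_detect=th.theta_detect)
    r_out = prof.r_out
    if r_out is None:
        # infected present but too dilute for theta_detect in any annulus:
        # fall back to the farthest annulus with any infected occupancy
        nz = np.nonzero(prof.frac_I > 0)[0]
        r_out = float(prof.radii[nz[-1]])
    upto = min(int(np.searchsorted(prof.radii, r_out)),
               len(prof.radii) - 1)

    core_mask = prof.radii <= max(th.core_frac * r_out, th.annulus_width)
    core_idx = np.nonzero(core_mask)[0]
    w = prof.counts[core_idx].astype(float)
    core_S = float(np.average(prof.frac_S[core_idx], weights=w))
    core_I = float(np.average(prof.frac_I[core_idx], weights=w))
    core_occ = core_S + core_I
    rim_idx = np.nonzero((prof.radii > th.rim_frac * r_out)
                         & (prof.radii <= r_out + th.annulus_width))[0]
    wr = np.maximum(prof.counts[rim_idx].astype(float), 1.0)
    rim_I = float(np.average(prof.frac_I[rim_idx], weights=wr))
    contrast = rim_I / max(core_I, 1e-12)
    s_share = core_S / max(core_occ, 1e-12)

    evidence = {
        "r_out": r_out, "core_S": core_S, "core_I": core_I,
        "core_occupancy": core_occ, "core_S_share": s_share,
        "rim_I": rim_I, "rim_core_contrast": contrast,
    }
    if _is_concentric(prof, upto, th):
        return PatternResult(PatternLabel.CONCENTRIC_RINGS, evidence)
    if core_occ < th.theta_hollow:
        return PatternResult(PatternLabel.HOLLOW_RING, evidence)
    # an occupied, susceptible-dominated core behind a contrasting
    # infected rim is the filled-ring morphology
    if (s_share >= th.theta_filled and core_I < th.theta_sparse
            and contrast > th.rim_contrast):
        return PatternResult(PatternLabel.FILLED_RING, evidence)
    if core_S >= th.theta_mix and core_I >= th.theta_mix:
        return PatternResult(PatternLabel.DISPERSE, evidence)
    if core_I >= th.theta_filled or core_I > core_S:
        return PatternResult(PatternLabel.SOLID_MASS, evidence)
    return PatternResult(PatternLabel.DISPERSE, evidence)


@dataclass
class GrowthLawResult:
    law: GrowthLaw
    r2: dict = field(default_factory=dict)   # goodness of fit per candidate
    changepoint: float | None = None
    sse: dict = field(default_factory=dict)


def _quad_fit_sse(t, I, polish=False):
    """Fit the surface-growth model I = (a + b*t)**2.

    Initialized by OLS of sqrt(I) on t; with ``polish`` the coefficients
    are refined by direct least squares on the raw count scale (used for
    the single-law candidate so it is scored on the same objective as its
    competitors).  Residuals are always measured on the raw scale.
    """
    coef = np.polyfit(t, np.sqrt(I), 1)
    if polish:
        from scipy.optimize import least_squares

        sol = least_squares(lambda c: np.polyval(c, t) ** 2 - I, coef,
                            method="lm", max_nfev=200)
        coef = sol.x
    pred = np.polyval(coef, t) ** 2
    return float(np.sum((I - pred) ** 2)), coef


def _lin_fit_sse(t, I):
    coef = np.polyfit(t, I, 1)
    pred = np.polyval(coef, t)
    return float(np.sum((I - pred) ** 2)), coef


def growth_law(ts: PopulationTimeSeries,
               mixed_improvement: float = 0.50,
               min_segment_frac: float = 0.15) -> GrowthLawResult:
    """Identify the growth law of an infected-cell count series.

    Quadratic growth (surface growth: sqrt(I) linear in t) is the signature
    of a filling infected disk; linear growth appears once an expanding ring
    of constant width has formed; a quadratic-then-linear changepoint is the
    hollow-ring signature.  The changepoint is chosen by a brute-force scan
    minimizing the combined squared residuals, and the mixed law is
    preferred only when it improves on the best single law by more than
    ``mixed_improvement`` (fraction of SSE).
    """
    mask = ts.I > 0
    if not np.any(mask):
        return GrowthLawResult(GrowthLaw.NONE)
    t = ts.t[mask]
    I = ts.I[mask]
    if len(t) < 5:
        raise ValueError("need >= 5 time points with I > 0")
    # a compact inoculum first relaxes (interior deaths) before the
    # expanding-plaque growth law establishes; the law is fitted to the
    # expansion phase, after the count has recovered its initial value
    half = max(len(I) // 2, 1)
    below = np.nonzero(I[:half] < I[0])[0]
    if below.size:
        i0 = int(below[-1]) + 1
        if len(I) - i0 >= 5:
            t, I = t[i0:], I[i0:]
    tss = float(np.sum((I - I.mean()) ** 2))
    tss = max(tss, 1e-300)

    sse_q, _ = _quad_fit_sse(t, I, polish=True)
    sse_l, _ = _lin_fit_sse(t, I)

    # Two-law candidate: quadratic up to the changepoint, then linear,
    # continuous at the changepoint (the ring keeps the cell count it had
    # when it formed).  Continuity prevents the split from absorbing
    # arbitrary variance on single-law data.  Each segment must carry
    # enough of the series to represent a genuine growth phase.
    best_c = None
    sse_m = np.inf
    n = len(t)
    seg = max(3, int(np.ceil(min_segment_frac * n)))
    for c in range(seg, n - seg + 1):
        sq, coef = _quad_fit_sse(t[:c], I[:c])
        i_c = np.polyval(coef, t[c - 1]) ** 2
        dt = t[c:] - t[c - 1]
        denom = float(np.sum(dt * dt))
        slope = float(np.sum((I[c:] - i_c) * dt)) / denom if denom else 0.0
        sl = float(np.sum((I[c:] - (i_c + slope * dt)) ** 2))
        if sq + sl < sse_m:
            sse_m = sq + sl
            best_c = c

    def r2(sse):
        return float(np.clip(1.0 - sse / tss, 0.0, 1.0))

    sse = {"QUADRATIC": sse_q, "LINEAR": sse_l, "MIXED": sse_m}
    r2s = {k: r2(v) for k, v in sse.items()}
    best_single = min(sse_q, sse_l)
    # a changepoint pinned to the edge of its allowed range indicates no
    # interior law change, only end-of-series curvature
    interior = best_c is not None and seg < best_c < n - seg
    if interior and sse_m < (1.0 - mixed_improvement) * best_single:
        return GrowthLawResult(GrowthLaw.MIXED_QUAD_THEN_LINEAR, r2=r2s,
                               changepoint=float(t[best_c]), sse=sse)
    if sse_q <= sse_l:
        return GrowthLawResult(GrowthLaw.QUADRATIC, r2=r2s, sse=sse)
    return GrowthLawResult(GrowthLaw.LINEAR, r2=r2s, sse=sse)


def classify_outcome(result: RunResult,
                     thresholds: PatternThresholds = DEFAULT_THRESHOLDS,
                     ) -> OutcomeLabel:
    """Map a terminated lattice run to its long-run regime label.

    Cell extinction splits into virus-mediated (before any cell touched the
    domain boundary; red in the phase diagrams) and boundary-mediated
    (after boundary contact; orange).  Virus extinction splits by whether
    the virus ever invaded: its count reached ``invasion_gamma`` times the
    inoculum, or it depleted the target cells ``invasion_gamma``-fold below
    their starting number (a slow virus in a small habitat can consume the
    whole prey pool without itself ever quadrupling).  Survival of both
    populations to the step limit is coexistence.
    """
    I0 = max(int(result.series.I[0]), 1)
    S0 = int(result.series.S[0])
    g = thresholds.invasion_gamma
    invaded = (result.max_I >= g * I0
               or (S0 > 0 and result.min_S <= S0 / g))
    term = result.termination
    if term is TerminationReason.CELLS_EXTINCT or (
            term is TerminationReason.MAX_STEPS and result.final_S == 0):
        if result.boundary_contacted:
            return OutcomeLabel.CELL_EXTINCTION_POST_BOUNDARY
        return OutcomeLabel.CELL_EXTINCTION_PRE_BOUNDARY
    if term is TerminationReason.VIRUS_EXTINCT:
        if invaded:
            return OutcomeLabel.VIRUS_EXTINCTION_AFTER_INVASION
        return OutcomeLabel.VIRUS_EXTINCTION_NO_INVASION
    return OutcomeLabel.COEXISTENCE
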