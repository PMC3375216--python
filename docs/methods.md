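# Methods

## The agent-based lattice model

Each spot of an `N×N` grid is empty (0), holds an uninfected target cell
(1), or an infected cell (2). One time step performs `N²` sequential
samplings of a uniformly random spot, with replacement, on a single
evolving grid (asynchronous update — a synchronous scheme would alter
front propagation). For a sampled cell one uniform draw `u` selects among
death, action, or nothing:

* susceptible: dies if `u < D/Λ`; else divides if `u < (D+R)/Λ` into one
  of its eight Moore neighbors chosen uniformly, succeeding only if the
  destination is inside the grid and empty;
* infected: dies if `u < A/Λ`; else transmits if `u < (A+B)/Λ` to a
  uniformly chosen Moore neighbor, succeeding only onto a susceptible
  cell. The source survives transmission; infected cells never divide
  (adenovirus infection arrests the cell cycle).

`Λ = max(1, R+D, A+B)` turns arbitrary non-negative weights into valid
probabilities while preserving every rate ratio; since the emergent
patterns depend only on the ratios `R/B`, `A/B` (at `D = 0`), this is a
pure choice of time unit. Failed placements are not retried within a
sampling. Boundaries are hard walls: the destination is drawn from the
eight conceptual positions and the event silently fails off-grid, so edge
cells are effectively slower — the geometry needed for boundary-mediated
extinction. A centered square whose parity differs from the grid's shifts
one spot toward the origin.

Two stock initial conditions: a centered infected square in a grid
otherwise full of susceptible cells (initial plaque growth), and a small
infected square nested in a susceptible square surrounded by empty space
(long-run outcome studies; defaults 5×5 in 13×13).

Runs terminate at `max_steps`, when the infected count reaches zero
(virus extinct; cells extinct if the susceptible count is also zero).
Occupancy is conserved exactly (`n_empty + n_S + n_I = N²` at every
step), and all randomness derives from a single seed via
`numpy.random.SeedSequence` spawning, so identical configurations are
bit-identical. The inner loop is numba-compiled, reseeded per step from a
(seed, step) pair.

### Choice of showcase parameter values

The regime a parameter set falls into is governed by the local
equilibria at neighborhood capacity `K = 9` (below). The showcase sets
used in tests and in the acceptance script are:

* hollow ring / quadratic-then-linear growth: `R=0.0455, B=0.49,
  A=0.0105` (`S¹ = 0.19` — the wake goes locally extinct behind the
  front). These are the virus-mediated-extinction exemplar rates scaled
  by a common factor of 3.5, a pure time-unit change that lets the ring
  form within a 600-step run on a 300×300 grid.
* disperse / quadratic growth: `R=0.19, B=0.52, A=0.12` (`S¹ = 2.08`,
  `I¹ = 1.85` — the wake relaxes to a local mixture), 300 steps.
* filled ring at intermediate times: `R=0.04, B=0.6, A=0.07`
  (`S¹ = 1.05`, `I¹ = 0.50` — the wake retains cells but cannot sustain
  infection, so infected cells concentrate at the rim while the interior
  regrows), 600 steps with snapshots every 60.

A remark on near-critical wakes: when `S¹` is only slightly below one
cell, the wake mixture decays so slowly (critical slowing) that no hollow
core forms on any practical run length; clean hollow rings need
`S¹ ≲ 0.5`.

## Pattern classification

The classifier works on the radial occupancy profile: spots are binned
into annuli of width 3 around the centroid of the infected cells of the
first snapshot that contains any (the founder region, held fixed). The
plaque radius `r_out` is the outer edge of the farthest annulus with
infected fraction above `θ_detect = 0.05`. The *core* is the inner 40% of
`r_out`, the *rim* the outer 25%. Decision rules, in order:

1. **CONCENTRIC_RINGS** — at least two infected bands (annuli above
   `θ_detect`) separated by a gap of ≥2 annuli whose susceptible fraction
   is ≥ `θ_mix = 0.15`. Requiring regrown cells in the gap distinguishes
   genuine reseeded rings from the patchiness of a single decaying wake.
2. **HOLLOW_RING** — core occupancy (S+I) below `θ_hollow = 0.2`.
3. **FILLED_RING** — susceptible share of the occupied core at least
   `θ_filled = 0.5`, core infected fraction below `θ_sparse = 0.2`, and
   rim/core infected contrast above 2.
4. **DISPERSE** — core susceptible and infected fractions both at least
   `θ_mix` (interspersed mixture, no rim/core contrast requirement).
5. **SOLID_MASS** — infected-dominated core (fraction ≥ `θ_filled`, or
   simply exceeding the susceptible fraction).
6. fallback **DISPERSE**.

All thresholds are exposed in `PatternThresholds`; the defaults above are
used throughout the tests. Labels are invariant under rotations and
reflections of the snapshots.

## Growth laws

The infected-count series is fitted after an inoculum-relaxation trim:
a compact infected block first loses its interior before the expanding
plaque's law establishes, so the fit starts after the count has recovered
its initial value (searched over the first half of the series). Three
candidates are scored by residual sum of squares on the raw count scale:

* quadratic (surface growth): `I = (a + b·t)²`, initialized by OLS of
  `√I` on `t` and polished by direct least squares;
* linear: OLS of `I` on `t`;
* quadratic-then-linear: a brute-force changepoint scan where the linear
  segment starts continuously from the quadratic's value at the
  changepoint, each segment carrying at least 15% of the points.

The mixed law is preferred only when it reduces the best single-law SSE
by more than 50% and its changepoint is interior. The margin is
deliberately large: single stochastic trajectories carry autocorrelated
meander that lets *any* changepoint split shave 10–20% of SSE even on
cleanly quadratic data, while genuine quadratic→linear series gain ~99%.
Goodness-of-fit is reported as R² clipped to [0, 1].

## Long-run outcome labels

A terminated lattice run maps to: cell extinction before/after boundary
contact; coexistence (both populations alive at the step limit); or virus
extinction with/without prior invasion. Invasion means the infected count
ever reached `γ = 4` times the inoculum **or** the susceptible pool was
depleted `γ`-fold below its start — the second clause matters because a
slow virus in the small nested habitat (169 cells) can consume
essentially all target cells without itself ever quadrupling.

## Local-equilibrium outcome prediction

With `K = 9` (a cell plus its Moore neighborhood) the mass-action system
has coexistence equilibrium `S¹ = AK/B`, `I¹ = RK(B−A)/(B(R+B))` at
`D = 0`, stable when `R₀ = B/A > 1`, approached monotonically (real
Jacobian eigenvalues) or through damped oscillations (complex pair). The
three-way outcome call: virus loss when `A ≥ B` or `I¹ < 1`; target-cell
extinction or controlled persistence when `S¹ < 1`; coexistence
otherwise. Concordance with the simulator is measured on a 30×30 grid
over a 14×14 grid of `(log₁₀ R/B, log₁₀ A/B)` points in
`[−1, 0.8] × [−2.2, 0.6]` at reference `B = 0.5`, excluding a factor-2
band around `S¹ = 1` and `I¹ = 1`, with the majority simulated outcome
over 10 seeds per point (3000-step limit); agreement is ≈99%, well above
the 85% considered concordant.

## Metapopulation model

`n` patches each of capacity `k` hold integer (S, I) counts. Channels per
patch: birth `r·S·max(0, 1−(S+I)/k)` (clipped at crowding), infection
`β·S·I/k`, infected death `a·I`, susceptible death `d·S` (default 0), and
migration at `m/2` per cell to each existing neighbor (walls at the chain
ends). Simulation is exact Gillespie (direct method): patch rates are
maintained incrementally, re-derived from scratch every 10³ events (the
largest discrepancy seen is reported and tested), and an event cap guards
against runaway rates. Totals are recorded on a uniform time grid and
patch profiles at requested times. Boundary contact is registered when
the *target-cell* wave reaches an end patch; infected cells can
random-walk through empty habitat far ahead of any population wave, and
counting such stragglers as "reaching the boundary" would misclassify
virus-mediated extinction as boundary-mediated.

Regime labels: both populations extinct before/after boundary contact
(MA/MB); persistence through low-occupancy traveling fronts (MB1, less
than half the patches occupied at the time limit) versus broad
coexistence (MC); virus extinction with/without invasion (MD/ME, same
invasion rule as the lattice). The default initial condition places 30
infected and 70 susceptible cells in the middle patch, five patches per
side at carrying capacity, the rest empty (n = 101, k = 100 in the
standard configuration).

## Reaction-diffusion front speeds

The continuum limit of hopping at `m/2` per side over spacing `h` is
diffusion with `D = m·h²/2`. Invasion fronts are pulled, so their speeds
follow from the linearization at the leading edge: `v_S = 2√(D_S·r)`
into empty habitat, `v_I = 2√(D_I·(β·S_front/k − a))` into a medium
holding `S_front` target cells per patch (zero when the argument is
negative — in particular at `S_front = S¹`, the infection cannot advance
into its own equilibrium wake). Equating the two speeds gives the
co-moving front density `H = k·(a + r·D_S/D_I)/β` (with `D_S = D_I`,
`k(a+r)/β`); `H < 1` cell marks virus-mediated extinction (MA), `H > 1`
boundary-mediated extinction (MB). The closed form is cross-checked
against a bisection root of `v_S(S) = v_I(S)` to 1e-9.

Empirical speeds are measured from patch profiles: the front is the
outermost position where the population reaches `k/2` (linear
interpolation between patches), and the speed is the least-squares slope
of position against time. Stochastic fronts run a little below the
deterministic prediction (demographic noise at the tip); at `k = 400`
the cell wave measures ~10–15% slow and the infection wave ~15–18% slow,
within the 20% band treated as agreement. Speeds approach the PDE values
from below as `k` grows.

## Phase-diagram scans

Outcomes are tallied on a grid of `(log₁₀ R/B, log₁₀ A/B)` (lattice,
reference `B = 0.5`, 30×30 grid, nested 5-in-13 start) or
`(log₁₀ r/β, log₁₀ a/β)` (metapopulation), with per-point majority labels
and full tallies retained. Overlays: the white line `S¹ = 1`
(horizontal at `A/B = 1/K`), the black line `I¹ = 1`
(`y = 1 − (1+x)/(Kx)` in ratio coordinates), the green line `H = 1`
(metapopulation), and a numerically bisected invasion threshold (yellow):
for each growth-ratio value, the smallest death ratio at which the
invasion frequency over replicates drops below `p_inv = 0.05`.
Per-point seeds derive deterministically from the scan seed, so scans are
bit-for-bit reproducible. Desk-scale defaults (12×12 points, 10
replicates) and a larger preset are exposed in the CLI.

## Fitting the simulator to observed counts

Observed infected-cell counts come from fluorescence areas: plaque area
divided by mean single-cell area, with the spread of replicate area
measurements propagated into the count standard deviation. The predicted
series is the pointwise mean (± sd) of the infected count over replicate
simulator runs whose seeds are fixed once per configuration — common
random numbers, making the stochastic objective a deterministic, smooth
function of the parameters. Steps map to days through a time-scale
factor, free by default (the mapping is not identifiable a priori),
pinnable in the configuration.

The fit minimizes unweighted squared residuals (a `1/sd²` weighting
exists but is off by default) by Nelder–Mead over log₁₀ parameters from
multiple starts. Non-identifiability is flagged when two starts end more
than 10% apart in some parameter yet within `5% + noise floor` in RSS,
where the noise floor `2·Σsd²/replicates` is the RSS scale at which two
independent replicate-averaged curves differ by sampling alone — the
objective genuinely cannot rank such fits. With three free rates and a
single ~10-point count series the objective is shallow, and the flag is
the expected outcome of recovery experiments; the self-fit (objective
evaluated at the generating parameters under the same random numbers) is
exactly zero.

Desk defaults: 100 replicates per evaluation on small grids (the tests
use a 40×40 grid, 11 daily points, 4 steps/day); a larger
replicate count only narrows the Monte-Carlo noise floor.

## Synthetic data

The fixture generator emulates the package's inputs, not any particular
experiment: count series are simulator output sampled at daily cadence
with optional Gaussian noise of a stated fractional sd (mimicking
quadruplicate area-measurement error), and snapshot fixtures are
parametric geometries (annuli, nested disks, random mixtures). They share
the simulators' seed discipline, so regeneration is byte-identical.
What passing tests on such data show is internal consistency — the
classifiers recognize the morphologies the simulator produces, the fitter
recovers or honestly flags its own generator's parameters. They do not
show that the event probabilities describe any particular virus-cell
system, nor do the synthetic series carry the heteroscedastic,
temporally correlated measurement error of real fluorescence imaging.

## Problem sizes and numerical choices

Simulation sizes in the tests and acceptance script (300×300 grids for
morphology runs, 30×30 for outcome scans, ~100-point parameter samples,
10–20 seeds per condition, 10³ oracle replicates) are chosen so the whole
suite runs on a single CPU in minutes while keeping every comparison
statistically meaningful; all tolerance bands (binomial 4–5σ for oracle
comparisons, 20% for stochastic front speeds, 0.1% for ODE convergence)
are stated next to the assertions they guard. ODE integration uses LSODA
with rtol 1e-8/atol 1e-10 and clips negative excursions within solver
tolerance. Known limitations: no virions as explicit agents, no cell
migration (movement only via offspring placement), transmission not
coupled to lysis, 2-D lattice and 1-D chain only, and pattern thresholds
tuned to the simulator's occupancy statistics rather than to microscopy
images.
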