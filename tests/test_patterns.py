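"""Pattern classification, radial profiles, growth laws, outcome labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plaquedyn as pq
from plaquedyn.core import EMPTY, INFECTED, SUSCEPTIBLE, GrowthLaw, \
    PatternLabel
from plaquedyn.fixtures import (annulus_grid, concentric_grid,
                                mixture_disk_grid)
from plaquedyn.patterns import (classify_pattern, growth_law,
                                radial_profile)


def series(t, I):
    t = np.asarray(t, dtype=float)
    return pq.PopulationTimeSeries(t=t, S=np.zeros_like(t),
                                   I=np.asarray(I, dtype=float))


class TestRadialProfile:
    def test_annulus_fixture_profile(self):
        grid = annulus_grid(101, 10, 15, core_state=EMPTY,
                            ring_state=INFECTED,
                            outside_state=SUSCEPTIBLE)
        prof = radial_profile(grid, (50, 50), width=3)
        core_bins = prof.radii <= 9
        assert np.all(prof.frac_empty[core_bins] > 0.95)
        ring_bin = np.searchsorted(prof.radii, 13.5)
        assert prof.frac_I[ring_bin] > 0.9
        outside = (prof.radii > 21) & (prof.radii < 45)
        assert np.all(prof.frac_S[outside] > 0.95)
        assert prof.r_out == pytest.approx(15.0, abs=3.0)

    def test_uniform_susceptible_grid(self):
        grid = np.full((40, 40), SUSCEPTIBLE, dtype=np.int8)
        prof = radial_profile(grid, (20, 20))
        assert np.all(prof.frac_S == 1.0)
        assert prof.r_out is None

    def test_fractions_sum_to_one(self):
        grid = mixture_disk_grid(60, 20, seed=1)
        prof = radial_profile(grid, (29.5, 29.5))
        total = prof.frac_empty + prof.frac_S + prof.frac_I
        assert np.allclose(total[prof.counts > 0], 1.0)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.zeros((5, 5), dtype=np.int8), (9, 0))


class TestClassifyPattern:
    def test_hollow_ring_fixture(self):
        grid = annulus_grid(121, 30, 45, core_state=EMPTY)
        assert classify_pattern([grid]).label is PatternLabel.HOLLOW_RING

    def test_filled_ring_fixture(self):
        grid = annulus_grid(121, 30, 38, core_state=SUSCEPTIBLE)
        assert classify_pattern([grid]).label is PatternLabel.FILLED_RING

    def test_disperse_fixture(self):
        grid = mixture_disk_grid(121, 40, p_infected=0.5, seed=3)
        assert classify_pattern([grid]).label is PatternLabel.DISPERSE

    def test_concentric_rings_fixture(self):
        grid = concentric_grid(161, [(20, 28), (48, 56)])
        assert classify_pattern([grid]).label is \
            PatternLabel.CONCENTRIC_RINGS

    def test_solid_mass_fixture(self):
        grid = annulus_grid(121, 0, 30, core_state=INFECTED,
                            ring_state=INFECTED,
                            outside_state=SUSCEPTIBLE)
        assert classify_pattern([grid]).label is PatternLabel.SOLID_MASS

    def test_extinct_when_no_infected_anywhere(self):
        grid = np.full((30, 30), SUSCEPTIBLE, dtype=np.int8)
        assert classify_pattern([grid]).label is PatternLabel.EXTINCT

    def test_empty_snapshot_list_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern([])

    @pytest.mark.parametrize("transform", [
        np.rot90, np.fliplr, np.flipud,
        lambda g: np.rot90(g, 2),
    ])
    def test_symmetry_invariance(self, transform):
        grids = [annulus_grid(121, 30, 45, core_state=EMPTY),
                 annulus_grid(121, 30, 38, core_state=SUSCEPTIBLE),
                 mixture_disk_grid(121, 40, seed=5)]
        for g in grids:
            assert classify_pattern([g]).label is \
                classify_pattern([transform(g)]).label


class TestGrowthLaw:
    def test_exact_quadratic(self):
        t = np.arange(1.0, 60)
        g = growth_law(series(t, (3 * t) ** 2))
        assert g.law is GrowthLaw.QUADRATIC
        assert g.r2["QUADRATIC"] == pytest.approx(1.0)

    def test_exact_linear(self):
        t = np.arange(1.0, 60)
        g = growth_law(series(t, 40 * t))
        assert g.law is GrowthLaw.LINEAR
        assert g.r2["LINEAR"] == pytest.approx(1.0)

    def test_changepoint_located_by_scan(self):
        t = np.arange(0.0, 100)
        I = np.where(t < 50, t ** 2, 2500 + 100 * (t - 50))
        g = growth_law(series(t[1:], I[1:]))
        assert g.law is GrowthLaw.MIXED_QUAD_THEN_LINEAR
        assert g.changepoint == pytest.approx(50, abs=6)

    def test_all_zero_counts(self):
        t = np.arange(0.0, 10)
        g = growth_law(series(t, np.zeros_like(t)))
        assert g.law is GrowthLaw.NONE

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            growth_law(series([0, 1, 2, 3], [1, 2, 3, 4]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.01, 100), st.floats(0.01, 10))
    def test_scale_invariance(self, c_count, c_time):
        t = np.arange(1.0, 80)
        rng = np.random.default_rng(0)
        I = (2 * t) ** 2 * (1 + 0.05 * rng.standard_normal(len(t)))
        base = growth_law(series(t, I)).law
        scaled = growth_law(series(t * c_time, I * c_count)).law
        assert base is scaled


class TestClassifyOutcome:
    def _result(self, S, I, term, boundary, max_I, min_S=None, S0=150,
                I0=25):
        ser = pq.PopulationTimeSeries(
            t=np.array([0.0, 1.0]), S=np.array([S0, S], dtype=float),
            I=np.array([I0, I], dtype=float))
        return pq.RunResult(series=ser, termination=term,
                            boundary_contacted=boundary, max_I=max_I,
                            min_S=min_S if min_S is not None else min(S0, S))

    def test_cell_extinction_pre_boundary(self):
        r = self._result(0, 0, pq.TerminationReason.CELLS_EXTINCT, False,
                         200)
        assert pq.classify_outcome(r) is \
            pq.OutcomeLabel.CELL_EXTINCTION_PRE_BOUNDARY

    def test_cell_extinction_post_boundary(self):
        r = self._result(0, 0, pq.TerminationReason.CELLS_EXTINCT, True,
                         200)
        assert pq.classify_outcome(r) is \
            pq.OutcomeLabel.CELL_EXTINCTION_POST_BOUNDARY

    def test_virus_extinction_without_invasion(self):
        r = self._result(500, 0, pq.TerminationReason.VIRUS_EXTINCT, True,
                         max_I=30, min_S=140)
        assert pq.classify_outcome(r) is \
            pq.OutcomeLabel.VIRUS_EXTINCTION_NO_INVASION

    def test_virus_extinction_after_invasion_via_count(self):
        r = self._result(500, 0, pq.TerminationReason.VIRUS_EXTINCT, True,
                         max_I=120, min_S=140)
        assert pq.classify_outcome(r) is \
            pq.OutcomeLabel.VIRUS_EXTINCTION_AFTER_INVASION

    def test_virus_extinction_after_invasion_via_prey_depletion(self):
        # a slow virus can eat the prey pool without quadrupling itself
        r = self._result(10, 0, pq.TerminationReason.VIRUS_EXTINCT, False,
                         max_I=60, min_S=8)
        assert pq.classify_outcome(r) is \
            pq.OutcomeLabel.VIRUS_EXTINCTION_AFTER_INVASION

    def test_coexistence_at_step_limit(self):
        r = self._result(300, 80, pq.TerminationReason.MAX_STEPS, True,
                         max_I=120)
        assert pq.classify_outcome(r) is pq.OutcomeLabel.COEXISTENCE
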