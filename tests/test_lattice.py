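"""Agent-based lattice model: initialization, update rules, invariants."""

import itertools

import numpy as np
import pytest

import plaquedyn as pq
from plaquedyn.core import EMPTY, INFECTED, SUSCEPTIBLE
from plaquedyn.lattice import LatticeParams, init_lattice, step


def counts_of(state):
    return state.counts()


class TestInit:
    def test_center_square_in_full_counts(self):
        p = LatticeParams(R=0.5, D=0, B=0.6, A=0.06, N=300)
        st = init_lattice(p, pq.InitCondition(
            scheme=pq.CENTER_SQUARE_IN_FULL, infected_side=30))
        n_e, n_s, n_i = st.counts()
        assert (n_i, n_s, n_e) == (900, 89100, 0)
        assert st.boundary_contacted  # susceptible cells fill the grid

    def test_nested_squares_counts(self, nested_init):
        p = LatticeParams(R=0.1, D=0, B=0.1, A=0.01, N=30)
        st = init_lattice(p, nested_init)
        n_e, n_s, n_i = st.counts()
        assert (n_i, n_s, n_e) == (25, 144, 731)
        assert not st.boundary_contacted

    def test_degenerate_no_infected(self):
        p = LatticeParams(R=0.1, D=0, B=0.1, A=0.01, N=20)
        st = init_lattice(p, pq.InitCondition(
            scheme=pq.CENTER_SQUARE_IN_FULL, infected_side=0))
        assert st.counts()[2] == 0
        assert st.counts()[1] == 400

    def test_invalid_nesting_raises(self):
        p = LatticeParams(R=0.1, D=0, B=0.1, A=0.01, N=10)
        with pytest.raises(ValueError):
            init_lattice(p, pq.InitCondition(scheme=pq.NESTED_SQUARES,
                                             infected_side=8,
                                             susceptible_side=5))
        with pytest.raises(ValueError):
            init_lattice(p, pq.InitCondition(
                scheme=pq.CENTER_SQUARE_IN_FULL, infected_side=11))

    def test_parity_shift_toward_origin(self):
        # N - side odd: square shifts one spot toward the origin
        p = LatticeParams(R=0.1, D=0, B=0.1, A=0.01, N=5)
        st = init_lattice(p, pq.InitCondition(
            scheme=pq.CENTER_SQUARE_IN_FULL, infected_side=2))
        rows = np.nonzero((st.grid == INFECTED).any(axis=1))[0]
        assert rows.tolist() == [1, 2]


class TestStep:
    def test_all_empty_grid_unchanged(self):
        p = LatticeParams(R=0.9, D=0.3, B=0.9, A=0.3, N=10)
        st = pq.LatticeState(grid=np.zeros((10, 10), dtype=np.int8))
        step(st, p, rng_seed=1)
        assert st.t == 1
        assert not st.grid.any()

    def test_single_infected_survival_probability(self):
        # with A=1 the cell dies iff its spot is sampled at least once:
        # P(alive after one step) = (1 - 1/N^2)^(N^2) ~ e^-1
        N = 10
        p = LatticeParams(R=0, D=0, B=0, A=1.0, N=N)
        n_rep = 4000
        alive = 0
        for rep in range(n_rep):
            grid = np.zeros((N, N), dtype=np.int8)
            grid[4, 4] = INFECTED
            st = pq.LatticeState(grid=grid)
            step(st, p, rng_seed=rep)
            alive += int(st.grid[4, 4] == INFECTED)
        expect = (1 - 1 / N**2) ** (N**2)
        se = np.sqrt(expect * (1 - expect) / n_rep)
        assert abs(alive / n_rep - expect) < 4 * se

    def test_conservation_every_step(self, nested_init):
        p = LatticeParams(R=0.3, D=0.05, B=0.4, A=0.1, N=20, seed=3)
        st = init_lattice(p, pq.InitCondition(scheme=pq.NESTED_SQUARES,
                                              infected_side=3,
                                              susceptible_side=9))
        for t in range(50):
            step(st, p)
            n_e, n_s, n_i = st.counts()
            assert n_e + n_s + n_i == 400

    def test_boundary_flag_monotone(self):
        p = LatticeParams(R=0.9, D=0, B=0, A=0, N=9, seed=1)
        st = init_lattice(p, pq.InitCondition(scheme=pq.NESTED_SQUARES,
                                              infected_side=0,
                                              susceptible_side=3))
        seen = False
        for _ in range(200):
            step(st, p)
            if seen:
                assert st.boundary_contacted
            seen = st.boundary_contacted


class TestSmallGridOracle:
    """One-step state distribution on a 2x2 grid against exhaustive
    enumeration of the N^2 sequential sampling process."""

    @staticmethod
    def _enumerate(grid0, p):
        lam = p.Lambda
        moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1),
                 (1, 0), (1, 1)]
        states = {tuple(grid0.ravel()): 1.0}
        for _ in range(4):  # N^2 = 4 sequential draws
            nxt = {}

            def add(s, pr):
                nxt[s] = nxt.get(s, 0.0) + pr

            for s, pr in states.items():
                g = np.array(s).reshape(2, 2)
                for i, j in itertools.product(range(2), range(2)):
                    p_spot = pr / 4.0
                    cell = g[i, j]
                    if cell == EMPTY:
                        add(s, p_spot)
                        continue
                    death = (p.D if cell == SUSCEPTIBLE else p.A) / lam
                    action = (p.R if cell == SUSCEPTIBLE else p.B) / lam
                    # death branch
                    g2 = g.copy()
                    g2[i, j] = EMPTY
                    add(tuple(g2.ravel()), p_spot * death)
                    # action branch: uniform over 8 conceptual neighbors
                    for di, dj in moves:
                        ni, nj = i + di, j + dj
                        pb = p_spot * action / 8.0
                        if 0 <= ni < 2 and 0 <= nj < 2:
                            tgt = g[ni, nj]
                            if cell == SUSCEPTIBLE and tgt == EMPTY:
                                g2 = g.copy()
                                g2[ni, nj] = SUSCEPTIBLE
                                add(tuple(g2.ravel()), pb)
                                continue
                            if cell == INFECTED and tgt == SUSCEPTIBLE:
                                g2 = g.copy()
                                g2[ni, nj] = INFECTED
                                add(tuple(g2.ravel()), pb)
                                continue
                        add(s, pb)  # off-grid or blocked: event fails
                    add(s, p_spot * (1.0 - death - action))
            states = nxt
        return states

    def test_one_step_distribution_matches_enumeration(self):
        p = LatticeParams(R=0.2, D=0.1, B=0.5, A=0.3, N=2)
        grid0 = np.array([[INFECTED, EMPTY], [EMPTY, SUSCEPTIBLE]],
                         dtype=np.int8)
        exact = self._enumerate(grid0, p)
        assert abs(sum(exact.values()) - 1.0) < 1e-12
        n_rep = 20000
        observed = {}
        for rep in range(n_rep):
            st = pq.LatticeState(grid=grid0.copy())
            step(st, p, rng_seed=rep)
            key = tuple(st.grid.ravel())
            observed[key] = observed.get(key, 0) + 1
        for s, prob in exact.items():
            if prob < 0.01:
                continue
            est = observed.get(s, 0) / n_rep
            se = np.sqrt(prob * (1 - prob) / n_rep)
            assert abs(est - prob) < 5 * se, (s, prob, est)


class TestRun:
    def test_logistic_filling_without_virus(self):
        # B=A=D=0, R>0: susceptible cells colonize every empty spot
        p = LatticeParams(R=0.8, D=0, B=0, A=0, N=15, max_steps=400,
                          seed=2)
        res = pq.run(p, pq.InitCondition(scheme=pq.NESTED_SQUARES,
                                         infected_side=0,
                                         susceptible_side=5),
                     record_every=400)
        S = res.series.S
        assert np.all(np.diff(S) >= 0)
        assert S[-1] == 15**2

    def test_pure_death_terminates_virus_extinct(self, nested_init):
        p = LatticeParams(R=0, D=0, B=0, A=0.5, N=30, max_steps=500,
                          seed=0)
        res = pq.run(p, nested_init, record_every=500)
        assert res.termination is pq.TerminationReason.VIRUS_EXTINCT
        assert res.final_I == 0

    def test_determinism_bit_identical(self, nested_init):
        p = LatticeParams(R=0.3, D=0, B=0.4, A=0.05, N=25, max_steps=150,
                          seed=77)
        r1 = pq.run(p, nested_init, record_every=50)
        r2 = pq.run(p, nested_init, record_every=50)
        assert np.array_equal(r1.series.I, r2.series.I)
        assert np.array_equal(r1.series.S, r2.series.S)
        for a, b in zip(r1.snapshots, r2.snapshots):
            assert np.array_equal(a, b)

    def test_virus_count_absorbing_at_zero(self):
        # once I = 0 the infected population can never reappear
        p = LatticeParams(R=0.5, D=0.1, B=0.9, A=0.9, N=15, max_steps=300,
                          seed=4)
        res = pq.run(p, pq.InitCondition(scheme=pq.NESTED_SQUARES,
                                         infected_side=2,
                                         susceptible_side=7),
                     record_every=300)
        I = res.series.I
        zeros = np.nonzero(I == 0)[0]
        if zeros.size:
            assert np.all(I[zeros[0]:] == 0)

    def test_rate_ratio_invariance_of_pattern(self):
        # scaling all weights by c changes only the time scale
        base = dict(R=0.19, D=0.0, B=0.52, A=0.12)
        labels = {}
        for c, steps in ((1.0, 160), (0.1, 1600)):
            p = LatticeParams(R=base["R"] * c, D=0.0, B=base["B"] * c,
                              A=base["A"] * c, N=140, max_steps=steps,
                              seed=9)
            res = pq.run(p, pq.InitCondition(
                scheme=pq.CENTER_SQUARE_IN_FULL, infected_side=14),
                record_every=steps)
            labels[c] = pq.classify_pattern(res.snapshots).label
        assert labels[1.0] == labels[0.1]

    def test_snapshot_roundtrip(self, tmp_path, nested_init):
        p = LatticeParams(R=0.3, D=0, B=0.4, A=0.05, N=20, max_steps=20,
                          seed=1)
        res = pq.run(p, pq.InitCondition(scheme=pq.NESTED_SQUARES,
                                         infected_side=3,
                                         susceptible_side=9),
                     record_every=10)
        path = tmp_path / "snap_t10.txt"
        from plaquedyn.lattice import read_snapshot, write_snapshot

        write_snapshot(res.snapshots[1], path)
        back = read_snapshot(path)
        assert np.array_equal(back, res.snapshots[1])

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            LatticeParams(R=-0.1, D=0, B=0.1, A=0.1, N=10)
        with pytest.raises(ValueError):
            LatticeParams(R=0.1, D=0, B=0.1, A=0.1, N=1)
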