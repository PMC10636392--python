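"""Exactness and bookkeeping of the event-driven simulator."""

import itertools

import numpy as np
import pytest

from fgba import Landscape, Params, run_ensemble, simulate
from fgba.landscape import A, B, F, G
from fgba.simulate import Trajectory

FROZEN = Params(alpha=0, beta=0, gamma=0, phi=0, lam=0, mu=0, rho_g=0, rho_f=0)


class TestBasicContracts:
    def test_frozen_chain_never_moves(self):
        ls = Landscape.uniform_random(10, 10, 0.5, seed=1)
        traj = simulate(ls, FROZEN, t_end=5.0, seed=0, record_dt=1.0)
        assert np.all(traj.fractions == traj.fractions[0])
        assert sum(traj.event_counts.values()) == 0
        assert np.array_equal(traj.final.cells, ls.cells)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            simulate(Landscape.all_grass(4), FROZEN, t_end=0.0, seed=0)

    def test_fractions_conserved_and_times_increasing(self):
        p = Params().with_phi_N(0.3, 400)
        traj = simulate(Landscape.uniform_random(20, 20, 0.4, seed=3), p,
                        t_end=30.0, seed=3, record_dt=0.5)
        assert np.all(np.diff(traj.times) > 0)
        np.testing.assert_allclose(traj.fractions.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_absorbing_states_without_disturbance(self):
        """With no ignition, recruitment or mortality, pure stands persist."""
        p = Params(beta=0, gamma=0, phi=0)
        for ls in (Landscape.all_forest(8), Landscape.all_grass(8)):
            traj = simulate(ls, p, t_end=50.0, seed=1, record_dt=10.0)
            assert np.array_equal(traj.final.cells, ls.cells)

    def test_determinism_and_ensemble_seeding(self):
        p = Params().with_phi_N(0.5, 144)
        ls = Landscape.uniform_random(12, 12, 0.5, seed=9)
        t1 = simulate(ls, p, 20.0, seed=42, record_dt=1.0)
        t2 = simulate(ls, p, 20.0, seed=42, record_dt=1.0)
        assert np.array_equal(t1.fractions, t2.fractions)
        assert t1.event_counts == t2.event_counts

        e1 = run_ensemble(ls, p, 10.0, n_reps=2, base_seed=7, record_dt=1.0)
        e2 = run_ensemble(ls, p, 10.0, n_reps=2, base_seed=7, record_dt=1.0)
        assert run_ensemble(ls, p, 10.0, n_reps=0, base_seed=7) == []
        assert np.array_equal(e1[0].fractions, e2[0].fractions)
        # replicates differ from each other
        assert e1[0].event_counts != e1[1].event_counts

    def test_snapshots_recorded(self):
        p = Params(gamma=0.1)
        traj = simulate(Landscape.all_forest(6), p, 10.0, seed=2,
                        record_dt=1.0, snapshot_times=[0.5, 5.0])
        assert set(traj.snapshots) == {0.5, 5.0}


class TestStatisticalExactness:
    def test_pure_death_decay(self):
        """Only mortality: independent cells die at gamma, so the ensemble
        mean of [F] at t = 1/gamma is e^{-1}."""
        gamma = 0.05
        p = Params(alpha=0, beta=0, gamma=gamma, phi=0, lam=0, mu=0,
                   rho_g=0, rho_f=0)
        finals = []
        for s in range(40):
            traj = simulate(Landscape.all_forest(20), p, t_end=1 / gamma,
                            seed=s, record_dt=1 / gamma)
            finals.append(traj.fractions[-1, 0])
        mean = np.mean(finals)
        # per-run SD of a binomial mean with p = e^-1, n = 400 cells
        se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / 400 / len(finals))
        assert abs(mean - np.exp(-1)) < 3 * se

    def test_event_counts_match_integrated_propensities(self):
        """Realized counts of composition-only channels agree with their
        exactly integrated propensities within Poisson error."""
        p = Params().with_phi_N(0.4, 900)
        traj = simulate(Landscape.uniform_random(30, 30, 0.5, seed=5), p,
                        t_end=150.0, seed=5, record_dt=1.0)
        n = 900
        expected_mortality = p.gamma * n * traj.cum_F[-1]
        expected_ignition = p.phi * n * traj.cum_G[-1]
        for observed, lam in ((traj.event_counts["F->G"], expected_mortality),
                              (traj.event_counts["G->B ignition"],
                               expected_ignition)):
            assert abs(observed - lam) < 3 * np.sqrt(lam) + 1e-9

    def test_tiny_lattice_matches_brute_force_stationary_distribution(self):
        """2x2 torus with recruitment, forest spread and mortality: sampled
        occupancy converges to the stationary law of the explicit 16-state
        generator (total-variation distance < 0.05)."""
        alpha, beta, gamma = 0.6, 0.4, 1.0
        p = Params(alpha=alpha, beta=beta, gamma=gamma, phi=0, lam=0, mu=0,
                   rho_g=0, rho_f=0)

        # brute-force oracle: enumerate {F,G}^4, build Q, solve pi Q = 0.
        # On the 2x2 torus each cell has the other-row and other-column cells
        # as neighbours twice (wrapping both ways).
        states = list(itertools.product([F, G], repeat=4))
        index = {s: k for k, s in enumerate(states)}
        nbr = {0: (1, 1, 2, 2), 1: (0, 0, 3, 3),
               2: (3, 3, 0, 0), 3: (2, 2, 1, 1)}
        Q = np.zeros((16, 16))
        for s, k in index.items():
            for i in range(4):
                if s[i] == G:
                    n_forest = sum(1 for j in nbr[i] if s[j] == F)
                    rate = beta + alpha * n_forest
                    target = list(s)
                    target[i] = F
                else:
                    rate = gamma
                    target = list(s)
                    target[i] = G
                Q[k, index[tuple(target)]] += rate
                Q[k, k] -= rate
        # stationary distribution: left null vector, normalized
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = pi / pi.sum()

        traj = simulate(Landscape.all_grass(2), p, t_end=4000.0, seed=11,
                        record_dt=4000.0,
                        snapshot_times=np.arange(50.0, 4000.0, 0.25))
        occ = np.zeros(16)
        for ls in traj.snapshots.values():
            occ[index[tuple(int(c) for c in ls.cells.ravel())]] += 1
        occ /= occ.sum()
        tv = 0.5 * np.abs(occ - pi).sum()
        assert tv < 0.05

    def test_fires_are_fast_transients(self, table1):
        """With the standard rates every burning phase lasts << 1e-3 y."""
        from fgba import grass_clusters, simulate_fire_event
        ls = Landscape.forest_with_hole(30, None, 0.2)
        members = grass_clusters(ls).members(1)
        durations = [simulate_fire_event(ls, table1, int(members[k]),
                                         seed=k).duration
                     for k in range(20)]
        assert max(durations) < 1e-3


class TestWindowAverages:
    def test_piecewise_constant_integral_is_exact(self):
        """Hand-computed integral of a synthetic step trajectory."""
        times = np.array([0.0, 1.0, 3.0, 4.0])
        F_vals = np.array([0.2, 0.5, 0.1, 0.1])
        # cumulative integral of the left-continuous step function
        cum = np.array([0.0, 0.2 * 1, 0.2 + 0.5 * 2, 0.2 + 1.0 + 0.1])
        traj = Trajectory(times=times,
                          fractions=np.column_stack([F_vals] * 4) / 4,
                          cum_F=cum, cum_G=cum, cum_phi=cum * 0,
                          ignition_times=np.array([]), event_counts={},
                          seed=0, params=FROZEN,
                          final=Landscape.all_grass(2))
        # integral = 0.2*1 + 0.5*2 + 0.1*1 = 1.3 over 4 years
        assert traj.window_average_F(0.0, 4.0) == pytest.approx(1.3 / 4)
        assert traj.window_average_F(1.0, 2.0) == pytest.approx(0.5)

    def test_constant_trajectory(self):
        traj = simulate(Landscape.all_forest(5), FROZEN, 10.0, seed=0,
                        record_dt=1.0)
        assert traj.window_average_F(2.0, 6.0) == pytest.approx(1.0)

    def test_window_outside_run_raises(self):
        traj = simulate(Landscape.all_forest(5), FROZEN, 10.0, seed=0,
                        record_dt=1.0)
        with pytest.raises(ValueError):
            traj.window_average_F(5.0, 10.0)

    def test_riemann_sampling_converges_to_exact_integral(self):
        """Sample means at finer cadence approach the event-exact average."""
        p = Params(gamma=0.3, beta=0.2)
        ls = Landscape.uniform_random(10, 10, 0.5, seed=4)
        traj = simulate(ls, p, 40.0, seed=4, record_dt=0.01)
        exact = traj.window_average_F(0.0, 40.0)
        # error bound for sampling a step path: ~ n_jumps * dt * (1/N) / T
        for dt, tol in ((1.0, 0.1), (0.05, 0.015)):
            sel = np.isclose(traj.times % dt, 0.0, atol=1e-9)
            riemann = traj.fractions[sel, 0][:-1].mean()
            assert abs(riemann - exact) < tol
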