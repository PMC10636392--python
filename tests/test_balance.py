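"""The balance equation, emergent curves, steady states, critical hole."""

import numpy as np
import pytest

from fgba import (EmergentCurves, Landscape, Params, critical_hole_size,
                  fit_emergent_curves, gain_rate, grass_clusters, loss_rate,
                  net_rate, ode_steady_states, pair_count,
                  single_cluster_net_rate, state_fractions,
                  weighted_forest_perimeter)
from fgba.landscape import F, G

from conftest import random_landscape

#: exact pf = 0.1 (rho_f/(rho_f+mu) with mu = 9 rho_f)
EXACT_PF = dict(rho_f=1e5, mu=9e5, rho_g=9e6)


class TestGainLoss:
    def test_all_forest_gain_is_minus_gamma(self, table1):
        assert gain_rate(1.0, 0.0, 0.0, table1) == pytest.approx(-0.02)

    def test_all_grass_gain_is_beta(self, table1):
        assert gain_rate(0.0, 1.0, 0.0, table1) == pytest.approx(2e-4)

    def test_constructed_root(self, table1):
        Fv, Gv = 0.8333, 0.1667
        FG = (table1.gamma * Fv - table1.beta * Gv) / table1.alpha
        assert gain_rate(Fv, Gv, FG, table1) == pytest.approx(0.0, abs=1e-15)

    def test_loss_zero_without_grass(self, table1):
        d = grass_clusters(Landscape.all_forest(8))
        assert loss_rate(d, table1.with_phi_N(1.0, 64)) == 0.0

    def test_loss_direct_substitution(self):
        """Single cluster, [G]=0.5, [FG]=0.1, phiN=1, pf=0.1 -> 5e-3 / y."""
        from fgba import ClusterDecomposition
        N = 100
        d = ClusterDecomposition(labels=np.zeros((10, 10), int),
                                 sizes=np.array([50]),
                                 fg_counts=np.array([10]), N=N)
        p = Params(**EXACT_PF).with_phi_N(1.0, N)
        assert loss_rate(d, p) == pytest.approx(5e-3)

    def test_cluster_sum_identity(self, rng):
        """The compact form phi*pf*N*[G]*[FG]cg equals the per-cluster sum
        of ignition rate x per-fire loss, on any decomposition."""
        for seed in range(6):
            ls = random_landscape(rng, 16, 16, p=(0.45, 0.55, 0, 0))
            d = grass_clusters(ls)
            p = Params(**EXACT_PF).with_phi_N(0.7, ls.N)
            direct = sum((p.phi * ls.N * gj) * (p.pf * fgj)
                         for gj, fgj in zip(d.g_fractions, d.fg_fractions))
            assert loss_rate(d, p) == pytest.approx(direct, rel=1e-12)

    def test_net_rate_all_forest(self, table1):
        terms = net_rate(Landscape.all_forest(10), table1.with_phi_N(1.0, 100))
        assert terms.net == pytest.approx(-table1.gamma)
        assert terms.loss == 0.0

    def test_net_rate_slow_view_maps_burning_to_grass(self, table1):
        cells = Landscape.all_forest(6).cells.copy()
        cells[2, 2] = 2  # a burning cell counts as grass on the slow view
        terms = net_rate(Landscape(cells), table1)
        frac = 1 / 36
        expected = (table1.beta * frac - table1.gamma * (1 - frac)
                    + table1.alpha * 4 / 36)
        assert terms.gain == pytest.approx(expected)


class TestSingleClusterApproximation:
    def test_no_interface_reduces_to_demography(self, table1):
        got = single_cluster_net_rate(0.3, 0.0, table1, 100)
        assert got == pytest.approx(table1.beta * 0.7 - table1.gamma * 0.3)

    def test_constructed_cancellation(self):
        """alpha = phi*pf*N*G makes the interface terms vanish."""
        N, Fv = 100, 0.4
        p = Params(**EXACT_PF)
        p = p.replace(phi=p.alpha / (p.pf * N * (1 - Fv)))
        got = single_cluster_net_rate(Fv, 0.123, p, N)
        assert got == pytest.approx(p.beta * 0.6 - p.gamma * 0.4)

    def test_agrees_with_full_balance_at_low_cover(self, table1):
        """With one grass cluster, the approximation is the exact balance."""
        from fgba import simulate
        p = table1.with_phi_N(0.38, 40 * 40)
        traj = simulate(Landscape.uniform_random(40, 40, 0.12, seed=3), p,
                        30.0, seed=3, record_dt=30.0)
        ls = traj.final.slow_view()
        fg = pair_count(ls, F, G)
        full = net_rate(ls, p).net
        approx = single_cluster_net_rate(state_fractions(ls).f_F, fg, p, ls.N)
        assert approx == pytest.approx(full, rel=0.15, abs=2e-4)


def make_linear_curves(c_fg, c_fgcg, n_grid=80):
    """Curves linear in F (PCHIP reproduces them exactly)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    fg = c_fg * (1.0 - grid)
    fgcg = c_fgcg * (1.0 - grid)
    z = np.zeros(n_grid)
    return EmergentCurves(grid, fg, fgcg, grid, fg, fgcg, z, z)


class TestEmergentCurves:
    def test_known_function_recovery(self, rng):
        """Scatter from a smooth curve + noise is recovered within 2 noise SD."""
        noise = 0.02
        Fd = rng.uniform(0.0, 1.0, 600)
        truth = lambda x: 0.8 * 4 * x * (1 - x)
        FGd = truth(Fd) + rng.normal(0, noise, 600)
        FGcgd = 0.9 * truth(Fd) + rng.normal(0, noise, 600)
        curves = fit_emergent_curves(np.column_stack([Fd, FGd, FGcgd]))
        grid = np.linspace(0.05, 0.95, 50)
        assert np.max(np.abs(curves.FG_star(grid) - truth(grid))) < 2 * noise
        assert np.max(np.abs(curves.FGcg_star(grid) - 0.9 * truth(grid))) < 2 * noise

    def test_degenerate_equal_scatter_gives_equal_fits(self, rng):
        Fd = rng.uniform(0.1, 0.9, 200)
        FGd = 2.0 * Fd * (1 - Fd) + rng.normal(0, 0.01, 200)
        curves = fit_emergent_curves(np.column_stack([Fd, FGd, FGd]))
        grid = np.linspace(0.15, 0.85, 30)
        np.testing.assert_allclose(curves.FG_star(grid),
                                   curves.FGcg_star(grid), atol=1e-9)

    def test_endpoints_clamped_to_zero(self, rng):
        Fd = np.concatenate([[0.0, 1.0], rng.uniform(0, 1, 100)])
        FGd = np.full_like(Fd, 0.3)
        curves = fit_emergent_curves(np.column_stack([Fd, FGd, FGd]))
        assert curves.FG_star(0.0) == pytest.approx(0.0, abs=1e-12)
        assert curves.FG_star(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            fit_emergent_curves([(0.5, 0.1, 0.1)] * 10)
        with pytest.raises(ValueError):
            fit_emergent_curves([(0.5, 0.1, 0.1)] * 60)  # no F spread

    def test_extrapolation_refused(self, rng):
        Fd = rng.uniform(0.3, 0.6, 100)
        curves = fit_emergent_curves(
            np.column_stack([Fd, Fd * 0 + 0.2, Fd * 0 + 0.1]))
        with pytest.raises(ValueError):
            curves.FG_star(0.9)

    def test_ordering_invariant(self, rng):
        """[FG]cg* <= [FG]* pointwise even when noise crosses them."""
        Fd = rng.uniform(0, 1, 300)
        base = 2 * Fd * (1 - Fd)
        curves = fit_emergent_curves(np.column_stack(
            [Fd, base + rng.normal(0, 0.05, 300),
             base + rng.normal(0, 0.05, 300)]))
        grid = np.linspace(*curves.F_range, 50)
        assert np.all(curves.FGcg_star(grid) <= curves.FG_star(grid) + 1e-12)


class TestSteadyStates:
    def test_engineered_roots_recovered(self):
        """Linear curves make the RHS an exact quadratic with known roots."""
        N = 100
        p = Params(**EXACT_PF, beta=0.0, gamma=0.01, alpha=0.03)
        p = p.with_phi_N(1.0, N)
        c_fg, c_fgcg = 0.5, 0.4
        # rhs = -gamma F + (1-F)(alpha c_fg - phiN pf c_fgcg (1-F))
        coeffs = [-p.phi * N * p.pf * c_fgcg,
                  -p.gamma - p.alpha * c_fg + 2 * p.phi * N * p.pf * c_fgcg,
                  p.alpha * c_fg - p.phi * N * p.pf * c_fgcg]
        true_roots = sorted(r for r in np.roots(coeffs)
                            if 0 <= r <= 1 and abs(r.imag) < 1e-12)
        roots = ode_steady_states(make_linear_curves(c_fg, c_fgcg), p, N)
        assert len(roots) == len(true_roots)
        for (got, _), want in zip(roots, true_roots):
            assert got == pytest.approx(float(want.real), abs=1e-6)

    def test_zero_is_root_when_beta_zero(self):
        p = Params(beta=0.0).with_phi_N(0.5, 100)
        curves = make_linear_curves(0.0, 0.0)
        # rhs = -gamma F: F = 0 is the only root, and it is stable
        roots = ode_steady_states(curves, p, 100)
        assert len(roots) == 1
        assert roots[0][0] == pytest.approx(0.0, abs=1e-6)
        assert roots[0][1] == "stable"

    def test_bistability_from_fitted_ensemble_curves(self, table1):
        """Curves fitted from tipping ensembles in the bistable regime give
        three roots: stable grassland, unstable saddle, stable forest."""
        from fgba import run_ensemble
        N = 30 * 30
        p = table1.with_phi_N(0.38, N)
        init = Landscape.uniform_random(30, 30, 0.45, seed=2)
        runs = run_ensemble(init, p, 150.0, n_reps=6, base_seed=2,
                            record_dt=1.0, record_interfaces=True)
        samples = np.concatenate([
            np.column_stack([tr.fractions[:, 0], tr.fg, tr.fgcg])
            for tr in runs])
        curves = fit_emergent_curves(samples)
        roots = ode_steady_states(curves, p, N)
        assert [s for _, s in roots] == ["stable", "unstable", "stable"]
        f_vals = [f for f, _ in roots]
        assert f_vals[0] < 0.1 and 0.2 < f_vals[1] < 0.6 and f_vals[2] > 0.7

    def test_no_sign_change_gives_empty_list(self):
        p = Params(beta=1.0, gamma=0.0)  # rhs > 0 except at F=1
        curves = make_linear_curves(0.0, 0.0)
        grid = np.linspace(0.1, 0.5, 20)
        sub = EmergentCurves(grid, grid * 0, grid * 0, grid, grid * 0,
                             grid * 0, grid * 0, grid * 0)
        assert ode_steady_states(sub, p, 100) == []


class TestCriticalHole:
    def test_direct_substitution(self):
        p = Params(**EXACT_PF, gamma=0.0, beta=0.0, alpha=0.03)
        assert critical_hole_size(p.with_phi_N(0.5, 100), 100) == \
            pytest.approx(0.6)

    def test_large_ignition_limit(self):
        p = Params(**EXACT_PF, gamma=0.0, beta=0.0, alpha=0.03)
        assert critical_hole_size(p.with_phi_N(1e6, 100), 100) < 1e-5

    def test_capped_at_one(self):
        p = Params(**EXACT_PF, gamma=0.0, beta=0.0, alpha=0.03)
        assert critical_hole_size(p.with_phi_N(0.01, 100), 100) == 1.0

    def test_requires_no_spontaneous_demography(self, table1):
        with pytest.raises(ValueError):
            critical_hole_size(table1.with_phi_N(0.5, 100), 100)

    def test_complement_of_unstable_root(self):
        """[G]c and the unstable root 1 - alpha/(phiN pf) sum to one."""
        p = Params(**EXACT_PF, gamma=0.0, beta=0.0, alpha=0.03)
        p = p.with_phi_N(0.8, 100)
        gc = critical_hole_size(p, 100)
        unstable_F = 1.0 - p.alpha / (p.phi * 100 * p.pf)
        assert gc + unstable_F == pytest.approx(1.0)


class TestBalancePredictsSimulatedChange:
    def test_finite_difference_regression_slope(self, table1):
        """d[F]/dt measured along simulated paths regresses on the balance
        prediction with slope ~ 1."""
        from fgba import run_ensemble
        p = table1.with_phi_N(0.6, 30 * 30)
        init = Landscape.uniform_random(30, 30, 0.45, seed=21)
        runs = run_ensemble(init, p, 60.0, n_reps=5, base_seed=21,
                            record_dt=2.0, record_interfaces=True)
        xs, ys = [], []
        for tr in runs:
            # predicted net from the recorded slow-view geometry
            Fs = tr.fractions[:, 0]
            Gs = 1.0 - Fs
            pred = (p.beta * Gs - p.gamma * Fs + p.alpha * tr.fg
                    - p.phi * p.pf * 900 * Gs * tr.fgcg)
            dFdt = np.gradient(Fs, tr.times)
            xs.append(pred[2:-2])
            ys.append(dFdt[2:-2])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        slope = np.sum(x * y) / np.sum(x * x)
        assert 0.8 < slope < 1.2
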