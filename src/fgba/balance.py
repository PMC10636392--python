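"""Macroscopic balance of forest area change.

On the slow (demographic) timescale the expected rate of change of forest
cover [F] decomposes into a gain and a loss term, both controlled by the
landscape's perimeter geometry::

    gain = beta*[G] - gamma*[F] + alpha*[FG]
    loss = phi*pf*N*[G]*[FG]cg
    d[F]/dt = gain - loss

Forest expands at its perimeter [FG] and by spontaneous recruitment; it is
eroded by fires, whose long-run damage is proportional to the total grass
area N*[G] (number of ignitions) times the grassland-weighted perimeter
[FG]cg (interface reached per ignition).  The loss term is algebraically
identical to the per-cluster sum  sum_j phi*N*[G]_j * pf*[FG]_j.

Simulated landscapes reveal that [FG] and [FG]cg collapse onto narrow bands
around functions of [F] alone (for fixed phi): fitting those emergent curves
closes the balance into a one-variable ODE whose roots are the macroscopic
steady states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .landscape import ClusterDecomposition, Landscape, grass_clusters, \
    pair_count, state_fractions, weighted_forest_perimeter
from .params import Params

__all__ = ["BalanceTerms", "EmergentCurves", "gain_rate", "loss_rate",
           "net_rate", "single_cluster_net_rate", "fit_emergent_curves",
           "ode_steady_states", "critical_hole_size"]


@dataclass(frozen=True)
class BalanceTerms:
    """Forest-area gain, loss and net rate of change (1/y); net = gain - loss."""

    gain: float
    loss: float

    @property
    def net(self) -> float:
        return self.gain - self.loss


def gain_rate(F: float, G: float, FG: float, params: Params) -> float:
    """Demographic gain beta*[G] - gamma*[F] + alpha*[FG] (1/y).

    All arguments are per-cell fractions ([FG] in pair-density units).
    """
    return params.beta * G - params.gamma * F + params.alpha * FG


def loss_rate(decomp: ClusterDecomposition, params: Params) -> float:
    """Fire-driven loss phi*pf*N*[G]*[FG]cg (1/y), from the decomposition.

    Equals the per-cluster sum  sum_j (phi*N*[G]_j) * (pf*[FG]_j)  exactly:
    ignition rate in cluster j times expected loss per fire there.
    """
    G_frac = decomp.grass_fraction
    if decomp.nc == 0 or G_frac == 0.0:
        return 0.0
    fgcg = weighted_forest_perimeter(decomp)
    return params.phi * params.pf * decomp.N * G_frac * fgcg


def net_rate(landscape: Landscape, params: Params,
             view: str = "slow") -> BalanceTerms:
    """Evaluate the balance equation on a landscape's measured geometry.

    ``view='slow'`` (default) maps burning and ash cells to grass before
    measuring geometry — the slow-timescale interpretation in which fire
    converts trees effectively straight to grass.  ``view='raw'`` uses the
    instantaneous labels.
    """
    if view == "slow":
        landscape = landscape.slow_view()
    elif view != "raw":
        raise ValueError("view must be 'slow' or 'raw'")
    frac = state_fractions(landscape)
    fg = pair_count(landscape, "F", "G")
    decomp = grass_clusters(landscape)
    return BalanceTerms(gain=gain_rate(frac.f_F, frac.f_G, fg, params),
                        loss=loss_rate(decomp, params))


def single_cluster_net_rate(F: float, FG_star_value: float, params: Params,
                            N: int) -> float:
    """Net rate under the single-grass-cluster approximation.

    When all grass forms one cluster, [FG]cg = [FG] and the balance becomes
    ``beta*G - gamma*F + (alpha - phi*pf*N*G) * [FG]*`` with G = 1 - F.
    Valid for low forest cover (roughly [F] < 0.2), where most grass belongs
    to the giant connected component.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0, 1]")
    G = 1.0 - F
    return (params.beta * G - params.gamma * F
            + (params.alpha - params.phi * params.pf * N * G) * FG_star_value)


# ---------------------------------------------------------------------------
# emergent curves
# ---------------------------------------------------------------------------

@dataclass
class EmergentCurves:
    """Nonparametric fits [FG]*(F) and [FG]cg*(F) with the scatter behind them.

    Evaluating outside the data-supported F-range raises: the curves are
    empirical and extrapolation is refused.
    """

    F_data: np.ndarray
    FG_data: np.ndarray
    FGcg_data: np.ndarray
    F_grid: np.ndarray
    FG_fit: np.ndarray
    FGcg_fit: np.ndarray
    FG_band: np.ndarray
    FGcg_band: np.ndarray

    def __post_init__(self):
        self._fg = PchipInterpolator(self.F_grid, self.FG_fit)
        self._fgcg = PchipInterpolator(self.F_grid, self.FGcg_fit)

    @property
    def F_range(self) -> tuple[float, float]:
        return float(self.F_grid[0]), float(self.F_grid[-1])

    def _check(self, F):
        F = np.asarray(F, dtype=float)
        lo, hi = self.F_range
        if np.any(F < lo - 1e-9) or np.any(F > hi + 1e-9):
            raise ValueError(f"F outside the fitted range [{lo:.3f}, {hi:.3f}]; "
                             "extrapolation refused")
        return np.clip(F, lo, hi)

    def FG_star(self, F):
        """Fitted steady-state forest perimeter [FG]*(F)."""
        return np.maximum(self._fg(self._check(F)), 0.0)

    def FGcg_star(self, F):
        """Fitted steady-state grassland-weighted perimeter [FG]cg*(F).

        Capped by [FG]*(F): the weighted perimeter can never exceed the
        plain one, and the cap keeps the interpolants ordered between grid
        nodes as well.
        """
        F = self._check(F)
        return np.minimum(np.maximum(self._fgcg(F), 0.0),
                          np.maximum(self._fg(F), 0.0))

    def residual_sd(self) -> tuple[float, float]:
        """Scatter SD around each fitted curve (a band-narrowness measure)."""
        r1 = self.FG_data - self.FG_star(self.F_data)
        r2 = self.FGcg_data - self.FGcg_star(self.F_data)
        return float(np.std(r1)), float(np.std(r2))


def _binned_fit(F, Y, grid, halfwidth):
    """Local-mean smoother on a fixed grid with clamped endpoints.

    A Nadaraya-Watson estimate with a boxcar kernel: simple, monotone-safe
    (never leaves the data's convex hull) and adequate for the dense,
    low-noise scatter the simulations produce.  Returns (fit, pointwise SE).
    """
    fit = np.empty_like(grid)
    band = np.empty_like(grid)
    for k, g in enumerate(grid):
        m = np.abs(F - g) <= halfwidth
        if m.sum() < 3:
            # widen until populated
            w = halfwidth
            while m.sum() < 3:
                w *= 1.6
                m = np.abs(F - g) <= w
        fit[k] = Y[m].mean()
        band[k] = Y[m].std(ddof=1) / np.sqrt(m.sum())
    return fit, band


def fit_emergent_curves(samples, n_grid: int = 60,
                        bandwidth: float | None = None,
                        clamp_endpoints: bool = True) -> EmergentCurves:
    """Fit the emergent curves [FG]*(F), [FG]cg*(F) from trajectory scatter.

    Parameters
    ----------
    samples
        Iterable of (F, FG, FGcg) triples — typically the record-time values
        of an ensemble of runs at fixed phi spanning an interval of [F].
        At least 50 points covering a nondegenerate F-interval are required.
    n_grid
        Number of grid points of the returned fit.
    bandwidth
        Boxcar half-width in [F] units; default = 2x the grid spacing.
    clamp_endpoints
        Pin the fits to 0 at F=0 and F=1 when the data range touches those
        endpoints (there is no interface without both species).
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("samples must be (F, FG, FGcg) triples")
    if len(arr) < 50:
        raise ValueError("need at least 50 scatter points")
    Fd, FGd, FGcgd = arr[:, 0], arr[:, 1], arr[:, 2]
    lo, hi = float(Fd.min()), float(Fd.max())
    if hi - lo < 0.02:
        raise ValueError("degenerate scatter: F-range too narrow to fit")

    # a pure landscape has no mixed interface: when the data reaches close
    # to an endpoint, extend the grid to it and pin the exact value 0 there
    # (a boundary condition, not extrapolation)
    pin_lo = clamp_endpoints and lo <= 0.02
    pin_hi = clamp_endpoints and hi >= 0.98
    grid = np.linspace(0.0 if pin_lo else lo, 1.0 if pin_hi else hi, n_grid)
    if bandwidth is None:
        bandwidth = 2.0 * (grid[-1] - grid[0]) / (n_grid - 1)
    fg_fit, fg_band = _binned_fit(Fd, FGd, grid, bandwidth)
    fgcg_fit, fgcg_band = _binned_fit(Fd, FGcgd, grid, bandwidth)

    fg_fit = np.maximum(fg_fit, 0.0)
    fgcg_fit = np.minimum(np.maximum(fgcg_fit, 0.0), fg_fit)

    if pin_lo:
        fg_fit[0] = fgcg_fit[0] = 0.0
    if pin_hi:
        fg_fit[-1] = fgcg_fit[-1] = 0.0

    return EmergentCurves(Fd, FGd, FGcgd, grid, fg_fit, fgcg_fit,
                          fg_band, fgcg_band)


def ode_steady_states(curves: EmergentCurves, params: Params, N: int,
                      n_scan: int = 400) -> list[tuple[float, str]]:
    """Roots of the emergent one-variable ODE, with stability flags.

    The right-hand side ``beta*G - gamma*F + alpha*[FG]*(F) -
    phi*pf*N*G*[FG]cg*(F)`` is scanned for sign changes over the fitted
    F-range and each bracket refined with Brent's method; stability follows
    from the sign of the numerical derivative (negative slope = stable).
    Returns a possibly empty list of (F*, 'stable'|'unstable') sorted by F*.
    """
    lo, hi = curves.F_range

    def rhs(F):
        G = 1.0 - F
        return (params.beta * G - params.gamma * F
                + params.alpha * curves.FG_star(F)
                - params.phi * params.pf * N * G * curves.FGcg_star(F))

    grid = np.linspace(lo, hi, n_scan)
    vals = np.array([rhs(x) for x in grid])
    roots: list[tuple[float, str]] = []
    h = (hi - lo) / n_scan
    for k in range(n_scan - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0:
            root = float(grid[k])
        elif a * b < 0.0:
            root = float(brentq(rhs, grid[k], grid[k + 1], xtol=1e-10))
        else:
            continue
        slope = (rhs(min(root + h, hi)) - rhs(max(root - h, lo))) / (2 * h)
        roots.append((root, "stable" if slope < 0 else "unstable"))
    # merge near-duplicates from grid-point exact zeros
    dedup: list[tuple[float, str]] = []
    for r, s in roots:
        if not dedup or r - dedup[-1][0] > 2 * h:
            dedup.append((r, s))
    return dedup


def critical_hole_size(params: Params, N: int) -> float:
    """Critical grass-hole fraction [G]c = alpha / (phi*N*pf), capped at 1.

    Valid only without spontaneous demography (gamma = beta = 0): a single
    grass hole in closed forest then closes when smaller than [G]c and grows
    without bound when larger.  Equivalently [G]c = phi_1/phi where phi_1 is
    the ignition rate at which the whole domain is the critical hole.
    """
    if params.gamma != 0.0 or params.beta != 0.0:
        raise ValueError("critical hole size is defined only for "
                         "gamma = beta = 0")
    denom = params.phi * N * params.pf
    if denom <= 0.0:
        raise ValueError("requires phi*N*pf > 0")
    return min(params.alpha / denom, 1.0)
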