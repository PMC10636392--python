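"""Mean-field approximation of the forest balance equation.

Assuming cell states are spatially uncorrelated (forest placed uniformly at
random at cover [F]) closes the balance equation: the perimeter becomes
[FG] = 4[F][G] and the grassland-weighted perimeter becomes the function
[FG]cg_u([F]) obtained by measuring the weighted perimeter on uniform-random
landscapes — there is no closed form, so it is estimated by Monte Carlo once
and tabulated.

The closed model

    dF/dt = beta*G + 4*alpha*F*G - gamma*F - phi*N*pf*G*[FG]cg_u(F)

yields analytic stable states (for beta ~ 0): F- = 0 and F+ = 1 - gamma/(4 alpha),
and — via the low-cover single-cluster limit where [FG]cg_u = [FG] = 4FG —
the onset ignition rate for bistability (phi*N)_min = (alpha - gamma/4)/pf.

Note on units: the balance equation proper keeps interfaces in pair-count
density [FG]; the mean-field form absorbs the factor 4 from
[FG]mf = 4[F][G], so its alpha term reads 4*alpha*F*G in cover-fraction
units.  Structured (non-random) landscapes from the dynamics violate the
closure: measured [FG] falls below 4[F][G] because forest aggregates —
:func:`mf_bias_check` quantifies this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .landscape import Landscape, grass_clusters, pair_count, \
    state_fractions, weighted_forest_perimeter
from .params import Params

__all__ = ["UncorrelatedPerimeterTable",
           "estimate_uncorrelated_weighted_perimeter", "mf_rate",
           "mf_low_cover_rate", "mf_stable_states", "mf_onset_ignition",
           "mf_bias_check", "mf_steady_state_roots"]


@dataclass
class UncorrelatedPerimeterTable:
    """Tabulated [FG]cg_u(F): the weighted perimeter of uncorrelated landscapes.

    ``means``/``ses`` are Monte-Carlo estimates on ``n_reps`` uniform-random
    lattices of side ``size`` per grid value of F.  Interpolation between
    grid points is monotone piecewise-cubic; the endpoints F=0 and F=1 are
    pinned to zero exactly.
    """

    F_grid: np.ndarray
    means: np.ndarray
    ses: np.ndarray
    size: int
    n_reps: int

    def __post_init__(self):
        self._interp = PchipInterpolator(self.F_grid, self.means)

    def __call__(self, F):
        F = np.asarray(F, dtype=float)
        if np.any(F < -1e-12) or np.any(F > 1.0 + 1e-12):
            raise ValueError("F outside the table range [0, 1]")
        return np.maximum(self._interp(np.clip(F, 0.0, 1.0)), 0.0)


def estimate_uncorrelated_weighted_perimeter(
        F_grid=None, size: int = 64, n_reps: int = 50,
        seed=None) -> UncorrelatedPerimeterTable:
    """Monte-Carlo table of [FG]cg_u(F) on uniform-random landscapes.

    For each F in the grid, ``n_reps`` lattices with forest placed i.i.d.
    at probability F are generated and the grassland-weighted perimeter is
    averaged.  F=0 and F=1 are included and exact (no interface).
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10 for a usable standard error")
    if size < 16:
        warnings.warn("lattices smaller than 16x16 carry strong finite-size "
                      "bias in cluster statistics", stacklevel=2)
    if F_grid is None:
        F_grid = np.linspace(0.0, 1.0, 26)
    F_grid = np.asarray(sorted(set(np.concatenate([[0.0, 1.0],
                                                   np.atleast_1d(F_grid)]))))
    rng = np.random.default_rng(seed)
    means = np.zeros_like(F_grid)
    ses = np.zeros_like(F_grid)
    for k, f in enumerate(F_grid):
        if f <= 0.0 or f >= 1.0:
            continue  # exact zeros
        vals = np.empty(n_reps)
        for r in range(n_reps):
            ls = Landscape.uniform_random(size, size, f, seed=rng)
            vals[r] = weighted_forest_perimeter(grass_clusters(ls))
        means[k] = vals.mean()
        ses[k] = vals.std(ddof=1) / np.sqrt(n_reps)
    return UncorrelatedPerimeterTable(F_grid, means, ses, size, n_reps)


def mf_rate(F, params: Params, N: int,
            table: UncorrelatedPerimeterTable) -> float:
    """Mean-field dF/dt = beta*G + 4*alpha*F*G - gamma*F - phi*N*pf*G*[FG]cg_u(F)."""
    F = float(F)
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0, 1]")
    G = 1.0 - F
    return (params.beta * G + 4.0 * params.alpha * F * G - params.gamma * F
            - params.phi * N * params.pf * G * float(table(F)))


def mf_low_cover_rate(F, params: Params, N: int) -> float:
    """Single-cluster low-cover limit: dF/dt = 4*alpha*F*G - gamma*F - 4*phi*N*pf*G^2*F.

    Valid when grass forms one giant cluster ([FG]cg_u = [FG] = 4FG) and
    beta ~ 0.  Its derivative at F=0 is 4*alpha - gamma - 4*phi*N*pf, whose
    sign change defines the onset of bistability.
    """
    F = float(F)
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0, 1]")
    G = 1.0 - F
    return (4.0 * params.alpha * F * G - params.gamma * F
            - 4.0 * params.phi * N * params.pf * G * G * F)


def mf_stable_states(params: Params) -> tuple[float, float]:
    """The two mean-field stable states (F_low, F_high) = (0, 1 - gamma/(4 alpha)).

    Grassland persists at F=0 (for beta ~ 0); at high cover fire is
    negligible and demography balances at 1 - gamma/(4 alpha), clamped to
    [0, 1] with a warning when gamma > 4 alpha (no forest state).
    """
    if params.alpha <= 0.0:
        raise ValueError("requires alpha > 0")
    F_high = 1.0 - params.gamma / (4.0 * params.alpha)
    if F_high < 0.0:
        warnings.warn("gamma > 4*alpha: mortality outpaces spread, no "
                      "high-cover state", stacklevel=2)
        F_high = 0.0
    return 0.0, F_high


def mf_onset_ignition(params: Params) -> tuple[float, float]:
    """((phi*N)_min, fire return interval 1/(phi*N)_min) for bistability onset.

    (phi*N)_min = (alpha - gamma/4) / pf: below this domain-total ignition
    rate the grassland state is unstable and forest always recovers.
    Returns (0, inf) with a warning when alpha <= gamma/4 (grassland is
    stable even without fire).
    """
    if params.pf <= 0.0:
        raise ValueError("requires pf > 0")
    val = (params.alpha - params.gamma / 4.0) / params.pf
    if val <= 0.0:
        warnings.warn("alpha <= gamma/4: no fire needed for grassland "
                      "stability", stacklevel=2)
        return 0.0, np.inf
    return val, 1.0 / val


def mf_steady_state_roots(params: Params, N: int,
                          table: UncorrelatedPerimeterTable,
                          n_scan: int = 1000) -> list[float]:
    """All roots of the mean-field rate in [0, 1] by sign-change bracketing."""
    from scipy.optimize import brentq
    grid = np.linspace(0.0, 1.0, n_scan)
    vals = np.array([mf_rate(x, params, N, table) for x in grid])
    roots = []
    for k in range(n_scan - 1):
        if vals[k] == 0.0:
            roots.append(float(grid[k]))
        elif vals[k] * vals[k + 1] < 0.0:
            roots.append(float(brentq(lambda x: mf_rate(x, params, N, table),
                                      grid[k], grid[k + 1], xtol=1e-10)))
    if vals[-1] == 0.0:
        roots.append(1.0)
    dedup = []
    for r in roots:
        if not dedup or r - dedup[-1] > 2.0 / n_scan:
            dedup.append(r)
    return dedup


def mf_bias_check(landscapes) -> dict:
    """Check the aggregation inequality [FG] < 4[F][G] over an ensemble.

    Structured landscapes produced by the dynamics have forest clumped
    together, so their perimeter falls below the uncorrelated value; each
    landscape with 0 < [F] < 1 is tested and the violation fraction
    reported.  Returns a dict with per-landscape arrays and summary counts.
    """
    fg = []
    fg_mf = []
    for ls in landscapes:
        sv = ls.slow_view()
        f = state_fractions(sv).f_F
        fg.append(pair_count(sv, "F", "G"))
        fg_mf.append(4.0 * f * (1.0 - f))
    fg = np.asarray(fg)
    fg_mf = np.asarray(fg_mf)
    interior = fg_mf > 0.0
    holds = fg[interior] < fg_mf[interior]
    return {
        "fg": fg,
        "fg_mf": fg_mf,
        "n": int(interior.sum()),
        "n_holds": int(holds.sum()),
        "violation_fraction": float(1.0 - holds.mean()) if interior.any() else 0.0,
    }
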