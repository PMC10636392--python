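"""Single-fire dynamics on a frozen vegetation landscape.

On the timescale of one fire (hours), forest demography is frozen: the only
active channels are fire spread on grass (rho_g per burning-grass pair),
fire intrusion into forest (rho_f per burning-forest pair) and spontaneous
extinction (B->A at mu).  A fire ignited in grass cluster j burns through
(part of) that cluster, reaches its forest interface, and removes forest
there.

Two descriptions of the expected forest loss per fire are provided and meant
to be compared:

* :func:`simulate_fire_event` — exact Monte Carlo of the restricted chain,
  in which burning forest cells do spread the fire further;
* :func:`expected_fire_loss` — the analytic approximation pf * [FG]_j (and
  its exact-exposure refinement), which assumes the fire sweeps the whole
  interface exactly once (pg -> 1) and that burning forest does not
  propagate (small pf).

The gap between the two quantifies the validity of the analytic form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._sumtree import SumTree
from .landscape import A, B, F, G, ClusterDecomposition, Landscape
from .params import Params
from .simulate import _neighbour_table

__all__ = ["FireEventResult", "simulate_fire_event",
           "forest_cell_burn_probability", "expected_fire_loss",
           "ApproximationValidityWarning"]


class ApproximationValidityWarning(UserWarning):
    """The single-sweep fire-loss approximation is outside its validity regime."""


@dataclass
class FireEventResult:
    """Outcome of one fire realization.

    ``burned_grass`` / ``burned_forest`` are flat cell indices that burned
    (they end as ash); ``forest_lost`` is ``len(burned_forest)`` and
    ``forest_lost_fraction`` the same divided by N.  ``duration`` is the time
    from ignition until the last cell stopped burning (years).
    """

    ignition_cell: int
    burned_grass: np.ndarray
    burned_forest: np.ndarray
    duration: float

    @property
    def forest_lost(self) -> int:
        return len(self.burned_forest)

    def forest_lost_fraction(self, N: int) -> float:
        return self.forest_lost / N


def simulate_fire_event(landscape: Landscape, params: Params,
                        ignition_cell, seed=None) -> FireEventResult:
    """Exact realization of a single fire: ignite, spread, burn out.

    Runs the chain restricted to {G->B, F->B, B->A} until no cell burns.
    The input landscape is not modified.  ``ignition_cell`` may be a flat
    index or an (row, col) pair and must hold grass.
    """
    height, width = landscape.cells.shape
    n = height * width
    if not np.isscalar(ignition_cell) and not isinstance(ignition_cell, (int, np.integer)):
        r, c = ignition_cell
        ignition_cell = int(r) * width + int(c)
    ignition_cell = int(ignition_cell)
    cells = landscape.cells.ravel().copy()
    if cells[ignition_cell] != G:
        raise ValueError("ignition cell must hold grass")

    rho_g, rho_f, mu = params.rho_g, params.rho_f, params.mu
    nbrs = _neighbour_table(height, width)
    rng = np.random.default_rng(seed)

    tree = SumTree(n)

    def burning_rate(i: int) -> float:
        r = mu
        for j in nbrs[i]:
            s = cells[j]
            if s == G:
                r += rho_g
            elif s == F:
                r += rho_f
        return r

    def ignite(i: int) -> None:
        cells[i] = B
        tree.set(i, burning_rate(i))
        for j in nbrs[i]:
            if cells[j] == B:
                tree.set(j, burning_rate(j))

    burned_grass = [ignition_cell]
    burned_forest: list[int] = []
    ignite(ignition_cell)
    n_burning = 1
    t = 0.0

    while n_burning:
        total = tree.total
        t += rng.exponential(1.0 / total)
        i = tree.sample(rng.random() * total)
        if tree.get(i) <= 0.0:
            continue
        r = rng.random() * tree.get(i)
        if r < mu:
            # extinction
            cells[i] = A
            tree.set(i, 0.0)
            for j in nbrs[i]:
                if cells[j] == B:
                    tree.set(j, burning_rate(j))
            n_burning -= 1
            continue
        r -= mu
        target = -1
        for j in nbrs[i]:
            s = cells[j]
            if s == G:
                if r < rho_g:
                    target = j
                    break
                r -= rho_g
            elif s == F:
                if r < rho_f:
                    target = j
                    break
                r -= rho_f
        if target < 0:
            continue  # float edge; null event
        (burned_grass if cells[target] == G else burned_forest).append(target)
        ignite(target)
        n_burning += 1

    return FireEventResult(
        ignition_cell=ignition_cell,
        burned_grass=np.array(sorted(burned_grass), dtype=np.int64),
        burned_forest=np.array(sorted(burned_forest), dtype=np.int64),
        duration=t,
    )


def forest_cell_burn_probability(fg_ij: int, pf: float,
                                 linearized: bool = False) -> float:
    """Probability an interface forest cell burns during a cluster-wide fire.

    A forest cell with ``fg_ij`` grass neighbours in the burning cluster
    escapes only if none of those exposures spreads, hence
    ``q = 1 - (1-pf)**fg_ij``; ``linearized=True`` returns the small-pf form
    ``pf * fg_ij`` instead.
    """
    if not 0.0 <= pf <= 1.0:
        raise ValueError("pf must be a probability in [0, 1]")
    fg_ij = int(fg_ij)
    if not 0 <= fg_ij <= 4:
        raise ValueError("fg_ij must be an exposure count in 0..4")
    if linearized:
        return pf * fg_ij
    return 1.0 - (1.0 - pf) ** fg_ij


def expected_fire_loss(decomp: ClusterDecomposition, j: int, pf: float,
                       landscape: Landscape | None = None,
                       exact: bool = False, pg: float | None = None) -> float:
    """Expected forest-loss fraction from one fire in grass cluster j.

    The default is the linearized single-sweep form ``pf * [FG]_j`` (per-cell
    normalized, matching the decomposition's fractions).  With
    ``exact=True`` (requires ``landscape``), the per-forest-cell exposure
    counts are enumerated and the exact escape probabilities summed; this is
    never larger than the linearized value.

    The analytic form assumes the fire sweeps the whole interface (pg close
    to 1) exactly once; pass ``pg`` to get a warning when pg < 0.9.
    """
    if not 1 <= j <= decomp.nc:
        raise ValueError(f"cluster index {j} out of range 1..{decomp.nc}")
    if not 0.0 <= pf <= 1.0:
        raise ValueError("pf must be a probability in [0, 1]")
    if pg is not None and pg < 0.9:
        warnings.warn(f"pg={pg:.3f} < 0.9: the whole-interface sweep "
                      "assumption is unreliable", ApproximationValidityWarning,
                      stacklevel=2)
    if not exact:
        return pf * float(decomp.fg_fractions[j - 1])
    if landscape is None:
        raise ValueError("exact=True requires the landscape")
    # exposure count of every forest cell to cluster j
    height, width = landscape.cells.shape
    is_forest = landscape.cells == F
    in_cluster = decomp.labels == j
    exposures = np.zeros((height, width), dtype=np.int64)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        exposures += np.roll(in_cluster, shift, axis=axis)
    k = exposures[is_forest]
    k = k[k > 0]
    return float(np.sum(1.0 - (1.0 - pf) ** k)) / decomp.N
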