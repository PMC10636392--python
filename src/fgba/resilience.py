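"""Landscape perturbations and the forest-feedback sensitivity indicator.

The balance equation assigns every landscape an expected rate of forest
change.  Perturbing the landscape and comparing rates before and after
yields the sensitivity

    lambda_F = (Fdot(perturbed) - Fdot(X)) / ([F](perturbed) - [F](X)),

the approximate derivative of the emergent one-variable dynamics at [F](X).
Negative values mean perturbations are dampened (the landscape sits in a
potential well); positive values mean amplification — the fire-vegetation
feedback pushes the landscape further from where it started.  Averaging the
numerator and denominator separately over an ensemble of naturally occurring
perturbations, weighted by their rates of occurrence, gives the robust
ensemble indicator lambda_F-bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import net_rate
from .landscape import F, G, Landscape, grass_clusters, state_fractions
from .params import Params

__all__ = ["PerturbationSpec", "apply_perturbation", "sensitivity",
           "mean_sensitivity", "default_perturbation_ensemble"]

KINDS = ("remove_perimeter_forest", "add_perimeter_forest",
         "random_mortality", "random_recruitment")


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation family.

    ``magnitude`` is the fraction of eligible cells flipped (in (0, 1]);
    ``weight`` is the rate/probability with which the corresponding natural
    process occurs, used by :func:`mean_sensitivity`.
    """

    kind: str
    magnitude: float
    weight: float = 1.0
    seed: object = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}; "
                             f"expected one of {KINDS}")
        if not 0.0 < self.magnitude <= 1.0:
            raise ValueError("magnitude must be in (0, 1]")
        if self.weight < 0.0:
            raise ValueError("weight must be >= 0")


def _eligible(landscape: Landscape, kind: str) -> np.ndarray:
    """Flat indices of cells the perturbation may flip."""
    cells = landscape.cells
    if kind == "random_mortality":
        return np.flatnonzero(cells.ravel() == F)
    if kind == "random_recruitment":
        return np.flatnonzero(cells.ravel() == G)
    decomp = grass_clusters(landscape)
    if decomp.nc == 0:
        return np.array([], dtype=np.int64)
    big = decomp.largest_cluster()
    in_big = decomp.labels == big
    if kind == "remove_perimeter_forest":
        # forest cells bordering the largest grass cluster
        target = cells == F
    else:  # add_perimeter_forest: cluster grass cells bordering forest
        target = in_big
        in_big = cells == F
    border = np.zeros_like(target)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        border |= np.roll(in_big, shift, axis=axis)
    return np.flatnonzero((target & border).ravel())


def apply_perturbation(landscape: Landscape,
                       spec: PerturbationSpec) -> Landscape:
    """Return a perturbed copy of the landscape (deterministic given seed).

    ``remove_perimeter_forest`` flips forest cells bordering the largest
    grass cluster to grass; ``add_perimeter_forest`` flips that cluster's
    grass cells bordering forest to forest; the random kinds flip a uniform
    sample of all forest (to G) or grass (to F) cells.  The number flipped
    is ``ceil(magnitude * n_eligible)``, so a vanishing magnitude still
    flips one cell.
    """
    eligible = _eligible(landscape, spec.kind)
    if len(eligible) == 0:
        raise ValueError(f"no eligible cells for perturbation {spec.kind!r}")
    k = int(np.ceil(spec.magnitude * len(eligible)))
    rng = np.random.default_rng(spec.seed)
    chosen = eligible if k >= len(eligible) else rng.choice(eligible, size=k,
                                                            replace=False)
    cells = landscape.cells.copy()
    flat = cells.ravel()
    new_label = G if spec.kind in ("remove_perimeter_forest",
                                   "random_mortality") else F
    flat[chosen] = new_label
    return Landscape(cells)


def sensitivity(landscape: Landscape, perturbed: Landscape,
                params: Params) -> float:
    """lambda_F for one perturbation: Delta(Fdot) / Delta([F]).

    Both landscapes are evaluated through the balance equation's
    slow-timescale view.  Negative = dampening, positive = amplification.
    """
    f0 = state_fractions(landscape.slow_view()).f_F
    f1 = state_fractions(perturbed.slow_view()).f_F
    dF = f1 - f0
    if dF == 0.0:
        raise ValueError("perturbation does not change [F]")
    d_net = net_rate(perturbed, params).net - net_rate(landscape, params).net
    return d_net / dF


def mean_sensitivity(landscape: Landscape, specs, params: Params,
                     n_realizations: int = 64, seed=None) -> float:
    """Weighted ensemble sensitivity lambda_F-bar.

    Computed as the ratio of weighted sums
    ``sum_i w_i Delta(Fdot)_i / sum_i w_i Delta([F])_i`` — not the weighted
    mean of per-perturbation ratios — over ``n_realizations`` seeded
    realizations of each spec.  Doubling all weights leaves the result
    unchanged.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one perturbation spec")
    if all(s.weight == 0.0 for s in specs):
        raise ValueError("all perturbation weights are zero")
    base = net_rate(landscape, params).net
    f0 = state_fractions(landscape.slow_view()).f_F
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child = iter(ss.spawn(len(specs) * n_realizations))
    num = 0.0
    den = 0.0
    for spec in specs:
        for _ in range(n_realizations):
            pert = apply_perturbation(
                landscape, PerturbationSpec(spec.kind, spec.magnitude,
                                            spec.weight, next(child)))
            dF = state_fractions(pert.slow_view()).f_F - f0
            ddot = net_rate(pert, params).net - base
            num += spec.weight * ddot
            den += spec.weight * dF
    if den == 0.0:
        raise ValueError("degenerate ensemble: weighted [F] change is zero")
    return num / den


def default_perturbation_ensemble(params: Params, N: int,
                                  magnitude: float = 0.1) -> list[PerturbationSpec]:
    """The four natural perturbation families with rate-proportional weights.

    Perimeter removal is weighted by the fire-loss rate scale phi*N*pf,
    perimeter addition by forest spread alpha, random mortality by gamma and
    random recruitment by beta.  The magnitude (fraction of eligible cells
    flipped) is a modelling choice with no canonical value; 0.1 keeps the
    perturbations small enough to probe local stability.
    """
    return [
        PerturbationSpec("remove_perimeter_forest", magnitude,
                         weight=params.phi * N * params.pf),
        PerturbationSpec("add_perimeter_forest", magnitude,
                         weight=params.alpha),
        PerturbationSpec("random_mortality", magnitude, weight=params.gamma),
        PerturbationSpec("random_recruitment", magnitude, weight=params.beta),
    ]
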