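"""Model rate constants and derived fire-spread probabilities.

All rates are per year.  The defaults are the empirically motivated values
for a 30 m-cell tropical forest-grassland lattice: fire spread and
extinction act on the scale of hours (rho_g, rho_f, mu ~ 1e5–1e6 /y), grass
regrows on ash over months (lam ~ 5 /y), and forest demography — spread,
recruitment, mortality — plays out over decades (alpha, beta, gamma ~
1e-4–1e-2 /y).  The ignition rate phi is per grass cell; figures and
configuration usually quote the domain-total rate phi*N instead, so helpers
for that convention are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = ["Params", "TimescaleWarning", "spread_probabilities"]


class TimescaleWarning(UserWarning):
    """Rates violate the fast-fire / slow-demography timescale ordering."""


@dataclass(frozen=True)
class Params:
    """The eight reaction rates of the forest-grass-fire automaton (1/y).

    Channels: spontaneous G,A->F (beta), F->G (gamma), G->B (phi), B->A (mu),
    A->G (lam); per-neighbour-pair spread G,A->F at alpha per F neighbour,
    G->B at rho_g per B neighbour, F->B at rho_f per B neighbour.
    """

    alpha: float = 3e-2      # forest spread per GF/AF pair
    beta: float = 2e-4       # spontaneous recruitment G/A -> F
    gamma: float = 2e-2      # spontaneous mortality F -> G
    phi: float = 0.0         # fire ignition per G cell
    lam: float = 5.0         # grass regrowth A -> G
    mu: float = 1e6          # fire extinction B -> A
    rho_g: float = 9e6       # fire spread per GB pair
    rho_f: float = 1.11e5    # fire spread per FB pair

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "phi", "lam", "mu", "rho_g", "rho_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    @property
    def pg(self) -> float:
        """Probability fire spreads into a neighbouring grass cell before extinction."""
        return spread_probabilities(self)[0]

    @property
    def pf(self) -> float:
        """Probability fire spreads into a neighbouring forest cell before extinction."""
        return spread_probabilities(self)[1]

    def phi_N(self, N: int) -> float:
        """Domain-total ignition rate phi*N for a lattice of N cells."""
        return self.phi * N

    def with_phi_N(self, phi_N: float, N: int) -> "Params":
        """Copy with per-cell phi set from a domain-total rate phi*N."""
        if N <= 0:
            raise ValueError("N must be positive")
        return replace(self, phi=phi_N / N)

    def replace(self, **kwargs) -> "Params":
        return replace(self, **kwargs)

    def validate_timescales(self) -> None:
        """Warn (never raise) when the timescale ordering is broken.

        The fast-slow analysis assumes rho_g, mu ~ 1e6 > rho_f ~ 1e5 >> 1/y
        and alpha, beta, gamma << lam ~ 1/y: fires must be effectively
        instantaneous relative to grass regrowth, which in turn is fast
        relative to forest demography.
        """
        fast = min(self.mu, self.rho_g)
        if self.rho_f and not (fast > self.rho_f):
            warnings.warn("expected rho_g, mu > rho_f", TimescaleWarning, stacklevel=2)
        if self.rho_f and not (self.rho_f >= 100 * self.lam):
            warnings.warn("fire spread not well separated from grass regrowth "
                          "(rho_f should be >> lam)", TimescaleWarning, stacklevel=2)
        slow = max(self.alpha, self.beta, self.gamma)
        if slow and self.lam and not (self.lam >= 10 * slow):
            warnings.warn("forest demography not well separated from grass "
                          "regrowth (alpha,beta,gamma should be << lam)",
                          TimescaleWarning, stacklevel=2)

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma,
                "phi": self.phi, "lam": self.lam, "mu": self.mu,
                "rho_g": self.rho_g, "rho_f": self.rho_f}


def spread_probabilities(params: Params) -> tuple[float, float]:
    """(pg, pf): per-pair probabilities of fire spreading before extinction.

    A burning cell ignites a given grass (forest) neighbour with rate rho_g
    (rho_f) and stops burning with rate mu; the race between the two
    exponential clocks gives pg = rho_g/(rho_g+mu) and pf = rho_f/(rho_f+mu).
    """
    if params.rho_g + params.mu <= 0 or params.rho_f + params.mu <= 0:
        raise ValueError("spread probabilities undefined when both spread "
                         "and extinction rates are zero")
    pg = params.rho_g / (params.rho_g + params.mu)
    pf = params.rho_f / (params.rho_f + params.mu)
    return pg, pf
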