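"""Run configuration: YAML round-trip with validated rate defaults.

The ignition rate may be given either per cell (``phi``) or as the
domain-total rate ``phiN`` quoted in figures; the configuration stores the
per-cell value and echoes both on save so the N-ambiguity is always
explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .params import Params

__all__ = ["RunConfig", "load_config", "save_config"]

_PARAM_KEYS = ("alpha", "beta", "gamma", "phi", "lam", "mu", "rho_g", "rho_f")
_TOP_KEYS = {"params", "width", "height", "init", "forest_fraction",
             "hole_fraction", "t_end", "record_dt", "seed", "out_dir",
             "phiN"}
_INIT_KINDS = ("all_grass", "all_forest", "uniform_random", "forest_with_hole")


@dataclass
class RunConfig:
    """Validated simulation run configuration with rate defaults built in."""

    params: Params = field(default_factory=Params)
    width: int = 100
    height: int = 100
    init: str = "all_grass"
    forest_fraction: float = 0.5
    hole_fraction: float = 0.1
    t_end: float = 400.0
    record_dt: float = 0.5
    seed: int = 0
    out_dir: str = "fgba_out"

    def __post_init__(self):
        if self.init not in _INIT_KINDS:
            raise ValueError(f"unknown init {self.init!r}; expected one of "
                             f"{_INIT_KINDS}")
        if self.width < 2 or self.height < 2:
            raise ValueError("lattice dimensions must be >= 2")
        if self.t_end <= 0 or self.record_dt <= 0:
            raise ValueError("t_end and record_dt must be positive")

    @property
    def N(self) -> int:
        return self.width * self.height

    def initial_landscape(self):
        from .landscape import Landscape
        if self.init == "all_grass":
            return Landscape.all_grass(self.width, self.height)
        if self.init == "all_forest":
            return Landscape.all_forest(self.width, self.height)
        if self.init == "uniform_random":
            return Landscape.uniform_random(self.width, self.height,
                                            self.forest_fraction,
                                            seed=self.seed)
        return Landscape.forest_with_hole(self.width, self.height,
                                          self.hole_fraction)

    def as_dict(self) -> dict:
        d = {"params": self.params.as_dict(),
             "width": self.width, "height": self.height, "init": self.init,
             "forest_fraction": self.forest_fraction,
             "hole_fraction": self.hole_fraction, "t_end": self.t_end,
             "record_dt": self.record_dt, "seed": self.seed,
             "out_dir": self.out_dir}
        d["phiN"] = self.params.phi * self.N
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Omitted rates fall back to the defaults; unknown keys and negative rates
    raise with the offending key named.  ``phiN`` (domain total) may be
    given instead of ``params.phi`` and is converted using width*height.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    praw = dict(raw.get("params") or {})
    unknown = set(praw) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown rate keys: {sorted(unknown)}")
    for k, v in praw.items():
        if v < 0:
            raise ValueError(f"rate {k!r} must be >= 0, got {v}")
    params = Params(**{k: float(v) for k, v in praw.items()})
    kwargs = {k: raw[k] for k in raw if k in _TOP_KEYS - {"params", "phiN"}}
    cfg = RunConfig(params=params, **kwargs)
    if "phiN" in raw:
        if raw["phiN"] < 0:
            raise ValueError("rate 'phiN' must be >= 0")
        phiN = float(raw["phiN"])
        if "phi" in praw:
            if abs(params.phi * cfg.N - phiN) > 1e-9 * max(1.0, phiN):
                raise ValueError("params.phi and phiN are inconsistent")
        else:
            cfg.params = params.with_phi_N(phiN, cfg.N)
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    """Write a config to YAML; ``load_config`` round-trips it losslessly."""
    d = cfg.as_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
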