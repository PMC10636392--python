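"""Noninvasive feedback control: stabilizing and measuring unstable equilibria.

A saddle state of the forest-grassland system cannot be observed in a plain
simulation — trajectories started there tip away.  Making the ignition rate
a function of the state,

    phi(t) = phi0 + g * ([F](t) - F_ref),        (clamped at 0)

introduces a stabilizing feedback: excess forest raises fire pressure and
vice versa.  At a controlled equilibrium the feedback term averages to zero,
so the measured pair (phi_bar, [F]_bar) is an equilibrium of the *uncontrolled*
system — the control is noninvasive.  Sweeping F_ref traces the unstable
branch of the bifurcation diagram; stable branches come from regular runs.

Equilibrium values are time averages over a window after burn-in:
[F]_bar is the event-exact integral mean, and phi_bar is estimated from the
realized ignition count n(G->B) as  phi_bar = (n/T) / [G]_bar  — the number
of ignitions per year per average grass cell.  Confidence intervals use the
moving-block bootstrap to respect serial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape
from .params import Params
from .simulate import Trajectory, simulate

__all__ = ["ControlConfig", "BifurcationBranch", "controlled_simulate",
           "equilibrium_estimate", "measure_saddle", "trace_branch",
           "block_bootstrap_ci", "auto_gain"]


@dataclass(frozen=True)
class ControlConfig:
    """Feedback-control and averaging configuration.

    ``phi0``: base per-cell ignition rate (1/y); ``gain``: feedback gain g
    (1/y per unit [F]); ``F_ref``: target forest fraction; ``t0``: burn-in
    before averaging (y); ``T``: averaging window (y).
    """

    phi0: float
    gain: float
    F_ref: float
    t0: float = 100.0
    T: float = 200.0

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("averaging window T must be positive")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if not 0.0 <= self.F_ref <= 1.0:
            raise ValueError("F_ref must be in [0, 1]")


def auto_gain(params: Params, N: int, phi0: float) -> float:
    """Heuristic feedback gain: full modulation of phi over a 0.01 excursion.

    Positive sign (more forest -> more fire, which opposes the runaway), and
    magnitude such that a deviation of 0.01 in [F] already changes the
    ignition rate by about its base value — roughly ten times the slope
    needed to flip the sign of the saddle eigenvalue, so the state is pinned
    near F_ref instead of drifting into the nonlinear regime where fire
    damage saturates.  Problem specific; always overridable.
    """
    return 100.0 * max(phi0, 0.25 / N)


def controlled_simulate(landscape: Landscape, params: Params,
                        cfg: ControlConfig, t_end: float | None = None,
                        seed=None, **kwargs) -> Trajectory:
    """Simulate with the feedback law phi(t) = phi0 + g([F](t) - F_ref).

    Identical to :func:`fgba.simulate.simulate` except that the ignition
    propensity tracks [F] after every forest-count-changing event (clamped
    at zero; a warning fires when clamping is active most of the run).
    The trajectory's ``phi_series`` records the effective phi at each record
    time.  ``t_end`` defaults to ``cfg.t0 + cfg.T``.
    """
    if t_end is None:
        t_end = cfg.t0 + cfg.T
    if t_end < cfg.t0 + cfg.T:
        raise ValueError("t_end must cover the burn-in plus averaging window")
    p = params.replace(phi=cfg.phi0)
    return simulate(landscape, p, t_end, seed=seed,
                    control=(cfg.gain, cfg.F_ref), **kwargs)


def equilibrium_estimate(trajectory: Trajectory, cfg: ControlConfig
                         ) -> tuple[float, float]:
    """(phi_bar * N, [F]_bar) from the averaging window [t0, t0+T].

    [F]_bar (and [G]_bar) are exact time-weighted averages — integrals of the
    piecewise-constant fraction series, not sample means.  phi_bar is the
    realized ignition count in the window divided by T and by [G]_bar.
    """
    t0, T = cfg.t0, cfg.T
    F_bar = trajectory.window_average_F(t0, T)
    G_bar = trajectory.window_average_G(t0, T)
    if G_bar <= 0.0:
        raise ValueError("no grass in the averaging window; phi_bar undefined")
    tt = trajectory.ignition_times
    n_ign = int(np.count_nonzero((tt >= t0) & (tt <= t0 + T)))
    # n/T = phi * N * [G]_bar at equilibrium, so dividing by [G]_bar gives
    # the domain-total rate phi*N directly
    phiN_bar = (n_ign / T) / G_bar
    return phiN_bar, F_bar


def block_bootstrap_ci(series, block_length: int, n_boot: int = 500,
                       seed=None, level: float = 0.95) -> float:
    """Moving-block-bootstrap CI half-width for the mean of a dependent series.

    Overlapping blocks of ``block_length`` consecutive values are resampled
    with replacement and concatenated to the original length; the half-width
    is half the distance between the (1±level)/2 quantiles of the bootstrap
    means.  Requires ``len(series) >= 2 * block_length``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    block_length = int(block_length)
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if n < 2 * block_length:
        raise ValueError("series too short for the requested block length")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_length))
    starts = rng.integers(0, n - block_length + 1, size=(n_boot, n_blocks))
    # gather blocks: shape (n_boot, n_blocks, block_length)
    idx = starts[:, :, None] + np.arange(block_length)[None, None, :]
    means = x[idx].reshape(n_boot, -1)[:, :n].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float((hi - lo) / 2.0)


def measure_saddle(params: Params, width: int, F_ref: float, phi0_N: float,
                   *, height: int | None = None, settle_T: float = 60.0,
                   measure_t0: float = 40.0, measure_T: float = 400.0,
                   settle_gain_mult: float = 40.0,
                   measure_gain_mult: float = 20.0, record_dt: float = 0.5,
                   snapshot_dt: float = 4.0, seed=0,
                   init: Landscape | None = None):
    """Two-stage saddle measurement: strong-gain settling, weak-gain averaging.

    Stage one pins the state near ``F_ref`` with a stiff feedback gain so the
    landscape relaxes onto saddle-type geometry; its rough (phi_bar, F_bar)
    re-centres stage two, which measures with a gain just strong enough to
    stabilize.  The weak measurement gain matters because the equilibrium
    estimator divides an ignition count by the mean grass cover: with heavy
    phi(t) modulation the ignitions oversample high-phi episodes and the
    estimate no longer matches the constant-phi system.  A long window keeps
    the Poisson error of the ignition count small.

    Returns ``(phiN_bar, F_bar, trajectory)`` where the trajectory is the
    stage-two run with landscape snapshots every ``snapshot_dt`` years in
    the averaging window.
    """
    height = width if height is None else height
    N = width * height
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    s1, s2, s3 = ss.spawn(3)
    if init is None:
        init = Landscape.uniform_random(width, height, F_ref, seed=s1)
    cfg1 = ControlConfig(phi0=phi0_N / N, gain=settle_gain_mult * phi0_N / N,
                         F_ref=F_ref, t0=settle_T / 2, T=settle_T / 2)
    tr1 = controlled_simulate(init, params, cfg1, seed=s2,
                              record_dt=record_dt)
    phiN1, F1 = equilibrium_estimate(tr1, cfg1)
    if phiN1 <= 0.0:
        phiN1, F1 = phi0_N, F_ref
    cfg2 = ControlConfig(phi0=phiN1 / N, gain=measure_gain_mult * phiN1 / N,
                         F_ref=F1, t0=measure_t0, T=measure_T)
    snaps = np.arange(measure_t0, measure_t0 + measure_T + 1e-9, snapshot_dt)
    tr2 = controlled_simulate(tr1.final.slow_view(), params, cfg2, seed=s3,
                              record_dt=record_dt, snapshot_times=snaps)
    phiN2, F2 = equilibrium_estimate(tr2, cfg2)
    return phiN2, F2, tr2


@dataclass
class BifurcationBranch:
    """Traced equilibrium points (phi_bar*N, [F]_bar) with stability and CIs.

    Points are sorted by phi_bar*N.  ``converged`` flags points where the
    controlled run settled near its target; non-convergent points are kept
    but flagged, never fabricated.
    """

    phiN: np.ndarray
    F: np.ndarray
    stability: list
    ci_F: np.ndarray
    gains: np.ndarray
    seeds: list
    converged: np.ndarray
    meta: dict = field(default_factory=dict)

    def stable_points(self):
        m = np.array([s == "stable" for s in self.stability])
        return self.phiN[m], self.F[m]

    def unstable_points(self):
        m = np.array([s == "unstable" for s in self.stability])
        return self.phiN[m], self.F[m]


def trace_branch(params: Params, width: int, f_refs, phi0_N: float,
                 gains=None, *, stable_phiN=(), t0: float = 100.0,
                 T: float = 200.0, record_dt: float = 0.5,
                 base_seed: int = 0, block_length: int = 50,
                 height: int | None = None) -> BifurcationBranch:
    """Trace the bifurcation diagram of equilibria versus ignition rate.

    Unstable (saddle) points: for each target fraction in ``f_refs``, a
    controlled run starts from a uniform-random landscape at that fraction
    with base ignition rate ``phi0_N`` (domain total); the equilibrium is the
    window average.  Stable points: regular runs from all-forest and
    all-grass at each ignition rate in ``stable_phiN``.

    ``gains`` is a scalar, a sequence matching ``f_refs``, or None for the
    :func:`auto_gain` heuristic.  Raises on an empty gain sequence.
    """
    f_refs = list(f_refs)
    if not f_refs:
        raise ValueError("f_refs grid must be nonempty")
    height = width if height is None else height
    N = width * height
    if gains is None:
        gains = [auto_gain(params, N, phi0_N / N)] * len(f_refs)
    elif np.isscalar(gains):
        gains = [float(gains)] * len(f_refs)
    else:
        gains = [float(g) for g in gains]
        if not gains:
            raise ValueError("gain list must be nonempty")
        if len(gains) != len(f_refs):
            raise ValueError("gains must match f_refs in length")

    rows = []
    ss = np.random.SeedSequence(base_seed)
    children = iter(ss.spawn(len(f_refs) + 2 * len(tuple(stable_phiN))))

    for f_ref, g in zip(f_refs, gains):
        seed = next(children)
        g_mult = g / (phi0_N / N)
        phiN_bar, F_bar, traj = measure_saddle(
            params, width, f_ref, phi0_N, height=height,
            settle_T=t0, measure_t0=t0, measure_T=T,
            measure_gain_mult=g_mult / 2, settle_gain_mult=g_mult,
            record_dt=record_dt, seed=seed)
        window = (traj.times >= t0)
        ci = block_bootstrap_ci(traj.fractions[window, 0], block_length,
                                seed=seed.spawn(1)[0])
        converged = abs(F_bar - f_ref) < 0.15
        rows.append((phiN_bar, F_bar, "unstable", ci, g, seed, converged))

    for phiN in stable_phiN:
        for init in (Landscape.all_forest(width, height),
                     Landscape.all_grass(width, height)):
            seed = next(children)
            p = params.with_phi_N(phiN, N)
            traj = simulate(init, p, t0 + T, seed=seed, record_dt=record_dt)
            cfg = ControlConfig(phi0=p.phi, gain=0.0, F_ref=0.0, t0=t0, T=T)
            _, F_bar = equilibrium_estimate(traj, cfg)
            window = (traj.times >= t0)
            ci = block_bootstrap_ci(traj.fractions[window, 0], block_length,
                                    seed=seed.spawn(1)[0])
            rows.append((phiN, F_bar, "stable", ci, 0.0, seed, True))

    rows.sort(key=lambda r: (r[0], r[1]))
    return BifurcationBranch(
        phiN=np.array([r[0] for r in rows]),
        F=np.array([r[1] for r in rows]),
        stability=[r[2] for r in rows],
        ci_F=np.array([r[3] for r in rows]),
        gains=np.array([r[4] for r in rows]),
        seeds=[r[5] for r in rows],
        converged=np.array([r[6] for r in rows]),
        meta={"t0": t0, "T": T, "width": width, "height": height},
    )
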