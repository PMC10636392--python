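"""Exact continuous-time (Gillespie) simulation of the forest-grass-fire automaton.

The lattice state is a continuous-time Markov chain.  Each cell carries a
propensity equal to the sum of its conversion channels:

======  =============================================================
state   channels (rate)
======  =============================================================
F       F->G (gamma); F->B (rho_f per burning neighbour)
G       G->F (beta + alpha per forest neighbour); G->B (phi ignition;
        rho_g per burning neighbour)
B       B->A (mu)
A       A->F (beta + alpha per forest neighbour); A->G (lam)
======  =============================================================

Sampling is the direct method with a binary sum tree over per-cell
propensities, so each event costs O(log N) and only the event's neighbourhood
is touched.  The ignition channel (phi per grass cell) is kept out of the
tree as a single global channel phi * nG: this makes state-dependent phi —
the feedback-control law used for unstable-branch tracing — an O(1) update.
Rates in this system span ten orders of magnitude; the direct method is
exact regardless, and elapsed time is accumulated with compensated
summation so that ~1e7 tiny fire-timescale increments do not lose precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._sumtree import SumTree
from .landscape import A, B, F, G, Landscape, grass_clusters, pair_count, \
    weighted_forest_perimeter
from .params import Params

__all__ = ["Trajectory", "simulate", "run_ensemble", "CHANNELS"]

#: Event-log channel names.
CHANNELS = ("G->F", "A->F", "F->G", "G->B ignition", "G->B spread",
            "F->B", "B->A", "A->G")

_REBUILD_EVERY = 1_000_000


@dataclass
class Trajectory:
    """Recorded output of one simulation run.

    ``times`` are the record times (strictly increasing, starting at 0 and
    ending at ``t_end``); ``fractions`` holds the instantaneous cover
    fractions [F], [G], [B], [A] at those times.  ``cum_F`` and ``cum_G``
    are the event-exact integrals of [F](t) and [G](t) from 0 to each record
    time, enabling exact time averages over any window aligned with the
    record grid.  ``ignition_times`` lists every spontaneous G->B event.
    """

    times: np.ndarray
    fractions: np.ndarray
    cum_F: np.ndarray
    cum_G: np.ndarray
    cum_phi: np.ndarray
    ignition_times: np.ndarray
    event_counts: dict
    seed: object
    params: Params
    final: Landscape
    fg: np.ndarray | None = None
    fgcg: np.ndarray | None = None
    phi_series: np.ndarray | None = None
    snapshots: dict = field(default_factory=dict)

    @property
    def n_ignitions(self) -> int:
        return len(self.ignition_times)

    def fraction(self, label: int) -> np.ndarray:
        return self.fractions[:, label]

    def window_average_F(self, t0: float, T: float) -> float:
        """Exact time average of [F] over [t0, t0+T] (Kahan-free: differenced
        cumulative integrals, linearly interpolated within record intervals)."""
        return _window_average(self.times, self.cum_F, t0, T)

    def window_average_G(self, t0: float, T: float) -> float:
        return _window_average(self.times, self.cum_G, t0, T)

    def window_average_phi(self, t0: float, T: float) -> float:
        """Exact time average of the (possibly state-dependent) per-cell phi."""
        return _window_average(self.times, self.cum_phi, t0, T)


def _window_average(times, cum, t0, T):
    if T <= 0:
        raise ValueError("averaging window T must be positive")
    if t0 < times[0] - 1e-12 or t0 + T > times[-1] + 1e-9:
        raise ValueError("averaging window not covered by the trajectory")
    hi = min(t0 + T, times[-1])
    c0 = float(np.interp(t0, times, cum))
    c1 = float(np.interp(hi, times, cum))
    return (c1 - c0) / (hi - t0)


def _neighbour_table(height: int, width: int) -> list[tuple[int, ...]]:
    n = height * width
    nbrs = []
    for i in range(n):
        r, c = divmod(i, width)
        nbrs.append((((r - 1) % height) * width + c,
                     ((r + 1) % height) * width + c,
                     r * width + (c - 1) % width,
                     r * width + (c + 1) % width))
    return nbrs


def simulate(landscape: Landscape, params: Params, t_end: float, seed=None,
             record_dt: float = 1.0, record_interfaces: bool = False,
             snapshot_times=(), control=None,
             interface_view: str = "slow") -> Trajectory:
    """Run one statistically exact realization of the automaton.

    Parameters
    ----------
    landscape
        Initial condition (not modified).
    params
        Rate constants; ``params.phi`` is the per-grass-cell ignition rate
        (use :meth:`Params.with_phi_N` when configuring the domain-total
        rate phi*N quoted in figures).
    t_end
        Simulated duration in years.
    seed
        Anything accepted by :func:`numpy.random.default_rng`.
    record_dt
        Cadence of state recording; a final record at ``t_end`` is always
        appended.  Recording is decoupled from events.
    record_interfaces
        Also record [FG] and the grassland-weighted perimeter [FG]cg at each
        record time (slower: requires a cluster decomposition per record).
    snapshot_times
        Times at which a full landscape copy is stored.
    control
        Optional ``(gain, F_ref)`` tuple: the ignition rate becomes the
        state-dependent feedback law ``phi(t) = phi + gain*([F](t) - F_ref)``
        clamped at zero, re-evaluated after every event that changes [F].
    interface_view
        'slow' computes recorded interfaces with burning/ash mapped to grass
        (the balance-equation view); 'raw' uses instantaneous labels.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if record_dt <= 0:
        raise ValueError("record_dt must be positive")
    if interface_view not in ("slow", "raw"):
        raise ValueError("interface_view must be 'slow' or 'raw'")

    height, width = landscape.cells.shape
    n = height * width
    cells = [int(v) for v in landscape.cells.ravel()]
    nbrs = _neighbour_table(height, width)

    alpha, beta, gamma = params.alpha, params.beta, params.gamma
    phi0, lam, mu = params.phi, params.lam, params.mu
    rho_g, rho_f = params.rho_g, params.rho_f

    # neighbour counts
    nF = [0] * n
    nB = [0] * n
    for i in range(n):
        for j in nbrs[i]:
            if cells[j] == F:
                nF[i] += 1
            elif cells[j] == B:
                nB[i] += 1

    def cell_rate(i: int) -> float:
        s = cells[i]
        if s == G:
            return beta + alpha * nF[i] + rho_g * nB[i]
        if s == F:
            return gamma + rho_f * nB[i]
        if s == B:
            return mu
        return beta + alpha * nF[i] + lam  # ash

    tree = SumTree(n)
    for i in range(n):
        tree.set(i, cell_rate(i))

    counts = [0, 0, 0, 0]
    for s in cells:
        counts[s] += 1
    F_count = counts[F]

    # grass-cell index for O(1) uniform ignition sampling
    g_list = [i for i in range(n) if cells[i] == G]
    g_pos = [-1] * n
    for p, i in enumerate(g_list):
        g_pos[i] = p

    gain_ctrl, f_ref = (control if control is not None else (0.0, 0.0))
    use_control = control is not None

    def phi_eff() -> float:
        if not use_control:
            return phi0
        return max(0.0, phi0 + gain_ctrl * (F_count / n - f_ref))

    phi_cur = phi_eff()

    rng = np.random.default_rng(seed)
    # buffered uniforms: one bulk draw amortizes generator overhead
    _buf = rng.random(8192)
    _buf_i = [0]

    def u() -> float:
        i = _buf_i[0]
        if i >= 8192:
            _buf[:] = rng.random(8192)
            i = 0
        _buf_i[0] = i + 1
        return _buf[i]

    # records
    rec_times: list[float] = []
    rec_frac: list[tuple] = []
    rec_cumF: list[float] = []
    rec_cumG: list[float] = []
    rec_cumphi: list[float] = []
    rec_fg: list[float] = []
    rec_fgcg: list[float] = []
    rec_phi: list[float] = []
    snapshots: dict = {}
    snap_queue = sorted(float(t) for t in snapshot_times)
    snap_idx = 0

    ignition_times: list[float] = []
    event_counts = {ch: 0 for ch in CHANNELS}

    t = 0.0
    t_comp = 0.0          # Kahan compensation for t
    cum_F = 0.0
    cum_G = 0.0
    cum_phi = 0.0
    clamped_time = 0.0
    next_rec = 0.0
    n_events = 0

    def interfaces_now():
        arr = np.array(cells, dtype=np.uint8).reshape(height, width)
        ls = Landscape(arr)
        if interface_view == "slow":
            ls = ls.slow_view()
        decomp = grass_clusters(ls)
        return decomp.fg_fraction, weighted_forest_perimeter(decomp)

    def record(at: float) -> None:
        rec_times.append(at)
        rec_frac.append((counts[F] / n, counts[G] / n, counts[B] / n, counts[A] / n))
        rec_cumF.append(cum_F + counts[F] / n * (at - t))
        rec_cumG.append(cum_G + counts[G] / n * (at - t))
        rec_cumphi.append(cum_phi + phi_cur * (at - t))
        rec_phi.append(phi_cur)
        if record_interfaces:
            fg, fgcg = interfaces_now()
            rec_fg.append(fg)
            rec_fgcg.append(fgcg)

    def snapshot(at: float) -> None:
        snapshots[at] = Landscape(
            np.array(cells, dtype=np.uint8).reshape(height, width))

    while True:
        total = tree.total + phi_cur * counts[G]
        if total > 0.0:
            dt = -math.log(1.0 - u()) / total
            t_event = t + dt
        else:
            t_event = math.inf

        # flush records / snapshots that precede the next event
        while next_rec <= t_event and next_rec <= t_end + 1e-12:
            record(min(next_rec, t_end))
            next_rec += record_dt
        while snap_idx < len(snap_queue) and snap_queue[snap_idx] <= min(t_event, t_end):
            snapshot(snap_queue[snap_idx])
            snap_idx += 1

        if t_event >= t_end:
            cum_F += counts[F] / n * (t_end - t)
            cum_G += counts[G] / n * (t_end - t)
            cum_phi += phi_cur * (t_end - t)
            if use_control and phi0 + gain_ctrl * (F_count / n - f_ref) < 0.0:
                clamped_time += t_end - t
            t = t_end
            break

        # advance exact integrals and time to the event
        cum_F += counts[F] / n * dt
        cum_G += counts[G] / n * dt
        cum_phi += phi_cur * dt
        if use_control and phi0 + gain_ctrl * (F_count / n - f_ref) < 0.0:
            clamped_time += dt
        y = dt - t_comp
        t_new = t + y
        t_comp = (t_new - t) - y
        t = t_new

        # choose the event
        r = u() * total
        ign_rate = phi_cur * counts[G]
        if r < ign_rate:
            # spontaneous ignition on a uniformly chosen grass cell
            i = g_list[min(int(u() * counts[G]), counts[G] - 1)]
            new_state, channel = B, "G->B ignition"
            ignition_times.append(t)
        else:
            i = tree.sample(r - ign_rate)
            if tree.get(i) <= 0.0:
                # float drift in the tree can (very rarely) land on a
                # zero-propensity leaf; treat as a null event
                continue
            s = cells[i]
            if s == G:
                r_f = beta + alpha * nF[i]
                if u() * (r_f + rho_g * nB[i]) < r_f:
                    new_state, channel = F, "G->F"
                else:
                    new_state, channel = B, "G->B spread"
            elif s == F:
                if u() * (gamma + rho_f * nB[i]) < gamma:
                    new_state, channel = G, "F->G"
                else:
                    new_state, channel = B, "F->B"
            elif s == B:
                new_state, channel = A, "B->A"
            else:  # ash
                r_f = beta + alpha * nF[i]
                if u() * (r_f + lam) < r_f:
                    new_state, channel = F, "A->F"
                else:
                    new_state, channel = G, "A->G"

        # apply the transition
        old = cells[i]
        cells[i] = new_state
        counts[old] -= 1
        counts[new_state] += 1
        event_counts[channel] += 1

        if old == G:
            p = g_pos[i]
            last = g_list[-1]
            g_list[p] = last
            g_pos[last] = p
            g_list.pop()
            g_pos[i] = -1
        if new_state == G:
            g_pos[i] = len(g_list)
            g_list.append(i)

        dF = (1 if new_state == F else 0) - (1 if old == F else 0)
        dB = (1 if new_state == B else 0) - (1 if old == B else 0)
        if dF or dB:
            for j in nbrs[i]:
                nF[j] += dF
                nB[j] += dB
                tree.set(j, cell_rate(j))
        tree.set(i, cell_rate(i))

        if dF:
            F_count += dF
            if use_control:
                phi_cur = phi_eff()

        n_events += 1
        if n_events % _REBUILD_EVERY == 0:
            tree.rebuild()

    if use_control and clamped_time > 0.5 * t_end:
        warnings.warn("feedback control clamped phi at zero for more than half "
                      "the run; the gain is likely mis-set", stacklevel=2)

    # ensure a final record exactly at t_end
    if not rec_times or rec_times[-1] < t_end - 1e-12:
        record(t_end)

    final = Landscape(np.array(cells, dtype=np.uint8).reshape(height, width))
    return Trajectory(
        times=np.array(rec_times),
        fractions=np.array(rec_frac),
        cum_F=np.array(rec_cumF),
        cum_G=np.array(rec_cumG),
        cum_phi=np.array(rec_cumphi),
        ignition_times=np.array(ignition_times),
        event_counts=event_counts,
        seed=seed,
        params=params,
        final=final,
        fg=np.array(rec_fg) if record_interfaces else None,
        fgcg=np.array(rec_fgcg) if record_interfaces else None,
        phi_series=np.array(rec_phi),
        snapshots=snapshots,
    )


def run_ensemble(landscape: Landscape, params: Params, t_end: float,
                 n_reps: int, base_seed: int, **kwargs) -> list[Trajectory]:
    """Independent seeded replicates with deterministic seed derivation.

    Replicate ``k`` uses ``numpy.random.SeedSequence([base_seed, k])``, so the
    whole ensemble is reproducible from ``base_seed`` and any replicate can
    be re-run in isolation.
    """
    out = []
    for k in range(int(n_reps)):
        seed = np.random.SeedSequence([int(base_seed), k])
        out.append(simulate(landscape, params, t_end, seed=seed, **kwargs))
    return out
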