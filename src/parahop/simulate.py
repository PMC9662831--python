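"""The hopping-and-relay stochastic simulator.

A 2D off-lattice discrete-time (``dt``) model: ParA-ATP dimers associate to a
rectangular nucleoid [0,L]×[0,W] from a well-mixed cytosolic pool, fluctuate
elastically about a home position (the chromosomal locus they are bound to),
hop diffusively (home position and dimer move together), and dissociate by
basal hydrolysis.  A plasmid is a ParB-coated disk: any bound dimer whose
centre comes within ``Rp + RA`` of the plasmid centre forms a tether.  The
plasmid then moves as a Brownian particle in the resultant harmonic potential
of all its tethers (effective spring constant n/σ², equilibrium point
``xp + Σ(xh − x)/n``) while ParB-stimulated hydrolysis breaks tethers at rate
``kh``.  All elastic motion uses the exact Ornstein–Uhlenbeck transition
density, not an Euler approximation, so ``dt`` only limits event-probability
and quasi-static-force accuracy.

Sub-step order within one ``dt`` (orderings differ at O(dt²)):
association → basal dissociation → tether breakage → bound-dimer motion
(fluctuation then hop) → tether formation → plasmid motion (tethered dimers
translate rigidly with their plasmid; home positions stay put) → reflection
at the rectangle boundary.

Two engines implement the same model:

* ``reference`` — a literal per-step kernel: every dimer draws its event
  Bernoulli trials and motion increments every step.  Used by :func:`step`
  and as the statistical oracle in tests.
* ``fast`` (default for :func:`run`) — statistically equivalent but
  event-driven: waiting times are presampled from the matching geometric
  distributions, and a dimer provably too far from every plasmid to make
  contact within k steps (5σ displacement envelope, including a generous
  allowance for plasmid motion) advances those k steps in a single exact
  aggregated Gaussian draw.  Near-plasmid dimers are stepped one dt at a
  time exactly as in the reference kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .params import ModelParams, validate_params

__all__ = [
    "SimulationState",
    "Trajectory",
    "init_state",
    "step",
    "run",
    "replicate_plasmid",
    "atp_consumption_rate",
    "para_kymograph",
]

# dimer states
CYTOSOLIC, BOUND, TETHERED = 0, 1, 2

_NEVER = 2**62          # sentinel wake/death step for rate-0 events
_Z_SAFE = 5.0           # displacement envelope half-width (standard deviations)
_SLEEP_MARGIN = 0.01    # μm, extra safety margin in the contact envelope
_V_DRIFT = 0.2          # μm/s, allowance for directed plasmid motion
_K_CAP = 512            # longest sleep window (steps)
_MIN_SLEEP = 4          # below this, step every dt
_BUF_LEN = 8192         # normal-draw buffer length


@njit(cache=True)
def _seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(inline="always")
def _reflect(x, hi):
    # fold x into [0, hi] by specular reflection
    period = 2.0 * hi
    x = x % period
    if x < 0.0:
        x += period
    if x > hi:
        x = period - x
    return x


@njit(cache=True, fastmath=True)
def _advance_ref(
    nsteps,
    state,
    pos,
    home,
    partner,
    ppos,
    counters,
    L,
    W,
    pa,
    pd,
    ph,
    decay_x,
    fluct_sd_x,
    decay_y,
    fluct_sd_y,
    hop_sd,
    free_sd,
    contact2,
    dt,
    Dp,
    sigx2,
    sigy2,
):
    """Literal per-step kernel (reference engine)."""
    nA = state.shape[0]
    n_pl = ppos.shape[0]
    for _ in range(nsteps):
        # (1) association, (2) basal dissociation, (3) tether breakage
        for i in range(nA):
            s = state[i]
            if s == CYTOSOLIC:
                if np.random.random() < pa:
                    x = np.random.random() * L
                    y = np.random.random() * W
                    pos[i, 0] = x
                    pos[i, 1] = y
                    home[i, 0] = x
                    home[i, 1] = y
                    state[i] = BOUND
            elif s == BOUND:
                if np.random.random() < pd:
                    state[i] = CYTOSOLIC
                    counters[0] += 1
            else:  # TETHERED
                if np.random.random() < ph:
                    state[i] = CYTOSOLIC
                    partner[i] = -1
                    counters[1] += 1

        # (4) bound-dimer motion: OU fluctuation about home, then hop
        for i in range(nA):
            if state[i] != BOUND:
                continue
            hx = home[i, 0]
            hy = home[i, 1]
            x = hx + (pos[i, 0] - hx) * decay_x + np.random.normal() * fluct_sd_x
            y = hy + (pos[i, 1] - hy) * decay_y + np.random.normal() * fluct_sd_y
            if hop_sd > 0.0:
                ox = np.random.normal() * hop_sd
                oy = np.random.normal() * hop_sd
                x += ox
                y += oy
                hx += ox
                hy += oy
            pos[i, 0] = _reflect(x, L)
            pos[i, 1] = _reflect(y, W)
            home[i, 0] = _reflect(hx, L)
            home[i, 1] = _reflect(hy, W)

        # (5) tether formation: bound dimer in contact with a plasmid disk
        if n_pl > 0:
            for i in range(nA):
                if state[i] != BOUND:
                    continue
                best = -1
                best_d2 = contact2
                for j in range(n_pl):
                    dx = pos[i, 0] - ppos[j, 0]
                    dy = pos[i, 1] - ppos[j, 1]
                    d2 = dx * dx + dy * dy
                    if d2 <= best_d2:
                        best_d2 = d2
                        best = j
                if best >= 0:
                    state[i] = TETHERED
                    partner[i] = best

        # (6) plasmid motion under the resultant tether force
        for j in range(n_pl):
            n_teth = 0
            sum_x = 0.0
            sum_y = 0.0
            for i in range(nA):
                if state[i] == TETHERED and partner[i] == j:
                    n_teth += 1
                    sum_x += home[i, 0] - pos[i, 0]
                    sum_y += home[i, 1] - pos[i, 1]
            px = ppos[j, 0]
            py = ppos[j, 1]
            if n_teth == 0:
                nx = px + np.random.normal() * free_sd
                ny = py + np.random.normal() * free_sd
            else:
                inv_n = 1.0 / n_teth
                eq = px + sum_x * inv_n
                a = math.exp(-dt * n_teth * Dp / sigx2)
                sd = math.sqrt(sigx2 * inv_n * (1.0 - a * a))
                nx = eq + (px - eq) * a + np.random.normal() * sd
                eq = py + sum_y * inv_n
                a = math.exp(-dt * n_teth * Dp / sigy2)
                sd = math.sqrt(sigy2 * inv_n * (1.0 - a * a))
                ny = eq + (py - eq) * a + np.random.normal() * sd
            # (7) reflection; tethered dimers translate rigidly
            nx = _reflect(nx, L)
            ny = _reflect(ny, W)
            dx = nx - px
            dy = ny - py
            ppos[j, 0] = nx
            ppos[j, 1] = ny
            if n_teth > 0 and (dx != 0.0 or dy != 0.0):
                for i in range(nA):
                    if state[i] == TETHERED and partner[i] == j:
                        pos[i, 0] = _reflect(pos[i, 0] + dx, L)
                        pos[i, 1] = _reflect(pos[i, 1] + dy, W)


@njit(inline="always")
def _geo(p):
    """Steps until a per-step Bernoulli(p) event fires (>= 1)."""
    if p <= 0.0:
        return _NEVER
    u = np.random.random()
    if u <= 0.0:
        return 1
    return 1 + int(math.log(u) / math.log1p(-p))


@njit(inline="always")
def _nrm(buf, ptr):
    i = ptr[0]
    if i >= buf.shape[0]:
        buf[:] = np.random.standard_normal(buf.shape[0])
        i = 0
    ptr[0] = i + 1
    return buf[i]


@njit(cache=True)
def _init_schedule(wake_step, pa):
    for i in range(wake_step.shape[0]):
        wake_step[i] = _geo(pa) - 1


@njit(inline="always")
def _sleep_steps_dt(d2, contact, var_rate, drift_dt, z):
    """Longest window (steps) during which a dimer at squared distance d2
    from the nearest plasmid provably (z-sigma envelope, plus a directed-
    plasmid-motion allowance drift_dt per step) cannot reach contact:
    solves z*sqrt(var_rate*k) + drift_dt*k <= d_free for k."""
    d_free = math.sqrt(d2) - contact - _SLEEP_MARGIN
    if d_free <= 0.0:
        return 0
    if var_rate <= 0.0:
        if drift_dt <= 0.0:
            return _K_CAP
        k = int(d_free / drift_dt)
        return k if k < _K_CAP else _K_CAP
    b = z * math.sqrt(var_rate)
    if drift_dt > 0.0:
        sq = (-b + math.sqrt(b * b + 4.0 * drift_dt * d_free)) / (2.0 * drift_dt)
        k = int(sq * sq)
    else:
        k = int((d_free / b) ** 2)
    return k if k < _K_CAP else _K_CAP


@njit(cache=True, fastmath=True)
def _advance_fast(
    nsteps,
    g0,
    state,
    pos,
    home,
    partner,
    last_step,
    wake_step,
    death_step,
    teth_members,
    teth_len,
    member_slot,
    ppos,
    counters,
    nbuf,
    nptr,
    L,
    W,
    pa,
    pd,
    ph,
    hop_sd,
    free_sd,
    contact2,
    dt,
    Dp,
    DA,
    Dh,
    sigx2,
    sigy2,
):
    nA = state.shape[0]
    n_pl = ppos.shape[0]
    contact = math.sqrt(contact2)
    two_dh_dt = 2.0 * Dh * dt
    # per-step displacement-variance rate of a bound dimer plus the plasmid's
    # diffusive component (per axis, upper bound on the fluctuation part)
    var_rate = 2.0 * (Dh + DA + Dp) * dt
    drift_dt = _V_DRIFT * dt
    rx = DA / sigx2
    ry = DA / sigy2

    g_end = g0 + nsteps
    for g in range(g0, g_end):
        # --- dimer events and motion -------------------------------------
        for i in range(nA):
            if wake_step[i] > g:
                continue
            s = state[i]
            if s == TETHERED:
                # scheduled ParB-stimulated tether breakage
                j = partner[i]
                slot = member_slot[i]
                last = teth_len[j] - 1
                moved = teth_members[j, last]
                teth_members[j, slot] = moved
                member_slot[moved] = slot
                teth_len[j] = last
                partner[i] = -1
                state[i] = CYTOSOLIC
                counters[1] += 1
                wake_step[i] = g + _geo(pa)
                continue
            if s == CYTOSOLIC:
                # scheduled association at a uniform point
                x = np.random.random() * L
                y = np.random.random() * W
                pos[i, 0] = x
                pos[i, 1] = y
                home[i, 0] = x
                home[i, 1] = y
                state[i] = BOUND
                death_step[i] = g + _geo(pd)
                last_step[i] = g
                k = 1  # moves this step
            else:  # BOUND
                if g >= death_step[i]:
                    state[i] = CYTOSOLIC
                    counters[0] += 1
                    wake_step[i] = g + _geo(pa)
                    continue
                k = g - last_step[i]
                if k < 1:
                    k = 1
                last_step[i] = g
            # exact k-step motion: OU fluctuation about home, then hop
            kdt = k * dt
            ax = math.exp(-kdt * rx)
            ay = math.exp(-kdt * ry)
            hx = home[i, 0]
            hy = home[i, 1]
            x = (
                hx
                + (pos[i, 0] - hx) * ax
                + _nrm(nbuf, nptr) * math.sqrt(sigx2 * (1.0 - ax * ax))
            )
            y = (
                hy
                + (pos[i, 1] - hy) * ay
                + _nrm(nbuf, nptr) * math.sqrt(sigy2 * (1.0 - ay * ay))
            )
            if two_dh_dt > 0.0:
                hop_k = math.sqrt(two_dh_dt * k)
                ox = _nrm(nbuf, nptr) * hop_k
                oy = _nrm(nbuf, nptr) * hop_k
                x += ox
                y += oy
                hx += ox
                hy += oy
            x = _reflect(x, L)
            y = _reflect(y, W)
            pos[i, 0] = x
            pos[i, 1] = y
            home[i, 0] = _reflect(hx, L)
            home[i, 1] = _reflect(hy, W)
            # tether formation or sleep scheduling
            best = -1
            best_d2 = contact2
            min_d2 = 1.0e30
            for j in range(n_pl):
                dx = x - ppos[j, 0]
                dy = y - ppos[j, 1]
                d2 = dx * dx + dy * dy
                if d2 < min_d2:
                    min_d2 = d2
                if d2 <= best_d2:
                    best_d2 = d2
                    best = j
            if best >= 0:
                state[i] = TETHERED
                partner[i] = best
                slot = teth_len[best]
                teth_members[best, slot] = i
                member_slot[i] = slot
                teth_len[best] = slot + 1
                wake_step[i] = g + _geo(ph)
                continue
            if n_pl == 0:
                ks = _K_CAP
            else:
                ks = _sleep_steps_dt(min_d2, contact, var_rate, drift_dt, _Z_SAFE)
            if ks >= _MIN_SLEEP:
                w = g + ks
                if w > death_step[i]:
                    w = death_step[i]
                wake_step[i] = w
            else:
                wake_step[i] = g + 1

        # --- plasmid motion ----------------------------------------------
        for j in range(n_pl):
            n_teth = teth_len[j]
            px = ppos[j, 0]
            py = ppos[j, 1]
            if n_teth == 0:
                nx = px + _nrm(nbuf, nptr) * free_sd
                ny = py + _nrm(nbuf, nptr) * free_sd
            else:
                sum_x = 0.0
                sum_y = 0.0
                for m in range(n_teth):
                    i = teth_members[j, m]
                    sum_x += home[i, 0] - pos[i, 0]
                    sum_y += home[i, 1] - pos[i, 1]
                inv_n = 1.0 / n_teth
                eq = px + sum_x * inv_n
                a = math.exp(-dt * n_teth * Dp / sigx2)
                sd = math.sqrt(sigx2 * inv_n * (1.0 - a * a))
                nx = eq + (px - eq) * a + _nrm(nbuf, nptr) * sd
                eq = py + sum_y * inv_n
                a = math.exp(-dt * n_teth * Dp / sigy2)
                sd = math.sqrt(sigy2 * inv_n * (1.0 - a * a))
                ny = eq + (py - eq) * a + _nrm(nbuf, nptr) * sd
            nx = _reflect(nx, L)
            ny = _reflect(ny, W)
            dx = nx - px
            dy = ny - py
            ppos[j, 0] = nx
            ppos[j, 1] = ny
            if n_teth > 0 and (dx != 0.0 or dy != 0.0):
                for m in range(n_teth):
                    i = teth_members[j, m]
                    pos[i, 0] = _reflect(pos[i, 0] + dx, L)
                    pos[i, 1] = _reflect(pos[i, 1] + dy, W)

    # --- sync: integrate pending motion of sleeping bound dimers ---------
    for i in range(nA):
        if state[i] != BOUND:
            continue
        k = (g_end - 1) - last_step[i]
        if k < 1:
            continue
        last_step[i] = g_end - 1
        kdt = k * dt
        ax = math.exp(-kdt * rx)
        ay = math.exp(-kdt * ry)
        hx = home[i, 0]
        hy = home[i, 1]
        x = (
            hx
            + (pos[i, 0] - hx) * ax
            + _nrm(nbuf, nptr) * math.sqrt(sigx2 * (1.0 - ax * ax))
        )
        y = (
            hy
            + (pos[i, 1] - hy) * ay
            + _nrm(nbuf, nptr) * math.sqrt(sigy2 * (1.0 - ay * ay))
        )
        if two_dh_dt > 0.0:
            hop_k = math.sqrt(two_dh_dt * k)
            ox = _nrm(nbuf, nptr) * hop_k
            oy = _nrm(nbuf, nptr) * hop_k
            x += ox
            y += oy
            hx += ox
            hy += oy
        pos[i, 0] = _reflect(x, L)
        pos[i, 1] = _reflect(y, W)
        home[i, 0] = _reflect(hx, L)
        home[i, 1] = _reflect(hy, W)


@dataclass
class SimulationState:
    """Mutable state of one simulation: dimers, plasmids, counters, clock.

    The number of dimers is fixed (they change state, never number); the
    plasmid count can grow via :func:`replicate_plasmid`.
    ``counters = [basal_hydrolysis_events, stimulated_hydrolysis_events]``.
    """

    time: float
    state: np.ndarray        # (nA,) int64, CYTOSOLIC/BOUND/TETHERED
    pos: np.ndarray          # (nA, 2) float64
    home: np.ndarray         # (nA, 2) float64
    partner: np.ndarray      # (nA,) int64, plasmid index or -1
    ppos: np.ndarray         # (n_plasmids, 2) float64
    counters: np.ndarray     # (2,) int64
    seed: int

    @property
    def n_bound(self) -> int:
        return int(np.sum(self.state != CYTOSOLIC))

    def tether_counts(self) -> np.ndarray:
        """Number of tethers per plasmid."""
        n = self.ppos.shape[0]
        out = np.zeros(n, dtype=np.int64)
        for j in range(n):
            out[j] = int(np.sum((self.state == TETHERED) & (self.partner == j)))
        return out


@dataclass
class Trajectory:
    """Sampled long-axis plasmid positions, mid-nucleoid relative (μm).

    ``positions`` has shape (n_samples, n_plasmids); a column is one plasmid's
    track.  ``times`` are seconds from the end of burn-in.  ``counters`` holds
    hydrolysis-event totals accumulated over the production ``duration`` (s).
    """

    times: np.ndarray
    positions: np.ndarray
    tether_counts: np.ndarray
    sampling_interval: float
    L: float
    seed: int
    params: ModelParams | None = None
    counters: dict = field(default_factory=dict)
    duration: float = 0.0
    para_kymo: np.ndarray | None = None
    cell_id: str = "sim"
    plasmid_ids: list = field(default_factory=list)

    @property
    def n_plasmids(self) -> int:
        return self.positions.shape[1]

    def series(self, i: int = 0) -> np.ndarray:
        """One plasmid's mid-relative long-axis positions."""
        return self.positions[:, i]


def _kernel_args_ref(p: ModelParams):
    dt = p.dt
    decay_x = math.exp(-dt * p.DA / p.sigma_x**2)
    decay_y = math.exp(-dt * p.DA / p.sigma_y**2)
    return (
        p.L,
        p.W,
        p.ka * dt,
        p.kd * dt,
        p.kh * dt,
        decay_x,
        p.sigma_x * math.sqrt(1.0 - decay_x**2),
        decay_y,
        p.sigma_y * math.sqrt(1.0 - decay_y**2),
        math.sqrt(2.0 * p.Dh * dt),
        math.sqrt(2.0 * p.Dp * dt),
        (p.Rp + p.RA) ** 2,
        dt,
        p.Dp,
        p.sigma_x**2,
        p.sigma_y**2,
    )


def _kernel_args_fast(p: ModelParams):
    dt = p.dt
    return (
        p.L,
        p.W,
        p.ka * dt,
        p.kd * dt,
        p.kh * dt,
        math.sqrt(2.0 * p.Dh * dt),
        math.sqrt(2.0 * p.Dp * dt),
        (p.Rp + p.RA) ** 2,
        dt,
        p.Dp,
        p.DA,
        p.Dh,
        p.sigma_x**2,
        p.sigma_y**2,
    )


def init_state(
    params: ModelParams,
    seed: int,
    plasmid_positions: Sequence[tuple[float, float]] | None = None,
) -> SimulationState:
    """Fresh state: all dimers cytosolic, plasmids placed, clock at zero.

    Default placement is the regular-positioning configuration: plasmid i of
    n at x = (2i−1)·L/(2n), y = W/2 (mid-nucleoid for a single plasmid).
    """
    p = validate_params(params)
    if plasmid_positions is None:
        ppos = np.empty((p.np, 2))
        for i in range(p.np):
            ppos[i, 0] = (2 * i + 1) * p.L / (2 * p.np)
            ppos[i, 1] = p.W / 2.0
    else:
        ppos = np.asarray(plasmid_positions, dtype=float).reshape(-1, 2).copy()
        if ppos.shape[0] != p.np:
            raise ValueError(
                f"expected {p.np} plasmid positions, got {ppos.shape[0]}"
            )
        for x, y in ppos:
            if not (0.0 <= x <= p.L and 0.0 <= y <= p.W):
                raise ValueError(
                    f"plasmid position ({x}, {y}) outside nucleoid "
                    f"[0,{p.L}]x[0,{p.W}]"
                )
    _seed(seed)
    nA = p.nA
    return SimulationState(
        time=0.0,
        state=np.full(nA, CYTOSOLIC, dtype=np.int64),
        pos=np.zeros((nA, 2)),
        home=np.zeros((nA, 2)),
        partner=np.full(nA, -1, dtype=np.int64),
        ppos=ppos,
        counters=np.zeros(2, dtype=np.int64),
        seed=seed,
    )


def step(state: SimulationState, params: ModelParams, n_steps: int = 1) -> SimulationState:
    """Advance the state by ``n_steps`` time steps of ``dt`` in place
    (reference per-step engine)."""
    p = validate_params(params)
    _advance_ref(
        n_steps,
        state.state,
        state.pos,
        state.home,
        state.partner,
        state.ppos,
        state.counters,
        *_kernel_args_ref(p),
    )
    state.time += n_steps * p.dt
    return state


def replicate_plasmid(state: SimulationState, plasmid_id: int) -> SimulationState:
    """Duplicate a plasmid in place: the copy shares the parent's position
    but inherits none of its ParA tethers."""
    n = state.ppos.shape[0]
    if not (0 <= plasmid_id < n):
        raise ValueError(f"no plasmid with id {plasmid_id} (have {n})")
    state.ppos = np.vstack([state.ppos, state.ppos[plasmid_id : plasmid_id + 1]])
    return state


class _FastAux:
    """Scheduling arrays of the event-driven engine."""

    def __init__(self, nA: int, max_plasmids: int, pa: float):
        self.last_step = np.zeros(nA, dtype=np.int64)
        self.wake_step = np.zeros(nA, dtype=np.int64)
        self.death_step = np.full(nA, _NEVER, dtype=np.int64)
        self.teth_members = np.zeros((max(max_plasmids, 1), max(nA, 1)), dtype=np.int64)
        self.teth_len = np.zeros(max(max_plasmids, 1), dtype=np.int64)
        self.member_slot = np.zeros(nA, dtype=np.int64)
        self.nbuf = np.zeros(_BUF_LEN)
        self.nptr = np.full(1, _BUF_LEN, dtype=np.int64)
        self.g = 0
        _init_schedule(self.wake_step, pa)

    def advance(self, n_steps: int, st: SimulationState, args):
        _advance_fast(
            n_steps,
            self.g,
            st.state,
            st.pos,
            st.home,
            st.partner,
            self.last_step,
            self.wake_step,
            self.death_step,
            self.teth_members,
            self.teth_len,
            self.member_slot,
            st.ppos,
            st.counters,
            self.nbuf,
            self.nptr,
            *args,
        )
        self.g += n_steps


def _n_steps(interval: float, dt: float, name: str) -> int:
    n = interval / dt
    if abs(n - round(n)) > 1e-6:
        raise ValueError(f"{name} = {interval} s is not a multiple of dt = {dt} s")
    return int(round(n))


def run(
    params: ModelParams,
    duration: float,
    burn_in: float = 600.0,
    sampling_interval: float = 60.0,
    seed: int = 0,
    plasmid_positions: Sequence[tuple[float, float]] | None = None,
    replicate_at: float | None = None,
    para_bins: int | None = None,
    engine: str = "fast",
) -> Trajectory:
    """Burn in, then simulate ``duration`` seconds, sampling plasmid positions.

    Event counters are reset at the end of burn-in so that
    :func:`atp_consumption_rate` reflects the production period only.
    ``replicate_at`` (s, production time, multiple of the sampling interval)
    duplicates plasmid 0 mid-run.  ``para_bins`` additionally records a
    kymograph of bound-ParA long-axis positions (one histogram per sample).
    ``engine`` is "fast" (event-driven, default) or "reference" (literal
    per-step); the two are statistically equivalent.
    """
    p = validate_params(params)
    if engine not in ("fast", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    per_sample = _n_steps(sampling_interval, p.dt, "sampling_interval")
    if per_sample < 1:
        raise ValueError("sampling_interval must be >= dt")
    burn_steps = _n_steps(burn_in, p.dt, "burn_in")
    n_samples = _n_steps(duration, p.dt, "duration") // per_sample

    state = init_state(p, seed, plasmid_positions)

    rep_sample = None
    max_np = state.ppos.shape[0]
    if replicate_at is not None:
        k = replicate_at / sampling_interval
        if abs(k - round(k)) > 1e-6:
            raise ValueError("replicate_at must be a multiple of sampling_interval")
        rep_sample = int(round(k))
        if not (0 <= rep_sample <= n_samples):
            raise ValueError("replicate_at outside the production window")
        max_np += 1

    if engine == "fast":
        aux = _FastAux(p.nA, max_np, p.ka * p.dt)
        args = _kernel_args_fast(p)

        def advance(n):
            aux.advance(n, state, args)

        def on_replicate():
            # new plasmid starts with zero tethers; membership arrays were
            # sized for it up front
            pass

    else:
        args = _kernel_args_ref(p)

        def advance(n):
            _advance_ref(
                n, state.state, state.pos, state.home, state.partner,
                state.ppos, state.counters, *args,
            )

        def on_replicate():
            pass

    if burn_steps:
        advance(burn_steps)
        state.time += burn_in
    state.counters[:] = 0

    times = np.arange(n_samples + 1) * sampling_interval
    positions = np.full((n_samples + 1, max_np), np.nan)
    tethers = np.zeros((n_samples + 1, max_np), dtype=np.int64)
    kymo = np.zeros((n_samples + 1, para_bins), dtype=np.int64) if para_bins else None

    def record(k):
        n_now = state.ppos.shape[0]
        positions[k, :n_now] = state.ppos[:, 0] - p.L / 2.0
        if engine == "fast":
            tethers[k, :n_now] = aux.teth_len[:n_now]
        else:
            tethers[k, :n_now] = state.tether_counts()
        if kymo is not None:
            on = state.state != CYTOSOLIC
            kymo[k], _ = np.histogram(state.pos[on, 0], bins=para_bins, range=(0.0, p.L))

    if rep_sample == 0:
        replicate_plasmid(state, 0)
        on_replicate()
    record(0)
    for k in range(1, n_samples + 1):
        advance(per_sample)
        state.time += sampling_interval
        if rep_sample is not None and k == rep_sample:
            replicate_plasmid(state, 0)
            on_replicate()
        record(k)

    return Trajectory(
        times=times,
        positions=positions,
        tether_counts=tethers,
        sampling_interval=sampling_interval,
        L=p.L,
        seed=seed,
        params=p,
        counters={
            "basal_hydrolysis_events": int(state.counters[0]),
            "stimulated_hydrolysis_events": int(state.counters[1]),
        },
        duration=float(duration),
        para_kymo=kymo,
        plasmid_ids=[str(i) for i in range(max_np)],
    )


def atp_consumption_rate(traj: Trajectory, duration: float | None = None) -> float:
    """Hydrolysis events per second over the accounted (post burn-in) period.

    Every dissociation — basal or ParB-stimulated — is one ATP hydrolysis.
    """
    if duration is None:
        duration = traj.duration
    if duration <= 0:
        raise ValueError("accounted duration must be positive")
    c = traj.counters
    events = c.get("basal_hydrolysis_events", 0) + c.get(
        "stimulated_hydrolysis_events", 0
    )
    return events / duration


def para_kymograph(
    samples: Sequence[np.ndarray], n_bins: int, L: float
) -> np.ndarray:
    """Histogram bound-ParA long-axis positions per sample time.

    ``samples`` is a sequence of arrays of dimer x positions (one array per
    sample).  Row sums equal the instantaneous bound count.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    out = np.zeros((len(samples), n_bins), dtype=np.int64)
    for k, xs in enumerate(samples):
        xs = np.asarray(xs, dtype=float)
        if xs.size:
            out[k], _ = np.histogram(xs, bins=n_bins, range=(0.0, L))
    return out
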