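"""Metropolis interaction kinetics and the main simulation loop.

Each step, every NK cell within the gate radius a0 of a dendritic cell is
subjected to an accept/reject test on its radial leap Delta_d toward the
DC (the stochastic displacement itself is the random variable — no extra
random number is drawn):

* start (not interacting):  Delta_d >= Dd_rms * (1 - w)
* stop  (interacting):     -Delta_d >= Dd_rms * w

where Dd_rms = sqrt(6 D0 dt) is the RMS three-dimensional displacement at
the *intrinsic* diffusion coefficient (0.2 um at the default parameters —
the typical per-second NK leap), and w = chi * c(r, t)/c_max is the
chemotactic weight: the chemokine level of the partner DC at the cell's
position, relative to the on-source maximum.  Near a DC the friction dip
makes the actual steps several times smaller than Dd_rms, so cells that
wander deep into a charged chemokine cloud stop only rarely — the origin
of the long-duration interaction component.

The feedback loop: a DC's source discharges (time constant tau) while it
has at least one active partner, and recharges otherwise; the factor is
continuous across switches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from . import dynamics, field
from .field import SourceMode
from .params import SimParams, derive_constants, place_dcs

__all__ = [
    "InteractionEvent", "StepDecision", "radial_approach",
    "start_test", "stop_test", "update_feedback",
    "run_simulation", "SimulationResult", "events_to_frame",
]


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------

@dataclass
class InteractionEvent:
    """One NK-DC interaction episode."""

    nk_id: int
    dc_id: int
    t_start: float
    t_end: Optional[float] = None
    censored: bool = False

    @property
    def duration(self) -> Optional[float]:
        return None if self.t_end is None else self.t_end - self.t_start


@dataclass(frozen=True)
class StepDecision:
    """Inputs and outcome of one Metropolis test."""

    delta_d: float       # radial approach over the step [um]; > 0 = approaching
    delta_d_rms: float   # reference RMS leap sqrt(6 D0 dt) [um]
    c_ratio: float       # chemotactic weight chi * c_DC/c_max, in [0, 1]
    action: str          # "START", "STOP" or "NONE"


def radial_approach(pos_before, pos_after, dc_pos):
    """Reduction of the NK-DC centre distance over one step [um].

    Positive when the cell approached the DC.  Vectorized over leading
    dimensions.
    """
    pos_before = np.asarray(pos_before, float)
    pos_after = np.asarray(pos_after, float)
    dc_pos = np.asarray(dc_pos, float)
    r0 = np.linalg.norm(pos_before - dc_pos, axis=-1)
    r1 = np.linalg.norm(pos_after - dc_pos, axis=-1)
    out = r0 - r1
    return out if np.ndim(out) else float(out)


def start_test(delta_d, delta_d_rms: float, c_ratio):
    """Metropolis acceptance for an interaction start.

    True iff delta_d >= delta_d_rms * (1 - c_ratio).  A receding step
    (delta_d < 0) can never start an interaction; at full chemotactic
    weight any approaching step starts one.
    """
    delta_d = np.asarray(delta_d, float)
    ok = (delta_d >= 0) & (delta_d >= delta_d_rms * (1.0 - np.asarray(c_ratio, float)))
    return ok if ok.ndim else bool(ok)


def stop_test(delta_d, delta_d_rms: float, c_ratio):
    """Metropolis acceptance for an interaction stop.

    True iff -delta_d >= delta_d_rms * c_ratio.  An approaching step never
    interrupts an interaction; at zero weight any strictly receding step
    does.
    """
    delta_d = np.asarray(delta_d, float)
    ok = (delta_d < 0) & (-delta_d >= delta_d_rms * np.asarray(c_ratio, float))
    return ok if ok.ndim else bool(ok)


def update_feedback(dc: dynamics.DCState, n_active_partners: int, t: float,
                    tau: float, tau_discharge: Optional[float] = None) -> None:
    """Set the DC source mode from its current partner count.

    The source discharges while at least one interaction is active and
    recharges otherwise; the factor stays continuous at every switch.
    """
    dc.source.switch(n_active_partners > 0, t, tau, tau_discharge)


def initial_positions(params: SimParams, dc_pos: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw the initial NK positions.

    ``init_mode='stationary'`` samples from the zero-chemotaxis stationary
    density of the space-dependent-friction dynamics, p(r) proportional to
    gamma(r) (cells accumulate where they are slow).  The long production
    runs the headline statistics refer to are dominated by this
    equilibrated regime, so starting from it removes an initialization
    transient whose relaxation time (the diffusion time across the
    friction dip, ~1e5 s) would otherwise swamp a desk-scale run.
    ``init_mode='uniform'`` is plain uniform-in-box placement.
    """
    box = np.asarray(params.box, float)
    if params.init_mode == "uniform" or len(dc_pos) == 0 or params.k_gamma == 0:
        return rng.uniform(0.0, 1.0, (n, 3)) * box
    out = np.empty((n, 3))
    got = 0
    # upper bound on gamma/gamma0: nearest DC plus ~0.5 for neighbours
    gmax = 1.0 + params.k_gamma * 1.5
    while got < n:
        cand = rng.uniform(0.0, 1.0, (4 * n, 3)) * box
        g = dynamics.friction_profile(cand, dc_pos, params)
        acc = rng.uniform(0.0, gmax, len(cand)) < g
        take = cand[acc][:n - got]
        out[got:got + len(take)] = take
        got += len(take)
    return out


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    tracks: pd.DataFrame
    events: List[InteractionEvent]
    params: SimParams
    dc_positions: np.ndarray

    @property
    def events_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


def events_to_frame(events: List[InteractionEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "nk_id": np.array([e.nk_id for e in events], dtype=int),
        "dc_id": np.array([e.dc_id for e in events], dtype=int),
        "t_start_s": np.array([e.t_start for e in events], dtype=float),
        "t_end_s": np.array([np.nan if e.t_end is None else e.t_end
                             for e in events], dtype=float),
        "duration_s": np.array([np.nan if e.duration is None else e.duration
                                for e in events], dtype=float),
        "censored": np.array([e.censored for e in events], dtype=bool),
    })


def run_simulation(params: SimParams, rng: Optional[np.random.Generator] = None,
                   progress: bool = False) -> SimulationResult:
    """Run the mixed Brownian-dynamics / Metropolis simulation.

    Per step: evaluate the per-DC source factors, advance all cells one
    Langevin step, run start/stop tests on the realized radial leaps
    (fields at the pre-move position and time), update the source feedback,
    then handle box exits.  Fully reproducible from ``params.seed`` (or an
    explicit generator).
    """
    consts = derive_constants(params)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    dc_pos = place_dcs(params, rng)
    m = len(dc_pos)

    n = params.n_nk
    box = np.asarray(params.box, float)
    pos = initial_positions(params, dc_pos, n, rng)
    prev_dir = dynamics.random_unit_vectors(n, rng)
    track_id = np.arange(n)
    next_id = n
    partner = np.full(n, -1)              # DC index, -1 = not interacting
    open_events: dict[int, InteractionEvent] = {}  # keyed by NK array slot
    events: List[InteractionEvent] = []

    dd_rms = math.sqrt(3.0) * consts.sigma_step  # sqrt(6 D0 dt), intrinsic 3D RMS
    c_max = field.steady_profile(params.reg_radius, params.j0, params.d_ck,
                                 params.k_deg, params.reg_radius)
    lam = consts.lam
    r_reg = params.reg_radius
    use_field = params.chi > 0 and params.j0 > 0 and m > 0
    d0, k_g, s2 = consts.d0, params.k_gamma, params.s_gamma**2
    dt = params.dt
    sig_th = params.sigma_theta

    # vectorized per-DC source clocks (SourceMode semantics, array form)
    dc_disch = np.zeros(m, bool)
    dc_tswitch = np.zeros(m)
    dc_fswitch = np.zeros(m)

    rec_tid, rec_step, rec_pos, rec_int, rec_partner = [], [], [], [], []

    def record(step_idx: int) -> None:
        rec_tid.append(track_id.copy())
        rec_step.append(np.full(n, step_idx))
        rec_pos.append(pos.copy())
        rec_int.append(partner >= 0)
        rec_partner.append(partner.copy())

    # chunked pre-generation of the per-step stochastic inputs
    CHUNK = 256
    mag_norm = theta_norm = phi_uni = None
    row = CHUNK
    arange_n = np.arange(n)

    for step_idx in range(params.n_steps):
        t = step_idx * dt
        if step_idx % params.record_stride == 0:
            record(step_idx)
        if row == CHUNK:
            mag_norm = rng.standard_normal((CHUNK, n, 3))
            theta_norm = rng.standard_normal((CHUNK, n))
            phi_uni = rng.uniform(0.0, 2.0 * np.pi, (CHUNK, n))
            row = 0

        if m:
            sep = pos[:, None, :] - dc_pos[None, :, :]       # (n, m, 3)
            d2 = np.einsum("nmk,nmk->nm", sep, sep)
            dist = np.sqrt(d2)
            egam = np.exp(d2 / (-2.0 * s2))                  # friction kernel
            gfac = 1.0 + k_g * egam.sum(axis=1)              # gamma(r)/gamma0
            d_loc = d0 / gfac
            # attractive friction drift -grad D
            grad_d = d0 * (k_g / s2) * np.einsum("nm,nmk->nk", egam, sep) \
                / (gfac**2)[:, None]
            drift = -grad_d
        else:
            gfac = np.ones(n)
            d_loc = np.full(n, d0)
            drift = np.zeros((n, 3))

        if use_field:
            # source factors at the pre-move time (continuity-matched)
            dt_sw = t - dc_tswitch
            decay = np.exp(-dt_sw / params.tau)
            factors = np.where(dc_disch, dc_fswitch * decay,
                               1.0 - (1.0 - dc_fswitch) * decay)
            rc = np.maximum(dist, r_reg)
            c_ss = params.j0 * np.exp(-rc / lam) / (4.0 * math.pi * params.d_ck * rc)
            # Metropolis weight: local chemokine level over the on-source max
            w_all = params.chi * (c_ss / c_max) * factors[None, :]  # (n, m)
            dcdr = -c_ss * (1.0 / rc + 1.0 / lam) * factors[None, :]
            dcdr[dist <= r_reg] = 0.0
            safe = np.where(dist == 0.0, 1.0, dist)
            grad = np.einsum("nm,nmk->nk", dcdr / safe, sep)
            drift = drift + consts.chi_phys * grad / (consts.gamma0 * gfac)[:, None]

        # --- stochastic displacement: Maxwell magnitude, WLC direction
        g3 = mag_norm[row]
        mag = np.sqrt(np.einsum("nk,nk->n", g3, g3) * (2.0 * d_loc * dt))
        if sig_th is None:
            u = g3 / np.linalg.norm(g3, axis=1, keepdims=True)
        else:
            u = dynamics.wlc_rotate(prev_dir, theta_norm[row] * sig_th, phi_uni[row])
        row += 1
        disp = drift * dt + mag[:, None] * u
        new_pos = pos + disp
        norm = np.sqrt(np.einsum("nk,nk->n", disp, disp))
        prev_dir = disp / np.where(norm == 0.0, 1.0, norm)[:, None]

        # --- Metropolis tests on the realized leaps
        if m:
            nsep = new_pos[:, None, :] - dc_pos[None, :, :]
            new_dist = np.sqrt(np.einsum("nmk,nmk->nm", nsep, nsep))
            delta_d = dist - new_dist                        # (n, m)

            interacting = partner >= 0
            nearest = np.argmin(dist, axis=1)
            t_next = t + dt
            # stops: receding leap beyond the weighted threshold
            p_idx = np.where(interacting, partner, 0)
            dd_p = delta_d[arange_n, p_idx]
            w_p = w_all[arange_n, p_idx] if use_field else 0.0
            stops = interacting & (dd_p < 0) & (-dd_p >= dd_rms * w_p)
            # starts: approaching leap inside the gate
            dd_s = delta_d[arange_n, nearest]
            w_s = w_all[arange_n, nearest] if use_field else 0.0
            starts = (~interacting & (dist[arange_n, nearest] < params.a0)
                      & (dd_s >= 0) & (dd_s >= dd_rms * (1.0 - w_s)))
            for i in np.flatnonzero(stops):
                ev = open_events.pop(i)
                ev.t_end = t_next
                partner[i] = -1
            for i in np.flatnonzero(starts):
                k = int(nearest[i])
                partner[i] = k
                ev = InteractionEvent(nk_id=int(track_id[i]), dc_id=k,
                                      t_start=t_next)
                open_events[i] = ev
                events.append(ev)

            # --- feedback update (factor-continuous mode switches)
            n_partners = np.bincount(partner[partner >= 0], minlength=m)
            new_disch = n_partners > 0
            changed = new_disch != dc_disch
            if changed.any():
                dec = np.exp(-(t_next - dc_tswitch[changed]) / params.tau)
                f_now = np.where(
                    dc_disch[changed], dc_fswitch[changed] * dec,
                    1.0 - (1.0 - dc_fswitch[changed]) * dec)
                dc_fswitch[changed] = f_now
                dc_tswitch[changed] = t_next
                dc_disch[changed] = new_disch[changed]

        # --- boundaries
        exited = np.any((new_pos < 0.0) | (new_pos > box), axis=1)
        if exited.any():
            idx = np.flatnonzero(exited)
            _, repl = dynamics.apply_boundaries(new_pos, params, rng)
            for j, i in enumerate(idx):
                if partner[i] >= 0:
                    ev = open_events.pop(i)
                    ev.t_end = t + dt
                    ev.censored = True
                    partner[i] = -1
                new_pos[i] = repl[j]
                track_id[i] = next_id
                next_id += 1
                prev_dir[i] = dynamics.random_unit_vectors(1, rng)[0]
        pos = new_pos

    # censor events still open at run end
    t_end = params.n_steps * params.dt
    for ev in open_events.values():
        ev.t_end = t_end
        ev.censored = True

    tracks = pd.DataFrame({
        "track_id": np.concatenate(rec_tid),
        "step": np.concatenate(rec_step),
        "t_s": np.concatenate(rec_step) * params.dt,
        "x_um": np.concatenate([p[:, 0] for p in rec_pos]),
        "y_um": np.concatenate([p[:, 1] for p in rec_pos]),
        "z_um": np.concatenate([p[:, 2] for p in rec_pos]),
        "interacting": np.concatenate(rec_int).astype(int),
        "partner_dc": np.concatenate(rec_partner),
    })
    return SimulationResult(tracks=tracks, events=events, params=params,
                            dc_positions=dc_pos)


def run_free_diffusion(n_cells: int, n_steps: int, d0: float, dt: float = 1.0,
                       seed: int = 0, isotropic: bool = True,
                       sigma_theta: float = 0.3) -> np.ndarray:
    """Fast free-diffusion path: positions of shape (n_steps+1, n_cells, 3).

    Pure Euler-Maruyama when ``isotropic``; otherwise WLC persistence with
    ``sigma_theta``.  No boundaries, no DCs — the calibration workload for
    recovering D from the MSD slope.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = math.sqrt(2.0 * d0 * dt)
    if isotropic:
        steps = rng.standard_normal((n_steps, n_cells, 3)) * sigma
    else:
        mags = np.linalg.norm(rng.standard_normal((n_steps, n_cells, 3)), axis=2) * sigma
        dirs = np.empty((n_steps, n_cells, 3))
        d = dynamics.random_unit_vectors(n_cells, rng)
        for s in range(n_steps):
            d = dynamics.wlc_direction(d, sigma_theta, rng)
            dirs[s] = d
        steps = mags[:, :, None] * dirs
    pos = np.concatenate([np.zeros((1, n_cells, 3)), np.cumsum(steps, axis=0)])
    return pos
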