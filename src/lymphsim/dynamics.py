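"""Langevin dynamics of NK cells: noise, persistence, drifts, boundaries.

One integration step combines, in the overdamped (Euler-Maruyama) limit:

* a stochastic displacement whose magnitude is that of a 3D Gaussian step
  with per-axis std sqrt(2 D(r) dt) and whose direction follows a
  worm-like-chain (WLC) rule — a Gaussian deviation angle of std
  sigma_theta about the previous step direction;
* the chemotactic drift chi * grad(c) / gamma(r);
* the attractive drift induced by the space-dependent friction
  gamma(r) = gamma0 * (1 + k_gamma * sum_k exp(-r_k^2 / 2 s_gamma^2)),
  which slows NK cells down near dendritic cells (a mean-field stand-in
  for contact interactions with the DC and the surrounding tissue).

All functions are vectorized over cells; the simulation loop lives in
:mod:`lymphsim.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import SimParams, DerivedConstants

__all__ = [
    "NKState", "DCState", "friction_profile", "friction_at", "local_diffusion",
    "friction_drift", "wlc_direction", "random_unit_vectors", "step_displacement",
    "apply_boundaries",
]


@dataclass
class NKState:
    """State of one NK cell."""

    id: int
    pos: np.ndarray                       # [um]
    prev_dir: Optional[np.ndarray] = None  # unit vector of the last step
    alive: bool = True
    interacting: bool = False
    partner_dc: Optional[int] = None


@dataclass
class DCState:
    """State of one immobile dendritic cell (position + source clock)."""

    id: int
    pos: np.ndarray
    source: "object" = None  # SourceMode; assigned by the engine


# ---------------------------------------------------------------------------
# friction profile
# ---------------------------------------------------------------------------

def friction_profile(pos: np.ndarray, dc_pos: np.ndarray, params: SimParams) -> np.ndarray:
    """Dimensionless friction enhancement gamma(r)/gamma0 at ``pos``.

    ``pos`` is (n, 3) or (3,); ``dc_pos`` is (m, 3).  Contributions of all
    DCs add: 1 + k_gamma * sum_k exp(-r_k^2 / (2 s_gamma^2)).
    """
    pos = np.atleast_2d(np.asarray(pos, float))
    if dc_pos is None or len(dc_pos) == 0:
        return np.ones(len(pos))
    dc_pos = np.atleast_2d(np.asarray(dc_pos, float))
    d2 = ((pos[:, None, :] - dc_pos[None, :, :]) ** 2).sum(axis=2)
    return 1.0 + params.k_gamma * np.exp(-d2 / (2.0 * params.s_gamma**2)).sum(axis=1)


def friction_at(pos: np.ndarray, dc_pos: np.ndarray, params: SimParams,
                consts: DerivedConstants) -> np.ndarray:
    """Space-dependent friction coefficient gamma(r) [kg/s]."""
    return consts.gamma0 * friction_profile(pos, dc_pos, params)


def local_diffusion(pos: np.ndarray, dc_pos: np.ndarray, params: SimParams,
                    consts: DerivedConstants) -> np.ndarray:
    """Local diffusion coefficient D(r) = D0 / (gamma(r)/gamma0) [um^2/s]."""
    return consts.d0 / friction_profile(pos, dc_pos, params)


def friction_drift(pos: np.ndarray, dc_pos: np.ndarray, params: SimParams,
                   consts: DerivedConstants) -> np.ndarray:
    """Attractive drift -grad D(r) [um/s] induced by the friction dip.

    The spatial modulation of the friction coefficient acts as a weak
    attractive force toward the DCs; its drift-velocity form is the
    (negated) gradient of the local diffusion coefficient.  It vanishes
    where D is flat (k_gamma = 0 or far from every DC).
    """
    pos = np.atleast_2d(np.asarray(pos, float))
    if dc_pos is None or len(dc_pos) == 0 or params.k_gamma == 0.0:
        return np.zeros((len(pos), 3))
    dc_pos = np.atleast_2d(np.asarray(dc_pos, float))
    sep = pos[:, None, :] - dc_pos[None, :, :]          # (n, m, 3)
    d2 = (sep**2).sum(axis=2)                            # (n, m)
    s2 = params.s_gamma**2
    g = friction_profile(pos, dc_pos, params)            # (n,)
    # dD/dx = D0 * k_gamma/s^2 * sum_k exp(-r_k^2/2s^2) * x_k / g^2
    weight = params.k_gamma / s2 * np.exp(-d2 / (2.0 * s2))  # (n, m)
    grad_d = consts.d0 * (weight[:, :, None] * sep).sum(axis=1) / (g**2)[:, None]
    return -grad_d


# ---------------------------------------------------------------------------
# worm-like-chain directions
# ---------------------------------------------------------------------------

def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Isotropically distributed unit vectors, shape (n, 3)."""
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a all-zero draw has probability 0; guard anyway
    norm[norm == 0.0] = 1.0
    return v / norm


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def wlc_rotate(prev_dir: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle ``theta`` at azimuth ``phi``."""
    prev_dir = np.atleast_2d(np.asarray(prev_dir, float))
    n = len(prev_dir)
    # orthonormal frame (e1, e2) perpendicular to prev_dir
    ref = np.zeros_like(prev_dir)
    smallest = np.argmin(np.abs(prev_dir), axis=1)
    ref[np.arange(n), smallest] = 1.0
    e1 = _cross(prev_dir, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = _cross(prev_dir, e1)
    new = (np.cos(theta)[:, None] * prev_dir
           + np.sin(theta)[:, None] * (np.cos(phi)[:, None] * e1
                                       + np.sin(phi)[:, None] * e2))
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def wlc_direction(prev_dir: np.ndarray, sigma_theta: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit vector by a Gaussian polar deviation angle.

    theta ~ N(0, sigma_theta), azimuth uniform about the previous
    direction; <cos theta> = exp(-sigma_theta^2 / 2).
    """
    prev_dir = np.atleast_2d(np.asarray(prev_dir, float))
    n = len(prev_dir)
    if sigma_theta == 0.0:
        return prev_dir.copy()
    theta = rng.standard_normal(n) * sigma_theta
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return wlc_rotate(prev_dir, theta, phi)


# ---------------------------------------------------------------------------
# one integration step
# ---------------------------------------------------------------------------

def step_displacement(pos: np.ndarray, prev_dir: np.ndarray, has_dir: np.ndarray,
                      drift: np.ndarray, dc_pos: np.ndarray, params: SimParams,
                      consts: DerivedConstants, rng: np.random.Generator,
                      noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Displacements and updated directions for all cells over one step.

    The stochastic magnitude is |xi| with xi three independent N(0, 2 D(r) dt)
    variables evaluated at the pre-step position; its direction is the WLC
    rotation of ``prev_dir`` (isotropic where ``has_dir`` is False).
    Deterministic drifts (chemotaxis + friction) add vectorially.
    Returns ``(displacement, new_dir)`` where ``new_dir`` is the realized
    step direction.  ``noise=False`` is a test hook for pure-drift motion.
    """
    pos = np.atleast_2d(pos)
    n = len(pos)
    disp = drift * params.dt
    if noise:
        d_loc = local_diffusion(pos, dc_pos, params, consts)
        sigma = np.sqrt(2.0 * d_loc * params.dt)
        mag = np.linalg.norm(rng.standard_normal((n, 3)), axis=1) * sigma
        dirs = np.empty((n, 3))
        if params.sigma_theta is None:
            dirs = random_unit_vectors(n, rng)
        else:
            dirs = wlc_direction(np.where(has_dir[:, None], prev_dir,
                                          random_unit_vectors(n, rng)),
                                 params.sigma_theta, rng)
            # cells without a previous direction start isotropic: the draw
            # above already randomized them before the WLC rotation
        disp = disp + mag[:, None] * dirs
    norm = np.linalg.norm(disp, axis=1, keepdims=True)
    new_dir = np.where(norm > 0, disp / np.where(norm == 0, 1.0, norm), prev_dir)
    if np.any(~np.isfinite(disp)):
        raise FloatingPointError("non-finite displacement in integration step")
    return disp, new_dir


def apply_boundaries(pos: np.ndarray, params: SimParams,
                     rng: np.random.Generator,
                     inset: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Detect box exits and draw replacement positions.

    Cells leaving the box die (their track ends); for each dead cell a
    replacement position is drawn uniformly on a random box face, offset
    ``inset`` um inward, so the live count is restored at the next step.
    Returns ``(exited_mask, replacement_positions)``.
    """
    box = np.asarray(params.box, float)
    pos = np.atleast_2d(pos)
    exited = np.any((pos < 0.0) | (pos > box), axis=1)
    n_new = int(exited.sum())
    repl = np.empty((n_new, 3))
    if n_new:
        repl[:] = rng.uniform(0.0, 1.0, (n_new, 3)) * box
        face_axis = rng.integers(0, 3, n_new)
        face_side = rng.integers(0, 2, n_new)
        repl[np.arange(n_new), face_axis] = np.where(
            face_side == 0, inset, box[face_axis] - inset)
    return exited, repl
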