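"""Chemokine concentration field of an immobile dendritic-cell point source.

A DC secretes chemokines at rate J(t) = j0 * f(t); the molecules diffuse
(D_CK) and degrade (characteristic time k), giving the screened steady
profile

    c_ss(r) = j0 * exp(-r / lambda) / (4 pi D_CK r),   lambda = sqrt(D_CK k).

Because the source modulation time tau (~1 h) is slow against the field
relaxation time k (~10 min), the transient field is well approximated by
separable forms.  Three evaluators of increasing fidelity are provided:

* the quasi-static product ``c_ss(r) * f(t)`` used inside the simulation,
  with the source factor f matched continuously across charging /
  discharging switches;
* the first-order charging form ``c_ss(r) - exp(-t/tau) * c_mod(r)`` where
  ``c_mod`` is the Yukawa kernel at the modified screening length
  lambda' = sqrt(D_CK / (1/k - 1/tau));
* the exact transient in closed (erfc) form, and a finite-volume
  Crank-Nicolson solver of the radial diffusion-degradation equation that
  serves as an independent numerical oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc

from .params import SimParams

__all__ = [
    "SourceMode", "FieldEval", "screening_length", "steady_profile",
    "time_factor", "evaluate", "chemotactic_drift",
    "first_order_charging", "exact_charging", "pde_oracle",
]


# ---------------------------------------------------------------------------
# source mode clock
# ---------------------------------------------------------------------------

@dataclass
class SourceMode:
    """State of one DC's chemokine source.

    ``discharging`` is True while at least one NK cell is interacting with
    the DC (the feedback loop suppresses secretion).  ``f_switch`` stores
    the source factor at the moment of the last mode change so that the
    factor is continuous in time.
    """

    discharging: bool = False
    t_switch: float = 0.0
    f_switch: float = 0.0

    def factor(self, t: float, tau: float, tau_discharge: Optional[float] = None) -> float:
        return time_factor(self, t, tau, tau_discharge)

    def switch(self, discharging: bool, t: float, tau: float,
               tau_discharge: Optional[float] = None) -> None:
        """Change mode at time ``t``, keeping the factor continuous."""
        if discharging != self.discharging:
            self.f_switch = self.factor(t, tau, tau_discharge)
            self.t_switch = t
            self.discharging = discharging


def time_factor(mode: SourceMode, t, tau: float,
                tau_discharge: Optional[float] = None):
    """Dimensionless source factor f(t) in [0, 1].

    Charging relaxes toward 1 with time constant ``tau``; discharging
    decays toward 0 with ``tau_discharge`` (defaulting to ``tau``), each
    continuing from the value recorded at the last mode switch.
    """
    t = np.asarray(t, float)
    if np.any(t < mode.t_switch):
        raise ValueError("t precedes the last mode switch")
    if mode.discharging:
        out = mode.f_switch * np.exp(-(t - mode.t_switch)
                                     / (tau if tau_discharge is None else tau_discharge))
    else:
        out = 1.0 - (1.0 - mode.f_switch) * np.exp(-(t - mode.t_switch) / tau)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# steady and transient radial profiles
# ---------------------------------------------------------------------------

def screening_length(d_ck: float, k_deg: float) -> float:
    """Chemokine screening length lambda = sqrt(D_CK * k) [um]."""
    return math.sqrt(d_ck * k_deg)


def steady_profile(r, j0: float, d_ck: float, k_deg: float, r_reg: float):
    """Steady concentration of a regularized point source [molecules/um^3].

    The Yukawa profile diverges at the origin; inside ``r_reg`` the
    concentration is clamped at its value on the regularization sphere,
    which also defines ``c_max = steady_profile(r_reg, ...)``.
    """
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if r_reg <= 0:
        raise ValueError("r_reg must be positive")
    lam = screening_length(d_ck, k_deg)
    rc = np.maximum(r, r_reg)
    out = j0 * np.exp(-rc / lam) / (4.0 * math.pi * d_ck * rc)
    return out if out.ndim else float(out)


def _yukawa(r, j0: float, d_ck: float, lam: float, r_reg: float):
    rc = np.maximum(np.asarray(r, float), r_reg)
    return j0 * np.exp(-rc / lam) / (4.0 * math.pi * d_ck * rc)


def modified_screening_length(d_ck: float, k_deg: float, tau: float) -> float:
    """lambda' = sqrt(D_CK / (1/k - 1/tau)); requires tau > k."""
    if tau <= k_deg:
        raise ValueError("the first-order form requires tau > k_deg")
    return math.sqrt(d_ck / (1.0 / k_deg - 1.0 / tau))


def first_order_charging(r, t, j0: float, d_ck: float, k_deg: float,
                         tau: float, r_reg: float):
    """First-order separable concentration for a source charging from zero.

    c(r,t) ~= c_ss(r) - exp(-t/tau) * c_mod(r), with c_mod the Yukawa
    kernel at the modified screening length lambda'.  The small negative
    undershoot near t = 0 (where the neglected diffusive transient
    dominates) is clamped to zero to restore positivity.
    """
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    lam = screening_length(d_ck, k_deg)
    lamp = modified_screening_length(d_ck, k_deg, tau)
    c = (_yukawa(r, j0, d_ck, lam, r_reg)
         - np.exp(-t / tau) * _yukawa(r, j0, d_ck, lamp, r_reg))
    out = np.maximum(c, 0.0)
    return out if out.ndim else float(out)


def _green_cumulative(r, t, d_ck: float, kappa: float):
    """Integral_0^t exp(-s/kappa) * exp(-r^2/4Ds) / (4 pi D s)^{3/2} ds,
    times 4 pi D r — i.e. the dimensionless charging factor of the Yukawa
    profile at screening length sqrt(D*kappa)."""
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    lam = math.sqrt(d_ck * kappa)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = r / np.sqrt(4.0 * d_ck * t)
        b = np.sqrt(t / kappa)
        val = 0.5 * (np.exp(-r / lam) * erfc(a - b)
                     + np.exp(r / lam) * erfc(a + b))
    return np.where(t > 0, val, 0.0)


def exact_charging(r, t, j0: float, d_ck: float, k_deg: float,
                   tau: float, r_reg: float):
    """Exact transient concentration for J(t) = j0 * (1 - exp(-t/tau)).

    Closed form of the Fourier-transform solution of the
    diffusion-degradation equation with an adiabatically switched-on point
    source: the difference of two erfc-type charging integrals, at the
    nominal and at the modified screening lengths.
    """
    r = np.maximum(np.asarray(r, float), r_reg)
    t = np.asarray(t, float)
    kprime = 1.0 / (1.0 / k_deg - 1.0 / tau)
    pref = j0 / (4.0 * math.pi * d_ck * r)
    c = pref * (_green_cumulative(r, t, d_ck, k_deg)
                - np.exp(-t / tau) * _green_cumulative(r, t, d_ck, kprime))
    out = np.maximum(c, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# field evaluation for the simulator
# ---------------------------------------------------------------------------

@dataclass
class FieldEval:
    """Concentration, gradient and normalized level at one point."""

    c: float                 # [molecules/um^3]
    grad_c: np.ndarray       # [molecules/um^4], points toward the source
    c_over_cmax: float       # in [0, 1]


def evaluate(dc_pos: np.ndarray, mode: SourceMode, nk_pos: np.ndarray,
             t: float, params: SimParams) -> FieldEval:
    """Separable field of one DC at one NK position.

    c = c_ss(|nk - dc|) * f(t); the gradient is radial and vanishes inside
    the regularized core, so no force ever diverges.
    """
    r_reg = params.reg_radius
    sep = np.asarray(nk_pos, float) - np.asarray(dc_pos, float)
    r = float(np.linalg.norm(sep))
    f = time_factor(mode, t, params.tau)
    c_ss = steady_profile(r, params.j0, params.d_ck, params.k_deg, r_reg)
    c_max = steady_profile(r_reg, params.j0, params.d_ck, params.k_deg, r_reg)
    c = c_ss * f
    if r > r_reg:
        lam = screening_length(params.d_ck, params.k_deg)
        dcdr = -c_ss * (1.0 / r + 1.0 / lam)  # radial derivative, < 0
        grad = f * dcdr * (sep / r)
    else:
        grad = np.zeros(3)
    return FieldEval(c=float(c), grad_c=grad,
                     c_over_cmax=float(c / c_max) if c_max > 0 else 0.0)


def chemotactic_drift(field: FieldEval, chi_phys: float, gamma_r: float) -> np.ndarray:
    """Drift velocity chi_phys * grad(c) / gamma [um/s]."""
    if gamma_r <= 0:
        raise ValueError("gamma_r must be positive")
    return chi_phys * field.grad_c / gamma_r


# ---------------------------------------------------------------------------
# numerical oracle
# ---------------------------------------------------------------------------

def pde_oracle(params: SimParams, r_grid: np.ndarray, t_eval: np.ndarray,
               dr: float = 0.1, dt: float = 2.0, source_radius: float = 0.5,
               r_max: float | None = None, charging: bool = True) -> np.ndarray:
    """Direct numerical solution of the radial diffusion-degradation PDE.

        dc/dt = D_CK (1/r^2) d/dr (r^2 dc/dr) - c/k + s(r, t)

    The point source is represented as a uniform volumetric source inside a
    small ball of radius ``source_radius`` (corrections to the exterior
    solution are O((source_radius/lambda)^2), i.e. negligible); its total
    strength is j0 * f(t) with f the charging factor 1 - exp(-t/tau) (or 1
    for a constant source when ``charging`` is False).  Conservative
    finite-volume discretization in spherical shells, Crank-Nicolson in
    time, absorbing far boundary.

    Returns the concentration on ``r_grid`` at each time in ``t_eval``
    (shape ``(len(t_eval), len(r_grid))``), linearly interpolated from the
    solver grid.  Raises if the solution loses positivity.
    """
    lam = screening_length(params.d_ck, params.k_deg)
    if r_max is None:
        r_max = 5.0 * lam
    if np.max(r_grid) > r_max:
        raise ValueError("r_grid extends beyond the solver domain")
    n = int(round(r_max / dr))
    edges = np.linspace(0.0, r_max, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    area = 4.0 * math.pi * edges[1:-1] ** 2  # interior faces

    D = params.d_ck
    # flux coupling between neighbouring shells across interior face i: w[i]
    w = area * D / dr  # length n-1
    # tridiagonal operator L (diffusion + degradation):
    #   dg[i] = L[i,i], sup[i] = L[i,i+1], sub[i] = L[i+1,i]
    dg = np.full(n, -1.0 / params.k_deg)
    dg[:-1] -= w / vol[:-1]
    dg[1:] -= w / vol[1:]
    # absorbing outer boundary: ghost cell with c = 0 beyond r_max
    dg[-1] -= 4.0 * math.pi * r_max**2 * D / dr / vol[-1]
    sup = w / vol[:-1]
    sub = w / vol[1:]

    # source density [molecules/um^3/s]: deposit exactly j0/s in total,
    # split among cells by overlap volume with the source ball
    v_src = 4.0 / 3.0 * math.pi * source_radius**3
    overlap = np.clip(
        4.0 / 3.0 * math.pi * np.minimum(edges[1:], source_radius) ** 3
        - 4.0 / 3.0 * math.pi * np.minimum(edges[:-1], source_radius) ** 3,
        0.0, None)
    src = params.j0 * (overlap / v_src) / vol

    t_end = float(np.max(t_eval))
    n_t = int(math.ceil(t_end / dt))
    # Crank-Nicolson: (I - dt/2 L) c_{j+1} = (I + dt/2 L) c_j + dt * s_{j+1/2}
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * dt * sup
    ab[1, :] = 1.0 - 0.5 * dt * dg
    ab[2, :-1] = -0.5 * dt * sub

    c = np.zeros(n)
    out = np.empty((len(t_eval), len(r_grid)))
    t_eval = np.asarray(t_eval, float)
    recorded = np.zeros(len(t_eval), bool)

    def record(t_now: float, c_now: np.ndarray) -> None:
        for i, te in enumerate(t_eval):
            if not recorded[i] and t_now >= te - 1e-9:
                out[i] = np.interp(r_grid, centers, c_now)
                recorded[i] = True

    record(0.0, c)
    t_now = 0.0
    for _ in range(n_t):
        t_mid = t_now + 0.5 * dt
        f = (1.0 - math.exp(-t_mid / params.tau)) if charging else 1.0
        lc = dg * c
        lc[:-1] += sup * c[1:]
        lc[1:] += sub * c[:-1]
        rhs = c + 0.5 * dt * lc + dt * src * f
        c = solve_banded((1, 1), ab, rhs)
        t_now += dt
        if np.min(c) < -1e-9 * max(np.max(c), 1e-30):
            raise RuntimeError("PDE oracle lost positivity (unstable discretization)")
        record(t_now, c)
    if not recorded.all():
        raise ValueError("t_eval contains times beyond the integration window")
    return out
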