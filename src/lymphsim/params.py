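"""Physical parameters of the NK-cell / dendritic-cell simulation.

All quantities are carried in a single internal unit system: micrometres,
seconds, kelvin, kilograms and molecule counts.  Forces never appear as bare
newtons; every deterministic term of the dynamics is expressed as a drift
velocity F/gamma in um/s, which keeps magnitudes well conditioned.

The default parameter set describes 100 Natural Killer (NK) cells diffusing
in a 500 x 500 x 50 um^3 lymph-node box around 10 immobile dendritic cells
(DCs) that act as chemokine point sources, with a 1 s integration step.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

#: Boltzmann constant [J/K].
K_B = 1.380649e-23

#: Conversion factor m^2 -> um^2.
_M2_TO_UM2 = 1.0e12

#: Default intrinsic NK diffusion coefficient [um^2/s], chosen so that the
#: per-second 3D RMS step sqrt(6*D0*1 s) equals the typical instantaneous
#: NK speed of 0.2 um/s measured at a 1 s sampling interval.
DEFAULT_D_NK0 = 0.2**2 / 6.0


class ConfigurationError(ValueError):
    """Raised when a parameter set is inconsistent or incomplete."""


@dataclass
class SimParams:
    """Full parameter set of the simulation.

    Exactly one of ``viscosity`` [Pa s] and ``d_nk0`` [um^2/s] must be
    given; the other is derived through the Stokes-Einstein relation.
    ``chi`` is dimensionless on the 0-1 sweep axis and is multiplied
    internally by the kinetic-energy reference value ``chi_ref``
    (see :func:`chi_ref_estimate`).
    """

    dt: float = 1.0                       # integration time step [s]
    n_steps: int = 40_000                 # number of steps
    box: Tuple[float, float, float] = (500.0, 500.0, 50.0)  # [um]
    n_nk: int = 100                       # number of NK cells
    n_dc: int = 10                        # number of DCs (if positions not given)
    dc_positions: Optional[np.ndarray] = None  # (m, 3) [um]
    r_nk: float = 5.0                     # NK radius [um]
    temperature: float = 310.0            # [K]
    viscosity: Optional[float] = None     # effective medium viscosity [Pa s]
    d_nk0: Optional[float] = DEFAULT_D_NK0  # intrinsic NK diffusion [um^2/s]
    k_gamma: float = 10.0                 # friction-dip amplitude (dimensionless)
    s_gamma: float = 25.0                 # friction-dip range [um]
    a0: float = 25.0                      # interaction gate radius [um]
    chi: float = 0.0                      # chemotactic parameter, 0-1 axis
    d_ck: float = 10.0                    # chemokine diffusion [um^2/s]
    k_deg: float = 600.0                  # chemokine degradation time [s]
    tau: float = 3600.0                   # source (de)activation time [s]
    j0: float = 1000.0                    # source strength [molecules/s]
    sigma_theta: Optional[float] = 0.3    # WLC deviation-angle std [rad]; None = isotropic
    t_th: float = 600.0                   # long-interaction threshold [s]
    m_nk: float = 9.0e-13                 # NK mass [kg]
    v_dc: float = 2.0e4                   # DC volume [um^3]
    n_ck: float = 1.0e5                   # chemokines per DC
    v_typ: float = 0.2                    # typical NK speed [um/s]
    r_reg: Optional[float] = None         # field regularization radius [um]; None -> r_nk
    init_mode: str = "stationary"         # "stationary" or "uniform" NK placement
    record_stride: int = 10               # trajectory recording stride [steps]
    seed: int = 0                         # master RNG seed

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.n_steps <= 0:
            raise ConfigurationError("n_steps must be positive")
        if any(L <= 0 for L in self.box):
            raise ConfigurationError("box lengths must be positive")
        for name in ("r_nk", "temperature", "d_ck", "k_deg", "tau", "s_gamma",
                     "m_nk", "v_dc", "v_typ", "t_th"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.j0 < 0 or self.n_ck < 0:
            raise ConfigurationError("j0 and n_ck must be non-negative")
        if self.chi < 0:
            raise ConfigurationError("chi must be non-negative")
        if self.k_gamma < 0:
            raise ConfigurationError("k_gamma must be non-negative")
        if self.a0 < self.r_nk:
            raise ConfigurationError("a0 must be at least r_nk")
        if self.viscosity is None and self.d_nk0 is None:
            raise ConfigurationError(
                "one of viscosity or d_nk0 must be given")
        if self.viscosity is not None and self.d_nk0 is not None \
                and not math.isclose(self.d_nk0, _d0_from_viscosity(self), rel_tol=1e-9):
            raise ConfigurationError(
                "viscosity and d_nk0 both given but inconsistent; set one to None")
        if self.sigma_theta is not None and self.sigma_theta < 0:
            raise ConfigurationError("sigma_theta must be non-negative or None")
        if self.record_stride < 1:
            raise ConfigurationError("record_stride must be >= 1")
        if self.init_mode not in ("stationary", "uniform"):
            raise ConfigurationError("init_mode must be 'stationary' or 'uniform'")
        if self.dc_positions is not None:
            self.dc_positions = np.atleast_2d(np.asarray(self.dc_positions, float))
            if self.dc_positions.shape[1] != 3:
                raise ConfigurationError("dc_positions must be (m, 3)")
            self.n_dc = len(self.dc_positions)

    @property
    def reg_radius(self) -> float:
        """Field regularization radius [um] (defaults to the NK radius)."""
        return self.r_nk if self.r_reg is None else self.r_reg

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["dc_positions"] is not None:
            d["dc_positions"] = np.asarray(d["dc_positions"]).tolist()
        d["box"] = list(d["box"])
        return d


@dataclass(frozen=True)
class DerivedConstants:
    """Quantities derived from a :class:`SimParams`.

    gamma0    intrinsic friction coefficient [kg/s]
    d0        intrinsic diffusion coefficient [um^2/s]
    viscosity effective medium viscosity [Pa s]
    sigma_step per-axis RMS displacement per step sqrt(2*d0*dt) [um]
    lam       chemokine screening length sqrt(d_ck*k_deg) [um]
    chi_ref   reference chemotactic parameter [kg um^5 / (s^2 molecule)]
    chi_phys  physical chemotactic parameter chi * chi_ref
    """

    gamma0: float
    d0: float
    viscosity: float
    sigma_step: float
    lam: float
    chi_ref: float
    chi_phys: float


def _d0_from_viscosity(params: SimParams) -> float:
    gamma0 = 6.0 * math.pi * params.viscosity * params.r_nk * 1e-6  # kg/s
    return K_B * params.temperature / gamma0 * _M2_TO_UM2


def derive_constants(params: SimParams) -> DerivedConstants:
    """Derive the Stokes-Einstein and chemokine constants from ``params``."""
    if params.d_nk0 is not None:
        d0 = params.d_nk0
        gamma0 = K_B * params.temperature / (d0 / _M2_TO_UM2)
        viscosity = gamma0 / (6.0 * math.pi * params.r_nk * 1e-6)
    elif params.viscosity is not None:
        viscosity = params.viscosity
        gamma0 = 6.0 * math.pi * viscosity * params.r_nk * 1e-6
        d0 = K_B * params.temperature / gamma0 * _M2_TO_UM2
    else:  # pragma: no cover - guarded by validate()
        raise ConfigurationError("one of viscosity or d_nk0 must be given")
    chi_ref = chi_ref_estimate(params.m_nk, params.v_typ, params.v_dc, params.n_ck)
    return DerivedConstants(
        gamma0=gamma0,
        d0=d0,
        viscosity=viscosity,
        sigma_step=math.sqrt(2.0 * d0 * params.dt),
        lam=math.sqrt(params.d_ck * params.k_deg),
        chi_ref=chi_ref,
        chi_phys=params.chi * chi_ref,
    )


def chi_ref_estimate(m_nk: float, v_typ: float, v_dc: float, n_ck: float) -> float:
    """Kinetic-energy estimate of the chemotactic parameter scale.

    chi_ref = (1/2 m v^2) * V_DC / N_CK, the average NK kinetic energy per
    unit chemokine concentration in a DC volume.  Units:
    kg um^5 / (s^2 molecule), so that chi_ref * grad(c) / gamma is a drift
    velocity in um/s.
    """
    if m_nk <= 0 or v_typ <= 0 or v_dc <= 0 or n_ck <= 0:
        raise ConfigurationError("chi_ref inputs must be positive")
    return 0.5 * m_nk * v_typ**2 * v_dc / n_ck


@dataclass(frozen=True)
class RegimeReport:
    """Check of the constant-degradation-rate assumption.

    The chemokine loss on NK cells (Smoluchowski encounter rate
    4*pi*D_CK*r_NK*n_NK) must be small against the production rate
    N_CK/tau for the degradation time to be treated as concentration
    independent.
    """

    production_rate: float   # [1/s]
    consumption_rate: float  # [1/s]
    ok: bool


def validate_regime(params: SimParams, tau: Optional[float] = None,
                    safety_factor: float = 10.0) -> RegimeReport:
    """Compare chemokine production against consumption on NK cells.

    ``tau`` overrides the source time constant used for the production
    estimate (the headline ~330 1/s figure uses tau = 300 s).
    """
    tau = params.tau if tau is None else tau
    production = params.n_ck / tau
    n_conc = params.n_nk / (params.box[0] * params.box[1] * params.box[2])  # [1/um^3]
    consumption = 4.0 * math.pi * params.d_ck * params.r_nk * n_conc
    ok = production > 0 and consumption * safety_factor <= production
    return RegimeReport(production_rate=production,
                        consumption_rate=consumption, ok=ok)


def place_dcs(params: SimParams, rng: np.random.Generator,
              min_separation: float = 50.0, max_tries: int = 10_000) -> np.ndarray:
    """Place DCs uniformly at random in the box with a minimum pairwise distance."""
    if params.dc_positions is not None:
        return np.asarray(params.dc_positions, float)
    box = np.asarray(params.box, float)
    placed: list[np.ndarray] = []
    for _ in range(max_tries):
        p = rng.uniform(0.0, 1.0, 3) * box
        if all(np.linalg.norm(p - q) >= min_separation for q in placed):
            placed.append(p)
            if len(placed) == params.n_dc:
                return np.array(placed)
    raise ConfigurationError(
        f"could not place {params.n_dc} DCs with separation {min_separation} um")
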