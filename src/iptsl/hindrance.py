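"""Size-dependent transport coefficients for nanoparticles.

Three standard ingredients: Stokes-Einstein free diffusion, Ogston-type
fiber-matrix retardation in the interstitium, and the cylindrical-pore
(Renkin/Deen) model of the vessel wall, which yields a permeability and a
filtration reflection coefficient from the particle-to-pore radius ratio
lambda = a / r_p.  Particles at or above the pore size are sterically
excluded (P_eff = 0, sigma_f = 1) - the mechanism that keeps large
thermosensitive liposomes from leaking out of tumor vessels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

K_BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class HindranceCoefficients:
    D0: float        # free-solution diffusivity, m^2/s
    D_L: float       # interstitial (fiber-matrix) diffusivity, m^2/s
    P_eff: float     # vessel-wall permeability, m/s
    sigma_f: float   # filtration reflection coefficient, in [0, 1]
    lam: float       # particle radius / pore radius


def stokes_einstein_D0(diameter: float, T: float = 310.15, viscosity: float = 7.0e-4) -> float:
    """Free-solution diffusivity D0 = k_B T / (3 pi mu d), m^2/s."""
    if diameter <= 0 or T <= 0 or viscosity <= 0:
        raise ValueError("diameter, temperature and viscosity must be positive")
    return K_BOLTZMANN * T / (3.0 * math.pi * viscosity * diameter)


def fiber_matrix_DL(D0: float, particle_radius: float, fiber_radius_af: float,
                    fiber_fraction: float) -> float:
    """Ogston-form interstitial diffusivity
    D_L = D0 exp(-sqrt(phi_f) (1 + a/a_f))."""
    if particle_radius < 0:
        raise ValueError("particle radius must be non-negative")
    if not 0.0 <= fiber_fraction < 1.0:
        raise ValueError("fiber volume fraction must be in [0, 1)")
    return D0 * math.exp(-math.sqrt(fiber_fraction) * (1.0 + particle_radius / fiber_radius_af))


def renkin_hindrance(lam: float) -> float:
    """Steric partition times the Renkin hydrodynamic hindrance,
    H(lam) = (1-lam)^2 (1 - 2.104 lam + 2.09 lam^3 - 0.95 lam^5), 0 for lam >= 1."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam >= 1.0:
        return 0.0
    return (1.0 - lam) ** 2 * (1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)


def pore_area_factor(P_reference: float, D0_reference: float, reference_radius: float,
                     rp: float, delta_wall: float) -> float:
    """Calibrate the dimensionless pore-area fraction gamma so that the pore
    model reproduces a measured reference permeability (free doxorubicin)."""
    lam = reference_radius / rp
    H = renkin_hindrance(lam)
    if H <= 0:
        raise ValueError("reference solute must fit through the pores")
    return P_reference * delta_wall / (H * D0_reference)


def pore_model(particle_radius: float, rp: float, delta_wall: float, D0: float,
               gamma: float) -> tuple[float, float]:
    """Vessel-wall permeability and reflection coefficient from the pore model.

    P_eff = gamma H(lam) D0 / delta_wall;
    sigma_f = 1 - Phi(2 - Phi) max(0, 1 - lam^2/3), Phi = (1 - lam)^2,
    clipped to [0, 1]; complete exclusion (0, 1) for lam >= 1.
    """
    if rp <= 0 or delta_wall <= 0:
        raise ValueError("pore radius and wall thickness must be positive")
    lam = particle_radius / rp
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam >= 1.0:
        return 0.0, 1.0
    P_eff = gamma * renkin_hindrance(lam) * D0 / delta_wall
    phi_p = (1.0 - lam) ** 2
    sigma_f = 1.0 - phi_p * (2.0 - phi_p) * max(0.0, 1.0 - lam**2 / 3.0)
    return P_eff, min(max(sigma_f, 0.0), 1.0)


def liposome_coefficients(config) -> HindranceCoefficients:
    """All hindered-transport coefficients for the scenario's TSL diameter."""
    t = config.tissue
    tr = config.transport
    a = config.tsl_diameter / 2.0
    D0 = stokes_einstein_D0(config.tsl_diameter, viscosity=tr.viscosity)
    D_L = fiber_matrix_DL(D0, a, t.a_f, tr.fiber_fraction)
    D0_dox = stokes_einstein_D0(tr.dox_diameter, viscosity=tr.viscosity)
    gamma = pore_area_factor(tr.P_dox, D0_dox, tr.dox_diameter / 2.0, t.r_p, t.delta_wall)
    P_eff, sigma_f = pore_model(a, t.r_p, t.delta_wall, D0, gamma)
    return HindranceCoefficients(D0=D0, D_L=D_L, P_eff=P_eff, sigma_f=sigma_f, lam=a / t.r_p)
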