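"""Scenario configuration: physical parameters, presets and validation.

All quantities are stored in SI units (m, s, Pa, K, mol·m⁻³).  Config files
may use the conventional literature units for a few parameters (molar
concentrations, cm²·s⁻¹ diffusivities); those are normalized on load, see
:func:`load_config`.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

MOLAR = 1000.0  # 1 mol/L in mol/m^3
CM2_S = 1e-4  # cm^2/s in m^2/s
CM_S = 1e-2  # cm/s in m/s


@dataclass
class TissueParams:
    """Vascular / interstitial fluid parameters of the tumor (Starling/Darcy)."""

    kappa: float = 3e-14            # interstitial hydraulic conductivity, m^2 Pa^-1 s^-1
    L_P: float = 2.10e-11           # vessel wall hydraulic conductivity, m Pa^-1 s^-1
    S_over_V: float = 2e4           # vascular surface area density, m^-1
    P_B: float = 2100.0             # microvascular blood pressure, Pa
    pi_B: float = 2700.0            # plasma osmotic pressure, Pa
    pi_i: float = 2000.0            # interstitial osmotic pressure, Pa
    sigma_s: float = 0.9            # osmotic reflection coefficient for plasma proteins
    a_f: float = 200e-9             # matrix fiber radius, m
    r_p: float = 200e-9             # vessel wall pore radius, m
    delta_wall: float = 5e-6        # vessel wall thickness, m

    @property
    def effective_pressure(self) -> float:
        """Effective filtration pressure P_e = P_B - sigma_s (pi_B - pi_i), Pa."""
        return self.P_B - self.sigma_s * (self.pi_B - self.pi_i)

    @property
    def alpha_flow(self) -> float:
        """Inverse pressure-screening length sqrt(L_P (S/V) / kappa), m^-1."""
        return math.sqrt(self.L_P * self.S_over_V / self.kappa)


@dataclass
class TransportParams:
    """Solute transport parameters for doxorubicin and its carriers."""

    D_F: float = 3.40e-6 * CM2_S    # free drug interstitial diffusivity, m^2/s
    P_dox: float = 3.00e-4 * CM_S   # free drug vessel wall permeability, m/s
    K_ON: float = 1.5e2 / MOLAR     # binding rate constant, m^3 mol^-1 s^-1
    K_OFF: float = 8e-3             # unbinding rate constant, s^-1
    K_INT: float = 5e-5             # internalization rate constant, s^-1
    phi: float = 0.3                # accessible volume fraction
    C_rec: float = 1e-5 * MOLAR     # receptor concentration, mol/m^3
    omega: float = 0.6603           # survival-model constant, m^3/mol
    fiber_fraction: float = 0.05    # matrix fiber volume fraction (fiber-matrix model)
    viscosity: float = 7.0e-4       # interstitial fluid viscosity at 37 C, Pa s
    dox_diameter: float = 1.2e-9    # free doxorubicin hydrodynamic diameter, m
    phi_divides_transvascular: bool = True  # apply 1/phi to transvascular exchange
    necrotic_binding: bool = True   # keep binding/internalization in the necrotic core

    @property
    def k_on_eff(self) -> float:
        """Forward binding rate (1/phi) K_ON C_rec, s^-1."""
        return self.K_ON * self.C_rec / self.phi


@dataclass
class RegionThermal:
    rho: float      # density, kg/m^3
    c: float        # specific heat, J kg^-1 K^-1
    K: float        # thermal conductivity, W m^-1 K^-1
    w_b0: float     # baseline blood perfusion rate, s^-1


@dataclass
class ThermalParams:
    """Bioheat, damage and controller constants."""

    tumor: RegionThermal = field(default_factory=lambda: RegionThermal(1000.0, 3800.0, 0.552, 0.002))
    normal: RegionThermal = field(default_factory=lambda: RegionThermal(1055.0, 3600.0, 0.512, 0.018))
    rho_b: float = 1050.0           # blood density, kg/m^3
    c_b: float = 3617.0             # blood specific heat, J kg^-1 K^-1
    T_body: float = 37.0            # body / boundary temperature, C
    A_f: float = 1.98e106           # Arrhenius frequency factor, s^-1
    dE: float = 6.67e5              # Arrhenius activation energy, J/mol
    R_gas: float = 8.314            # gas constant, J mol^-1 K^-1
    K_p: float = 0.2                # PI proportional gain, 1/K
    K_i: float = 0.01               # PI integral gain, 1/(K s)
    T_set: float = 43.0             # controller set point at the probe, C


@dataclass
class AcousticParams:
    """Single-element bowl transducer and medium acoustics."""

    inner_diameter: float = 20.0e-3   # central hole diameter, m
    outer_diameter: float = 70.0e-3   # aperture diameter, m
    focal_length: float = 62.64e-3    # radius of curvature, m
    sound_speed: float = 1550.0       # m/s (identical in tumor and normal tissue)
    density: float = 1000.0           # acoustic reference density, kg/m^3
    alpha_per_MHz: float = 8.55       # absorption coefficient, Np m^-1 MHz^-1
    source_pressure: float = 2.5e4    # surface pressure amplitude rho*c*u0, Pa

    def alpha_abs(self, f: float) -> float:
        """Absorption coefficient at frequency f [Hz], Np/m."""
        return self.alpha_per_MHz * f / 1e6


@dataclass
class Numerics:
    """Grid spacings, time steps and tolerances."""

    # transport/flow radial mesh (tumor interior)
    dr_coarse: float = 250e-6       # interior spacing, m
    dr_fine: float = 7.5e-6         # spacing in the surface band, m
    surface_band: float = 600e-6    # width of the uniformly fine band at the surface, m
    grading_ratio: float = 1.25     # geometric grading between coarse and fine zones
    n_theta: int = 24               # polar cells over [0, pi]
    # thermal extension beyond the tumor
    dr_outer_start: float = 100e-6  # first cell outside the tumor, m
    dr_outer_max: float = 2.5e-3    # cap on outer spacing, m
    outer_grading: float = 1.35
    thermal_margin: float = 25e-3   # thermal domain radius >= max(4R, R+margin), m
    # time stepping
    dt_transport: float = 1.0       # s
    dt_thermal_ramp: float = 0.1    # s, while the controller ramps up
    t_ramp: float = 100.0           # s
    dt_thermal_mid: float = 0.5     # s
    t_mid: float = 300.0            # s
    dt_thermal: float = 2.0         # s, quasi-steady
    thermal_snapshot_every: float = 30.0   # s
    transport_snapshot_every: float = 300.0  # s
    flow_rtol: float = 1e-10
    acoustic_ppw: float = 4.0       # quadrature points per wavelength on the source
    planar: bool = False            # planar-2D (polar) metric instead of spherical


@dataclass
class ScenarioConfig:
    """Full description of one simulation scenario."""

    mode: str = "conventional"                 # "conventional" | "tsl"
    tumor_radius_R: float = 10e-3              # m
    necrotic_radius_Rn: float | None = None    # m, defaults to R/2
    tsl_diameter: float = 100e-9               # m (tsl mode)
    hifu_frequency: float = 1.0e6              # Hz (tsl mode)
    treatment_duration: float = 3600.0         # s
    boundary_concentration: float = 0.8        # mol/m^3, cavity reservoir
    scenario_id: str = "run"
    tissue: TissueParams = field(default_factory=TissueParams)
    transport: TransportParams = field(default_factory=TransportParams)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    acoustic: AcousticParams = field(default_factory=AcousticParams)
    numerics: Numerics = field(default_factory=Numerics)

    def __post_init__(self) -> None:
        if self.necrotic_radius_Rn is None:
            self.necrotic_radius_Rn = self.tumor_radius_R / 2.0
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("conventional", "tsl"):
            raise ValueError(f"unknown mode {self.mode!r}")
        R, Rn = self.tumor_radius_R, self.necrotic_radius_Rn
        if not (0.0 < Rn < R):
            raise ValueError(f"necrotic radius must satisfy 0 < Rn < R (got Rn={Rn}, R={R})")
        positive = {
            "tumor_radius_R": R,
            "treatment_duration": self.treatment_duration,
            "boundary_concentration": self.boundary_concentration,
            "kappa": self.tissue.kappa,
            "L_P": self.tissue.L_P,
            "S_over_V": self.tissue.S_over_V,
            "D_F": self.transport.D_F,
            "phi": self.transport.phi,
            "r_p": self.tissue.r_p,
            "delta_wall": self.tissue.delta_wall,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"physical parameter {name} must be positive (got {value})")
        if self.tissue.P_B < 0 or self.tissue.pi_B < 0 or self.tissue.pi_i < 0:
            raise ValueError("pressures must be non-negative")
        if self.mode == "tsl":
            if self.hifu_frequency <= 0:
                raise ValueError("hifu_frequency must be positive in tsl mode")
            if not (1e-9 <= self.tsl_diameter <= 1e-6):
                raise ValueError("tsl_diameter outside the supported 1 nm - 1 um range")


_UNIT_NORMALIZERS = {
    # config-file key -> (target dataclass field, factor to SI)
    "C_rec_M": ("C_rec", MOLAR),
    "K_ON_per_M_s": ("K_ON", 1.0 / MOLAR),
    "D_F_cm2_s": ("D_F", CM2_S),
    "P_dox_cm_s": ("P_dox", CM_S),
}


def _apply_block(obj: Any, block: dict[str, Any]) -> Any:
    """Return a copy of dataclass ``obj`` updated from a config block."""
    known = {f.name for f in fields(obj)}
    updates: dict[str, Any] = {}
    for key, value in block.items():
        if key in _UNIT_NORMALIZERS:
            name, factor = _UNIT_NORMALIZERS[key]
            updates[name] = value * factor
        elif key in known:
            current = getattr(obj, key)
            if isinstance(current, RegionThermal) and isinstance(value, dict):
                updates[key] = replace(current, **value)
            else:
                updates[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return replace(obj, **updates)


def config_from_dict(doc: dict[str, Any]) -> ScenarioConfig:
    """Build a validated ScenarioConfig from a nested dict (TOML layout)."""
    cfg = ScenarioConfig.__new__(ScenarioConfig)
    base = ScenarioConfig()
    for f in fields(ScenarioConfig):
        setattr(cfg, f.name, getattr(base, f.name))
    cfg.necrotic_radius_Rn = None  # defaults to R/2 of the *loaded* radius
    scenario = dict(doc.get("scenario", {}))
    top_keys = {
        "mode", "tumor_radius_R", "necrotic_radius_Rn", "tsl_diameter",
        "hifu_frequency", "treatment_duration", "boundary_concentration",
        "scenario_id",
    }
    for key, value in scenario.items():
        if key not in top_keys:
            raise ValueError(f"unknown [scenario] key {key!r}")
        setattr(cfg, key, value)
    for block_name, attr in (
        ("tissue", "tissue"), ("transport", "transport"),
        ("thermal", "thermal"), ("acoustic", "acoustic"), ("numerics", "numerics"),
    ):
        if block_name in doc:
            setattr(cfg, attr, _apply_block(getattr(cfg, attr), doc[block_name]))
    if cfg.necrotic_radius_Rn is None:
        cfg.necrotic_radius_Rn = cfg.tumor_radius_R / 2.0
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a TOML scenario configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return config_from_dict(doc)
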