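"""Independent closed-form references and toy-field generators.

Everything in this module is derived analytically, independently of the
finite-volume solvers, so each solver can be checked against it without
running the full pipeline: the two-region spherical flow solution, the
on-axis field of a focused bowl source, the free-space heat kernel, the
half-space diffusion profile, and dense matrix-exponential integration of
semi-discrete reaction-transport systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .config import ScenarioConfig
from .geometry import DomainGrid


@dataclass
class AnalyticFlowSolution:
    """Closed-form steady pressure/velocity for a two-region spherical tumor.

    Shell (Rn < rho < R):  P_e - P_i = (a e^{alpha(rho-R)} + b e^{-alpha(rho-Rn)})/rho
    Core  (rho < Rn):      P_i constant, zero velocity.
    """

    alpha: float
    P_e: float
    kappa: float
    R: float
    Rn: float
    a: float
    b: float

    def _u(self, rho):
        rho = np.asarray(rho, dtype=float)
        return (self.a * np.exp(self.alpha * (rho - self.R))
                + self.b * np.exp(-self.alpha * (rho - self.Rn))) / rho

    def _du(self, rho):
        rho = np.asarray(rho, dtype=float)
        ea = np.exp(self.alpha * (rho - self.R))
        eb = np.exp(-self.alpha * (rho - self.Rn))
        return (self.alpha * (self.a * ea - self.b * eb)) / rho - (self.a * ea + self.b * eb) / rho**2

    def pressure(self, rho):
        """Interstitial pressure P_i(rho), Pa."""
        rho = np.asarray(rho, dtype=float)
        core = self.P_e - self._u(np.full_like(rho, self.Rn, dtype=float))
        shell = self.P_e - self._u(np.clip(rho, self.Rn, None))
        return np.where(rho < self.Rn, core, shell)

    def velocity(self, rho):
        """Radial interstitial fluid velocity, m/s (outward positive)."""
        rho = np.asarray(rho, dtype=float)
        v = self.kappa * self._du(np.clip(rho, self.Rn, None))
        return np.where(rho < self.Rn, 0.0, v)

    def ode_residual(self, n: int = 1000) -> float:
        """Max residual of (1/r^2)(r^2 u')' = alpha^2 u at n interior radii."""
        rho = np.linspace(self.Rn * 1.001, self.R * 0.999, n)
        h = (self.R - self.Rn) * 1e-4
        du = (self._u(rho + h) - self._u(rho - h)) / (2 * h)
        d2u = (self._u(rho + h) - 2 * self._u(rho) + self._u(rho - h)) / h**2
        res = d2u + 2.0 / rho * du - self.alpha**2 * self._u(rho)
        scale = self.alpha**2 * max(np.max(np.abs(self._u(rho))), 1e-300)
        return float(np.max(np.abs(res)) / scale)


def analytic_flow(R: float, Rn: float, params: ScenarioConfig) -> AnalyticFlowSolution:
    """Exact steady Darcy/Starling solution for the spherical two-region tumor."""
    if not 0 < Rn < R:
        raise ValueError("need 0 < Rn < R")
    t = params.tissue
    alpha = t.alpha_flow
    P_e = t.effective_pressure
    E = np.exp(-alpha * (R - Rn))
    # u(R) = P_e  and  u'(Rn) = 0
    ratio = (alpha - 1.0 / Rn) / (alpha + 1.0 / Rn)
    a = R * P_e / (1.0 + E**2 * ratio)
    b = a * E * ratio
    return AnalyticFlowSolution(alpha=alpha, P_e=P_e, kappa=t.kappa, R=R, Rn=Rn, a=a, b=b)


def bowl_axis_pressure(z, focal_length: float, outer_diameter: float,
                       inner_diameter: float, k: complex, p0: float):
    """On-axis pressure amplitude of a spherically focused bowl (exact
    Rayleigh integral for uniform surface velocity; O'Neil's solution).

    ``z`` is measured from the apex along the beam axis (focus at
    z = focal_length); ``p0 = rho c u0`` is the surface pressure amplitude;
    ``k`` may be complex to include absorption.  Returns |p|.
    """
    z = np.asarray(z, dtype=float)
    F = focal_length
    sin_out = (outer_diameter / 2.0) / F
    sin_in = (inner_diameter / 2.0) / F
    cos_out = np.sqrt(1.0 - sin_out**2)
    cos_in = np.sqrt(1.0 - sin_in**2)
    s = F - z  # signed distance from the focus
    out = np.empty_like(z, dtype=float)
    small = np.abs(s) < 1e-9 * F
    d_of = np.sqrt(F**2 + s**2 - 2 * F * s * cos_out)
    d_if = np.sqrt(F**2 + s**2 - 2 * F * s * cos_in)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = p0 * (F / s) * (np.exp(1j * k * d_of) - np.exp(1j * k * d_if))
    out = np.abs(np.where(small, np.nan, val))
    # focal limit: p -> -i k p0 F (cos_in - cos_out) e^{ikF}
    focal = np.abs(1j * k * p0 * F * (cos_in - cos_out) * np.exp(1j * k * F))
    return np.where(small, focal, out)


def heat_kernel_gaussian(r, t: float, diffusivity: float, sigma0: float, dT0: float):
    """Free-space conduction of a 3D Gaussian temperature perturbation.

    T(r, t) - T_inf = dT0 (sigma0^2 / s2)^{3/2} exp(-r^2 / (2 s2)),
    s2 = sigma0^2 + 2 D t.  Exact heat-kernel solution, no perfusion.
    """
    s2 = sigma0**2 + 2.0 * diffusivity * t
    return dT0 * (sigma0**2 / s2) ** 1.5 * np.exp(-np.asarray(r, dtype=float) ** 2 / (2 * s2))


def halfspace_diffusion(depth, t: float, D: float, C0: float):
    """Pure-diffusion penetration from a constant-concentration boundary:
    C = C0 erfc(x / (2 sqrt(D t)))."""
    from scipy.special import erfc
    return C0 * erfc(np.asarray(depth, dtype=float) / (2.0 * np.sqrt(D * t)))


def dense_ode_solution(A: np.ndarray, b: np.ndarray, C0: np.ndarray, t: float) -> np.ndarray:
    """Exact solution of dC/dt = A C + b via one augmented matrix exponential."""
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    E = scipy.linalg.expm(M * t)
    return E[:n, :n] @ C0 + E[:n, n]


def toy_fields(kind: str, grid: DomainGrid, **kwargs) -> np.ndarray:
    """Deterministic scalar fields on the grid for unit-testing metrics/solvers.

    kinds: ``uniform`` (value=...), ``radial_exponential`` (surface value C0
    decaying inward with length L), ``gaussian_hotspot`` (center_r, center_z,
    width, amplitude, baseline).
    """
    rc = grid.r_centers[:, None]
    th = grid.theta_centers[None, :]
    if kind == "uniform":
        return np.full((grid.nr, grid.nt), float(kwargs.get("value", 0.0)))
    if kind == "radial_exponential":
        C0 = float(kwargs.get("C0", 1.0))
        L = float(kwargs["L"])
        depth = grid.tumor_radius - rc
        return C0 * np.exp(-depth / L) * np.ones_like(th)
    if kind == "gaussian_hotspot":
        r_cyl = rc * np.sin(th)
        z = rc * np.cos(th)
        w = float(kwargs.get("width", grid.tumor_radius / 4))
        cz = float(kwargs.get("center_z", 0.0))
        cr = float(kwargs.get("center_r", 0.0))
        amp = float(kwargs.get("amplitude", 1.0))
        base = float(kwargs.get("baseline", 0.0))
        return base + amp * np.exp(-(((r_cyl - cr) ** 2 + (z - cz) ** 2) / (2 * w**2)))
    raise ValueError(f"unknown toy field kind {kind!r}")
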