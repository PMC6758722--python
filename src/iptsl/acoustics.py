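"""Linear monochromatic field of a focused bowl transducer.

The time-averaged pressure amplitude is computed from the Rayleigh-
Sommerfeld integral over the spherical cap (outer aperture 70 mm with a
20 mm central hole by default), with tissue absorption folded into a
complex wavenumber.  Nonlinear propagation and acoustic diffusivity are
neglected: at the sub-2 MPa focal pressures used for mild hyperthermia
their contribution to the heating term is below a few percent, and the PI
temperature controller rescales the deposition anyway.

Heat deposition follows the plane-progressive-wave relation
q = 2 alpha_abs I with I = p^2 / (2 rho c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .geometry import DomainGrid


@dataclass
class AcousticField:
    p_amp: np.ndarray      # (nr, nt) pressure amplitude on the grid, Pa
    I: np.ndarray          # intensity, W/m^2
    q: np.ndarray          # volumetric heat deposition, W/m^3
    f: float               # drive frequency, Hz
    focus_z: float         # focus position on the beam axis (grid frame), m
    diagnostics: dict


class BowlSource:
    """Spherical-cap radiator with a central hole, focus at the origin,
    beam propagating toward +z (apex at z = -focal_length)."""

    def __init__(self, config: ScenarioConfig, f: float | None = None):
        ac = config.acoustic
        if ac.focal_length <= 0:
            raise ValueError("focal length must be positive")
        if not ac.inner_diameter < ac.outer_diameter:
            raise ValueError("inner aperture must be smaller than outer aperture")
        self.f = float(f if f is not None else config.hifu_frequency)
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        self.F = ac.focal_length
        self.p0 = ac.source_pressure
        self.rho = ac.density
        self.c = ac.sound_speed
        self.alpha = ac.alpha_abs(self.f)
        self.k = 2.0 * np.pi * self.f / self.c + 1j * self.alpha
        self.psi_in = np.arcsin(ac.inner_diameter / 2.0 / self.F)
        self.psi_out = np.arcsin(ac.outer_diameter / 2.0 / self.F)
        self.ppw = config.numerics.acoustic_ppw
        self._build_quadrature(self.ppw)

    def _build_quadrature(self, ppw: float) -> None:
        lam = self.c / self.f
        dpsi = lam / (ppw * self.F)
        n_rings = max(8, int(np.ceil((self.psi_out - self.psi_in) / dpsi)))
        psi_edges = np.linspace(self.psi_in, self.psi_out, n_rings + 1)
        xs, ys, zs, ws = [], [], [], []
        for p0, p1 in zip(psi_edges[:-1], psi_edges[1:]):
            psi = 0.5 * (p0 + p1)
            ring_r = self.F * np.sin(psi)
            n_phi = max(8, int(np.ceil(2 * np.pi * ring_r / (lam / ppw))))
            phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
            dS = self.F**2 * (np.cos(p0) - np.cos(p1)) * (2 * np.pi / n_phi)
            xs.append(ring_r * np.cos(phi))
            ys.append(ring_r * np.sin(phi))
            zs.append(np.full(n_phi, -self.F * np.cos(psi)))
            ws.append(np.full(n_phi, dS))
        self._src = tuple(np.concatenate(a) for a in (xs, ys, zs, ws))

    def pressure_at(self, r_cyl, z) -> np.ndarray:
        """|p| at cylindrical field points (r, z); focus at (0, 0)."""
        r_cyl = np.atleast_1d(np.asarray(r_cyl, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        xs, ys, zs, ws = self._src
        out = np.empty(r_cyl.shape, dtype=complex)
        flat_r, flat_z = r_cyl.ravel(), z.ravel()
        chunk = max(1, int(4e6 // xs.size))
        pref = -1j * self.k * self.p0 / (2 * np.pi)
        for i0 in range(0, flat_r.size, chunk):
            sl = slice(i0, i0 + chunk)
            dx = flat_r[sl, None] - xs[None, :]
            dz = flat_z[sl, None] - zs[None, :]
            d = np.sqrt(dx**2 + ys[None, :] ** 2 + dz**2)
            out.ravel()[sl] = pref * np.sum(np.exp(1j * self.k * d) / d * ws[None, :], axis=1)
        return np.abs(out)

    def field_on_grid(self, grid: DomainGrid, check_convergence: bool = True) -> AcousticField:
        """Evaluate amplitude, intensity and heat deposition at cell centers."""
        if grid.r_edges[0] > 1e-12:
            raise ValueError("grid does not contain the focus")
        r_cyl, z = grid.cell_centers_rz()
        p = self.pressure_at(r_cyl, z)
        diagnostics = {"n_sources": self._src[0].size, "f_Hz": self.f}
        if check_convergence:
            probe = self.pressure_at(np.array([2e-4]), np.array([0.0]))[0]
            fine = BowlSource.__new__(BowlSource)
            fine.__dict__.update(self.__dict__)
            fine._build_quadrature(self.ppw * 2.0)
            probe2 = fine.pressure_at(np.array([2e-4]), np.array([0.0]))[0]
            rel = abs(probe - probe2) / probe2
            diagnostics["quadrature_rel_change"] = rel
            if rel > 5e-3:
                raise RuntimeError(
                    f"acoustic quadrature not converged (focal change {rel:.2%} on refinement)"
                )
        I = p**2 / (2.0 * self.rho * self.c)
        q = 2.0 * self.alpha * I
        # the field maximum must sit on the beam axis near the focus
        imax = np.unravel_index(np.argmax(p), p.shape)
        rmax = grid.r_centers[imax[0]]
        th = grid.theta_centers[imax[1]]
        diagnostics["max_offaxis_m"] = float(rmax * np.sin(th))
        diagnostics["max_axial_m"] = float(rmax * np.cos(th))
        diagnostics["p_focal_Pa"] = float(p.max())
        return AcousticField(p_amp=p, I=I, q=q, f=self.f, focus_z=0.0, diagnostics=diagnostics)

    def axial_profile(self, z: np.ndarray) -> np.ndarray:
        """|p| on the beam axis (z measured from the focus)."""
        return self.pressure_at(np.zeros_like(z), z)

    def focal_extents_db(self, db: float = -6.0, span: float = 0.04, n: int = 801
                         ) -> tuple[float, float]:
        """(axial, radial) full widths of the focal spot at the given level."""
        z = np.linspace(-span / 2, span / 2, n)
        pz = self.axial_profile(z)
        level = 10 ** (db / 20.0) * pz.max()
        ax = z[pz >= level]
        r = np.linspace(0, span / 8, n)
        pr = self.pressure_at(r, np.zeros_like(r))
        ra = r[pr >= level]
        return float(ax.max() - ax.min()), float(2 * ra.max())


def bowl_field(config: ScenarioConfig, grid: DomainGrid, f: float | None = None,
               check_convergence: bool = True) -> AcousticField:
    """Compute the transducer field for a scenario on its grid."""
    return BowlSource(config, f=f).field_on_grid(grid, check_convergence=check_convergence)


def heating_rate(field: AcousticField) -> np.ndarray:
    """Volumetric power deposition q = 2 alpha_abs I, W/m^3."""
    return field.q
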