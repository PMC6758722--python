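"""Axisymmetric computational domain for the tumor and surrounding tissue.

The domain is a solid of revolution about the ultrasound beam axis,
discretized on a spherical-polar (rho, theta) tensor mesh centered at the
tumor center.  The tumor surface (rho = R) and the necrotic interface
(rho = Rn) fall exactly on mesh faces; the radial mesh is geometrically
graded so that the thin drug-penetration layer and the interstitial-pressure
boundary layer at the surface are resolved, while the thermal extension into
normal tissue stays coarse.

Region codes: 0 = necrotic core, 1 = viable tumor, 2 = normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig

NECROTIC, VIABLE, NORMAL = 0, 1, 2


def _tumor_radial_edges(R: float, Rn: float, num) -> np.ndarray:
    """Graded radial faces on [0, R] with exact faces at Rn and R.

    Built from the surface inward: a uniformly fine band, a geometric
    transition, then uniform interior / core zones.
    """
    cells: list[float] = []  # cell widths, surface -> center order
    n_fine = max(1, round(num.surface_band / num.dr_fine))
    cells += [num.dr_fine] * n_fine
    x = R - n_fine * num.dr_fine
    h = num.dr_fine * num.grading_ratio
    while x - h > Rn + 1e-12 and h < num.dr_coarse:
        cells.append(h)
        x -= h
        h *= num.grading_ratio
    if x > Rn + 1e-12:
        dr = min(num.dr_coarse, h)
        n_mid = max(1, round((x - Rn) / dr))
        cells += [(x - Rn) / n_mid] * n_mid
        x = Rn
    if x < Rn - 1e-12:
        raise ValueError(
            "radial mesh does not fit: surface band + grading overruns the "
            f"necrotic interface (R={R}, Rn={Rn}); reduce surface_band or dr_fine"
        )
    dr_core = min(num.dr_coarse, Rn / 4)
    n_core = max(1, round(Rn / dr_core))
    cells += [Rn / n_core] * n_core
    edges = R - np.concatenate(([0.0], np.cumsum(cells)))
    edges = edges[::-1]
    edges[0] = 0.0
    return edges


def _outer_radial_edges(R: float, R_out: float, num) -> np.ndarray:
    """Geometrically growing faces on (R, R_out]."""
    edges = [R]
    h = num.dr_outer_start
    x = R
    while x < R_out:
        x = min(x + h, R_out)
        edges.append(x)
        h = min(h * num.outer_grading, num.dr_outer_max)
    if len(edges) > 2 and (edges[-1] - edges[-2]) < 0.4 * (edges[-2] - edges[-3]):
        del edges[-2]  # merge a sliver last cell
    return np.asarray(edges[1:])


@dataclass
class DomainGrid:
    """Finite-volume mesh with axisymmetric revolution metrics."""

    r_edges: np.ndarray          # (nr+1,) radial faces, m
    theta_edges: np.ndarray      # (nt+1,) polar faces, rad, [0, pi]
    region: np.ndarray           # (nr, nt) int codes
    volumes: np.ndarray          # (nr, nt) cell volumes, m^3
    area_r: np.ndarray           # (nr+1, nt) radial-face areas, m^2
    area_t: np.ndarray           # (nr, nt+1) polar-face areas, m^2
    i_surface: int               # index of the radial face at rho = R
    i_necrotic: int              # index of the radial face at rho = Rn
    tumor_radius: float
    necrotic_radius: float
    planar: bool = False

    @property
    def nr(self) -> int:
        return len(self.r_edges) - 1

    @property
    def nt(self) -> int:
        return len(self.theta_edges) - 1

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.region != NORMAL

    @property
    def viable_mask(self) -> np.ndarray:
        return self.region == VIABLE

    def cell_centers_rz(self) -> tuple[np.ndarray, np.ndarray]:
        """Cylindrical coordinates (r >= 0, z) of cell centers; beam axis = z."""
        rc = self.r_centers[:, None]
        th = self.theta_centers[None, :]
        return rc * np.sin(th), rc * np.cos(th)

    def tumor_volume(self) -> float:
        return float(self.volumes[self.tumor_mask].sum())

    def theta_weights(self) -> np.ndarray:
        """Solid-angle (or planar angle) weight per polar row, sums to 4*pi (2*pi planar)."""
        if self.planar:
            return np.diff(self.theta_edges)
        return 2.0 * np.pi * (np.cos(self.theta_edges[:-1]) - np.cos(self.theta_edges[1:]))


def grid_from_edges(r_edges: np.ndarray, theta_edges: np.ndarray, R: float,
                    Rn: float, planar: bool = False) -> DomainGrid:
    """Assemble a DomainGrid (metrics + region labels) from given faces.

    ``r_edges`` must contain faces exactly at Rn and R.  Used by
    :func:`build_domain` and directly by tests that need tiny meshes.
    """
    r_edges = np.asarray(r_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)
    nt = len(theta_edges) - 1
    i_surface = int(np.argmin(np.abs(r_edges - R)))
    i_necrotic = int(np.argmin(np.abs(r_edges - Rn)))
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    region_1d = np.where(rc < Rn, NECROTIC, np.where(rc < R, VIABLE, NORMAL))
    region = np.repeat(region_1d[:, None], nt, axis=1)

    if planar:
        # half-disc with unit depth; theta faces at 0 and pi are symmetry planes
        dth = np.diff(theta_edges)
        vol = 0.5 * np.diff(r_edges**2)[:, None] * dth[None, :]
        area_r = r_edges[:, None] * dth[None, :]
        area_t = np.repeat(np.diff(r_edges)[:, None], nt + 1, axis=1)
    else:
        dw = 2.0 * np.pi * (np.cos(theta_edges[:-1]) - np.cos(theta_edges[1:]))
        vol = (np.diff(r_edges**3)[:, None] / 3.0) * dw[None, :]
        area_r = (r_edges**2)[:, None] * dw[None, :]
        half_r2 = 0.5 * np.diff(r_edges**2)
        area_t = 2.0 * np.pi * np.sin(theta_edges)[None, :] * half_r2[:, None]

    return DomainGrid(
        r_edges=r_edges,
        theta_edges=theta_edges,
        region=region,
        volumes=vol,
        area_r=area_r,
        area_t=area_t,
        i_surface=i_surface,
        i_necrotic=i_necrotic,
        tumor_radius=R,
        necrotic_radius=Rn,
        planar=planar,
    )


def build_domain(config: ScenarioConfig, thermal_extent: bool = True) -> DomainGrid:
    """Build the computational mesh for a scenario.

    With ``thermal_extent`` the mesh continues into normal tissue up to
    max(4R, R + thermal margin) so the 37 degC Dirichlet boundary of the heat
    problem cannot perturb tumor temperatures; flow and drug transport only
    use the cells with rho < R.
    """
    R = config.tumor_radius_R
    Rn = config.necrotic_radius_Rn
    num = config.numerics
    r_in = _tumor_radial_edges(R, Rn, num)
    if thermal_extent:
        R_out = max(4.0 * R, R + num.thermal_margin)
        r_edges = np.concatenate([r_in, _outer_radial_edges(R, R_out, num)])
    else:
        r_edges = r_in
    theta_edges = np.linspace(0.0, np.pi, num.n_theta + 1)

    # refinement invariant: the ~30 um penetration layer must be resolved
    near = (r_edges[:-1] > R - 0.5e-3 - 1e-12) & (r_edges[1:] <= R + 1e-12)
    widths = np.diff(r_edges)[near]
    if widths.size == 0 or widths.max() > 10e-6 + 1e-12:
        raise ValueError(
            "resolution too coarse: radial spacing within 0.5 mm of the tumor "
            f"surface must be <= 10 um (max found {widths.max() if widths.size else float('nan'):.2e} m)"
        )

    return grid_from_edges(r_edges, theta_edges, R, Rn, planar=num.planar)
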