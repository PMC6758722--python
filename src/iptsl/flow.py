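"""Steady interstitial fluid flow: Darcy's law with a Starling source.

The interstitial pressure P_i solves

    -div( kappa grad P_i ) = phi_B(P_i),
    phi_B = L_P (S/V) [P_B - P_i - sigma_s (pi_B - pi_i)]

inside the tumor, with P_i = 0 on the tumor surface (the peritoneal cavity
is at reference pressure), no flux on the symmetry axis, and phi_B = 0 in
the avascular necrotic core.  Lymphatic drainage is absent in tumor tissue.
The source is affine in P_i, so one sparse solve is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import ScenarioConfig
from .geometry import DomainGrid, NECROTIC


def starling_source(P_i, params: ScenarioConfig):
    """Transvascular fluid filtration rate per unit volume, s^-1 (Starling's law)."""
    t = params.tissue
    return t.L_P * t.S_over_V * (t.P_B - np.asarray(P_i, dtype=float) - t.sigma_s * (t.pi_B - t.pi_i))


@dataclass
class FlowField:
    """Steady pressure/velocity solution on the tumor sub-grid (rho < R)."""

    P: np.ndarray            # (nr_t, nt) interstitial pressure, Pa
    v_r: np.ndarray          # (nr_t+1, nt) radial face velocities, m/s (outward > 0)
    v_t: np.ndarray          # (nr_t, nt+1) polar face velocities, m/s
    phi_B: np.ndarray        # (nr_t, nt) volumetric source, s^-1
    grid: DomainGrid
    diagnostics: dict = field(default_factory=dict)


def solve_flow(grid: DomainGrid, config: ScenarioConfig) -> FlowField:
    """Solve the steady Darcy/Starling problem on the tumor interior."""
    t = config.tissue
    kappa = t.kappa
    if kappa <= 0:
        raise ValueError("hydraulic conductivity kappa must be positive")
    ns = grid.i_surface
    nt = grid.nt
    rc = grid.r_centers[:ns]
    thc = grid.theta_centers
    vol = grid.volumes[:ns]
    region = grid.region[:ns]
    R = grid.tumor_radius

    b_coef = np.where(region == NECROTIC, 0.0, t.L_P * t.S_over_V)
    P_e = t.effective_pressure

    n_cells = ns * nt
    idx = np.arange(n_cells).reshape(ns, nt)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = (vol * b_coef).ravel().copy()
    rhs = (vol * b_coef * P_e).ravel().copy()

    # internal radial faces
    for i in range(1, ns):
        T = kappa * grid.area_r[i] / (rc[i] - rc[i - 1])
        a, b = idx[i - 1], idx[i]
        rows.extend([a, b, a, b])
        cols.extend([b, a, a, b])
        vals.extend([-T, -T, T, T])
    # internal polar faces
    for j in range(1, nt):
        dl = rc * (thc[j] - thc[j - 1])
        T = kappa * grid.area_t[:ns, j] / dl
        a, b = idx[:, j - 1], idx[:, j]
        rows.extend([a, b, a, b])
        cols.extend([b, a, a, b])
        vals.extend([-T, -T, T, T])
    # Dirichlet P = 0 on the tumor surface
    T_s = kappa * grid.area_r[ns] / (R - rc[-1])
    a = idx[-1]
    rows.append(a)
    cols.append(a)
    vals.append(T_s)

    rows_a = np.concatenate([np.atleast_1d(r).ravel() for r in rows])
    cols_a = np.concatenate([np.atleast_1d(c).ravel() for c in cols])
    vals_a = np.concatenate([np.atleast_1d(v).ravel() for v in vals])
    A = sp.coo_matrix((vals_a, (rows_a, cols_a)), shape=(n_cells, n_cells)).tocsr()
    A = A + sp.diags(diag)

    P = spla.spsolve(A.tocsc(), rhs).reshape(ns, nt)
    res = np.linalg.norm(A @ P.ravel() - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if not np.isfinite(P).all() or res > 1e-6:
        raise RuntimeError(f"flow solve did not converge (relative residual {res:.3e})")

    phi_B = b_coef * (P_e - P)

    v_r = np.zeros((ns + 1, nt))
    v_r[1:ns] = -kappa * (P[1:] - P[:-1]) / (rc[1:, None] - rc[:-1, None])
    v_r[ns] = -kappa * (0.0 - P[-1]) / (R - rc[-1])
    v_t = np.zeros((ns, nt + 1))
    v_t[:, 1:nt] = -kappa * (P[:, 1:] - P[:, :-1]) / (rc[:, None] * np.diff(thc)[None, :])

    outflow = float((v_r[ns] * grid.area_r[ns]).sum())
    source = float((phi_B * vol).sum())
    diagnostics = {
        "max_ifp_Pa": float(P.max()),
        "max_ifv_m_s": float(np.abs(v_r[ns]).max()),
        "net_outflow_m3_s": outflow,
        "total_source_m3_s": source,
        "mass_balance_rel": abs(outflow - source) / max(abs(source), 1e-300),
        "residual": res,
    }
    return FlowField(P=P, v_r=v_r, v_t=v_t, phi_B=phi_B, grid=grid, diagnostics=diagnostics)


def radial_profile(grid: DomainGrid, values: np.ndarray, theta: float = np.pi / 2):
    """Profile of a cell field along an inward radial ray.

    Returns ``(depth, vals)`` where depth is the distance from the tumor
    surface (monotone increasing, 0 at the surface) and vals are linearly
    associated with cell centers of the nearest polar row.
    """
    j = int(np.argmin(np.abs(grid.theta_centers - theta)))
    ns = min(values.shape[0], grid.i_surface)
    rc = grid.r_centers[:ns]
    depth = grid.tumor_radius - rc[::-1]
    if depth.min() < -1e-12:
        raise ValueError("ray leaves the tumor domain")
    return depth, values[:ns, j][::-1]


def profile_value_at(depth_axis: np.ndarray, vals: np.ndarray, d: float) -> float:
    """Linear interpolation on a ray profile (with linear end extrapolation)."""
    if d <= depth_axis[0]:
        d0, d1 = depth_axis[0], depth_axis[1]
        return float(vals[0] + (vals[1] - vals[0]) * (d - d0) / (d1 - d0))
    return float(np.interp(d, depth_axis, vals))
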