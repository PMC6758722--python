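"""Treatment-evaluation metrics: cell kill, exposure AUC, penetration depth.

* FK(t) = 1 - exp(-omega C_I): exponential cell-survival model in the
  internalized doxorubicin concentration (omega = 0.6603 m^3/mol).  By
  default FK is evaluated on the tumor-mean C_I; a pointwise-then-average
  variant is available for sensitivity.
* AUC: trapezoidal time-integral of a mean-concentration series (SI units,
  mol m^-3 s).
* W_1/2: along each inward radial ray, the first depth at which the total
  drug concentration falls to 50% of its value at the tumor surface
  (linearly interpolated); reported per ray, as the max over rays, and
  relative to the tumor radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DomainGrid
from .transport import DrugState


@dataclass
class TreatmentMetrics:
    FK_final: float
    FK_series: np.ndarray
    AUC_F: float              # mol m^-3 s
    AUC_B: float              # mol m^-3 s
    W_half: np.ndarray        # per-ray, m (NaN where undefined)
    W_half_max: float         # m
    W_half_rel: float         # percent of R
    extras: dict = field(default_factory=dict)


def fraction_killed(C_I_mean, omega: float = 0.6603):
    """FK series from (tumor-mean) internalized concentration."""
    C = np.asarray(C_I_mean, dtype=float)
    if np.any(C < -1e-12):
        raise ValueError("negative internalized concentration")
    return 1.0 - np.exp(-omega * np.clip(C, 0.0, None))


def fraction_killed_pointwise(C_I_field: np.ndarray, grid: DomainGrid,
                              omega: float = 0.6603, viable_only: bool = False) -> float:
    """Volume average of the local kill fraction 1 - exp(-omega C_I(x))."""
    ns = C_I_field.shape[0]
    vol = grid.volumes[:ns]
    mask = (grid.region[:ns] != 2)
    if viable_only:
        mask &= grid.region[:ns] == 1
    fk = 1.0 - np.exp(-omega * np.clip(C_I_field, 0.0, None))
    return float((fk * vol)[mask].sum() / vol[mask].sum())


def auc(times, series, t_end: float | None = None) -> float:
    """Trapezoidal integral of a concentration time series, mol m^-3 s."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(series, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    if t_end is not None:
        if t_end > t[-1] + 1e-9:
            raise ValueError("series does not cover [0, t_end]")
        keep = t <= t_end + 1e-9
        t, c = t[keep], c[keep]
        if t[-1] < t_end - 1e-9:
            t = np.append(t, t_end)
            c = np.append(c, np.interp(t_end, times, series))
    return float(np.trapezoid(c, t))


def half_width(total_field: np.ndarray, grid: DomainGrid,
               rays: np.ndarray | None = None):
    """Penetration half-width along inward radial rays.

    Returns ``(W_per_ray, W_max, W_rel_percent)``; a ray with a
    non-positive surface value yields NaN, and an all-undefined field
    raises ValueError.
    """
    ns = min(total_field.shape[0], grid.i_surface)
    rc = grid.r_centers[:ns]
    depth = grid.tumor_radius - rc[::-1]        # ascending from the surface
    ray_idx = range(grid.nt) if rays is None else rays
    W = np.full(grid.nt if rays is None else len(rays), np.nan)
    for m, j in enumerate(ray_idx):
        prof = total_field[:ns, j][::-1]
        surf = prof[0] + (prof[1] - prof[0]) * (0.0 - depth[0]) / (depth[1] - depth[0])
        surf = max(surf, prof[0])  # guard against negative extrapolation
        if surf <= 0.0:
            continue
        half = 0.5 * surf
        below = np.nonzero(prof <= half)[0]
        if below.size == 0:
            W[m] = depth[-1]  # never drops to half within the tumor
            continue
        i = below[0]
        if i == 0:
            W[m] = 0.5 * depth[0]
        else:
            W[m] = float(np.interp(half, [prof[i], prof[i - 1]], [depth[i], depth[i - 1]]))
    if np.all(np.isnan(W)):
        raise ValueError("half-width undefined: total concentration vanishes on all rays")
    W_max = float(np.nanmax(W))
    return W, W_max, 100.0 * W_max / grid.tumor_radius


def compute_metrics(state: DrugState, config, include_liposomal: bool = True,
                    viable_only: bool = False) -> TreatmentMetrics:
    """Standard metric set for one finished run."""
    omega = config.transport.omega
    mean_I = state.mean_viable["I"] if viable_only else state.mean_I
    mean_F = state.mean_viable["F"] if viable_only else state.mean_F
    mean_B = state.mean_viable["B"] if viable_only else state.mean_B
    fk_series = fraction_killed(mean_I, omega)
    tot = state.total_final(include_liposomal=include_liposomal)
    W, W_max, W_rel = half_width(tot, state.grid)
    tot_noL = state.total_final(include_liposomal=False)
    try:
        _, W_max_noL, _ = half_width(tot_noL, state.grid)
    except ValueError:
        W_max_noL = float("nan")
    return TreatmentMetrics(
        FK_final=float(fk_series[-1]),
        FK_series=fk_series,
        AUC_F=auc(state.times, mean_F),
        AUC_B=auc(state.times, mean_B),
        W_half=W,
        W_half_max=W_max,
        W_half_rel=W_rel,
        extras={
            "FK_pointwise": fraction_killed_pointwise(state.C_I, state.grid, omega,
                                                      viable_only=viable_only),
            "W_half_max_excl_liposomal_m": W_max_noL,
            "mean_C_F_plateau": float(np.max(mean_F)),
            "mean_C_L_final": float(state.mean_L[-1]),
        },
    )
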