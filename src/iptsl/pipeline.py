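"""End-to-end scenario execution.

Pipeline order mirrors the model coupling: steady interstitial flow first;
in TSL mode the acoustic field and the PI-controlled bioheat transient next;
then the transient drug transport driven by both; finally the treatment
metrics.  Everything is deterministic - two runs of the same configuration
produce identical metrics bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .acoustics import AcousticField, bowl_field
from .bioheat import ThermalState, solve_bioheat
from .config import ScenarioConfig
from .flow import FlowField, solve_flow
from .geometry import DomainGrid, build_domain
from .hindrance import HindranceCoefficients, liposome_coefficients
from .io_vtk import write_series_csv, write_structured_vtk
from .metrics import TreatmentMetrics, compute_metrics
from .transport import DrugState, solve_conventional, solve_tsl

log = logging.getLogger("iptsl")


@dataclass
class RunManifest:
    scenario_id: str
    config_hash: str
    version: str
    mode: str
    parameters: dict
    metrics: dict
    wall_time_s: float


@dataclass
class RunResult:
    config: ScenarioConfig
    grid: DomainGrid
    flow: FlowField
    drug: DrugState
    metrics: TreatmentMetrics
    manifest: RunManifest
    acoustic: AcousticField | None = None
    thermal: ThermalState | None = None
    hindrance: HindranceCoefficients | None = None
    extra: dict = field(default_factory=dict)


def config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_scenario(config: ScenarioConfig, outdir: str | Path | None = None,
                 thermal: ThermalState | None = None,
                 acoustic: AcousticField | None = None,
                 grid: DomainGrid | None = None,
                 flow: FlowField | None = None) -> RunResult:
    """Execute one scenario; precomputed stages may be passed in for reuse
    across sweeps (e.g. the same thermal field for several TSL sizes)."""
    t_start = time.perf_counter()
    config.validate()
    if grid is None:
        grid = build_domain(config)
    log.info("grid: %d x %d cells, tumor volume %.3e m^3", grid.nr, grid.nt, grid.tumor_volume())
    if flow is None:
        flow = solve_flow(grid, config)
    log.info("flow: max IFP %.1f Pa, max IFV %.3e m/s, mass balance %.2e",
             flow.diagnostics["max_ifp_Pa"], flow.diagnostics["max_ifv_m_s"],
             flow.diagnostics["mass_balance_rel"])

    hind = None
    if config.mode == "tsl":
        if acoustic is None:
            acoustic = bowl_field(config, grid)
            log.info("acoustics: focal p %.2e Pa (quadrature change %.2e)",
                     acoustic.diagnostics["p_focal_Pa"],
                     acoustic.diagnostics.get("quadrature_rel_change", float("nan")))
        if thermal is None:
            thermal = solve_bioheat(grid, acoustic.q, config)
            log.info("bioheat: boundary axis T %.2f C, min D_P %.3f",
                     thermal.boundary_axis_temperature(), thermal.min_DP[-1])
        hind = liposome_coefficients(config)
        drug = solve_tsl(grid, flow, thermal, config, hind=hind)
    else:
        drug = solve_conventional(grid, flow, config)
    log.info("transport: mass closure %.2e", drug.audit["closure_rel"])

    metrics = compute_metrics(drug, config)
    metric_row = {
        "scenario_id": config.scenario_id,
        "mode": config.mode,
        "R_mm": config.tumor_radius_R * 1e3,
        "f_MHz": config.hifu_frequency / 1e6 if config.mode == "tsl" else float("nan"),
        "tsl_nm": config.tsl_diameter * 1e9 if config.mode == "tsl" else float("nan"),
        "FK_60min": metrics.FK_final,
        "AUC_F_mol_m3_s": metrics.AUC_F,
        "AUC_B_mol_m3_s": metrics.AUC_B,
        "W_half_max_um": metrics.W_half_max * 1e6,
        "W_half_rel_pct": metrics.W_half_rel,
        "max_IFP_Pa": flow.diagnostics["max_ifp_Pa"],
        "max_IFV_um_s": flow.diagnostics["max_ifv_m_s"] * 1e6,
        "boundary_T_C": thermal.boundary_axis_temperature() if thermal is not None else float("nan"),
    }
    manifest = RunManifest(
        scenario_id=config.scenario_id,
        config_hash=config_hash(config),
        version=__version__,
        mode=config.mode,
        parameters={"R_m": config.tumor_radius_R, "Rn_m": config.necrotic_radius_Rn,
                    "f_Hz": config.hifu_frequency, "tsl_m": config.tsl_diameter,
                    "duration_s": config.treatment_duration,
                    "C0_mol_m3": config.boundary_concentration},
        metrics=metric_row,
        wall_time_s=time.perf_counter() - t_start,
    )
    result = RunResult(config=config, grid=grid, flow=flow, drug=drug, metrics=metrics,
                       manifest=manifest, acoustic=acoustic, thermal=thermal, hindrance=hind)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: RunResult, outdir: str | Path) -> None:
    """CSV series, metric row, manifest and VTK snapshots for one run."""
    out = Path(outdir) / result.config.scenario_id
    out.mkdir(parents=True, exist_ok=True)
    d = result.drug
    write_series_csv(out / "mean_concentrations.csv", {
        "t_s": d.times, "C_L": d.mean_L, "C_F": d.mean_F,
        "C_B": d.mean_B, "C_I": d.mean_I, "FK": result.metrics.FK_series,
    })
    import pandas as pd
    pd.DataFrame([result.manifest.metrics]).to_csv(out / "metrics.csv", index=False,
                                                   float_format="%.17g")
    fields = {"C_L": d.C_L, "C_F": d.C_F, "C_B": d.C_B, "C_I": d.C_I,
              "P_i": result.flow.P}
    if result.thermal is not None:
        fields["T_final"] = result.thermal.T_snapshots[-1]
        fields["D_P"] = result.thermal.D_P
        write_series_csv(out / "controller.csv", {
            "t_s": result.thermal.probe_times, "T_probe_C": result.thermal.probe_T,
            "K_HIFU": result.thermal.K_HIFU, "min_D_P": result.thermal.min_DP,
        })
    if result.acoustic is not None:
        fields["p_amp"] = result.acoustic.p_amp
        fields["q"] = result.acoustic.q
    write_structured_vtk(out / "fields.vtk", result.grid, fields)
    manifest = asdict(result.manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def oracle_report(config: ScenarioConfig | None = None) -> list[dict]:
    """Solver-vs-oracle discrepancy table (used by the CLI ``verify``)."""
    from .oracles import analytic_flow, bowl_axis_pressure
    from .acoustics import BowlSource

    cfg = config or ScenarioConfig()
    rows = []
    grid = build_domain(cfg, thermal_extent=False)
    fl = solve_flow(grid, cfg)
    an = analytic_flow(cfg.tumor_radius_R, cfg.necrotic_radius_Rn, cfg)
    rc = grid.r_centers[: grid.i_surface]
    err = float(np.max(np.abs(fl.P[:, 0] - an.pressure(rc))) / an.P_e)
    rows.append({"check": "flow vs two-region closed form (Linf/P_e)",
                 "value": err, "tol": 0.01, "pass": err < 0.01})
    src = BowlSource(cfg, f=1.0e6)
    z = np.linspace(-0.02, 0.02, 81)
    p_num = src.axial_profile(z)
    ac = cfg.acoustic
    p_or = bowl_axis_pressure(z + ac.focal_length, ac.focal_length, ac.outer_diameter,
                              ac.inner_diameter, src.k, ac.source_pressure)
    aerr = float(np.max(np.abs(p_num - p_or)) / p_or.max())
    rows.append({"check": "bowl axis field vs closed form (Linf/peak)",
                 "value": aerr, "tol": 0.01, "pass": aerr < 0.01})
    res = an.ode_residual()
    rows.append({"check": "analytic flow ODE self-residual",
                 "value": res, "tol": 1e-6, "pass": res < 1e-6})
    return rows
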