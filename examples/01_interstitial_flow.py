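"""Steady interstitial fluid pressure and velocity in a 10 mm tumor.

Solves the Darcy/Starling problem and compares it with the exact two-region
spherical solution.  The elevated central pressure plateau and the outward
rim velocity are the physical barrier that keeps intraperitoneally
delivered drugs from penetrating the tumor.
"""

import numpy as np

from iptsl import ScenarioConfig, build_domain, solve_flow, radial_profile
from iptsl.oracles import analytic_flow

cfg = ScenarioConfig()  # R = 10 mm, necrotic core at R/2, table parameters
grid = build_domain(cfg)
flow = solve_flow(grid, cfg)
an = analytic_flow(cfg.tumor_radius_R, cfg.necrotic_radius_Rn, cfg)

d = flow.diagnostics
print(f"max IFP            : {d['max_ifp_Pa']:.1f} Pa "
      f"(closed-form cap P_e = {an.P_e:.0f} Pa)")
print(f"max IFV at surface : {d['max_ifv_m_s'] * 1e6:.3f} um/s (outward)")
print(f"mass balance error : {d['mass_balance_rel']:.2e}")

rc = grid.r_centers[: grid.i_surface]
err = np.max(np.abs(flow.P[:, 0] - an.pressure(rc))) / an.P_e
print(f"solver vs analytic : {err:.2e} relative Linf")

depth, p = radial_profile(grid, flow.P)
i = np.searchsorted(depth, 0.5e-3)
print(f"\npressure drops from the plateau to ~0 within a thin rim:")
for k in (0, i // 4, i // 2, i, len(depth) - 1):
    print(f"  depth {depth[k] * 1e6:8.1f} um : P_i = {p[k]:7.1f} Pa")
print("\nThe whole pressure difference is confined to a ~0.3 mm boundary "
      "layer (1/alpha = %.0f um), so convection opposes drug entry exactly "
      "where the drug enters." % (1e6 / an.alpha))
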