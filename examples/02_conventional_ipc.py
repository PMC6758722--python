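"""Conventional intraperitoneal doxorubicin: 60 minutes of cavity exposure.

Free drug surrounds the tumor at 0.8 mol/m^3 and must diffuse in against
the outward interstitial flow while being lost to the microvasculature and
bound/internalized by cells.  Prints the exposure metrics that quantify
why penetration is poor.
"""

import numpy as np

from iptsl import ScenarioConfig, run_scenario

cfg = ScenarioConfig(scenario_id="conventional_demo")
result = run_scenario(cfg)
m = result.metrics
state = result.drug

print(f"tumor-mean C_F plateau : {np.max(state.mean_F):.5f} mol/m^3")
print(f"AUC_F (60 min)         : {m.AUC_F:.2f} mol.m-3.s "
      f"= {m.AUC_F / 60:.3f} mol.m-3.min")
print(f"AUC_B (60 min)         : {m.AUC_B:.2f} mol.m-3.s "
      f"= {m.AUC_B / 60:.3f} mol.m-3.min")
print(f"fraction killed FK     : {m.FK_final:.2e}")
print(f"penetration W1/2       : {m.W_half_max * 1e6:.1f} um "
      f"({m.W_half_rel:.2f}% of the 10 mm radius)")
print(f"mass-balance closure   : {state.audit['closure_rel']:.1e}")

print("\nInterpretation: the free drug saturates a ~40 um surface shell in "
      "seconds (vascular loss limits the penetration length), so the "
      "tumor-volume mean stays ~10^-3 of the cavity concentration and the "
      "cell kill after one hour is negligible.")
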