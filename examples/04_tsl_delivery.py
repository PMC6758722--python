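"""HIFU-triggered thermosensitive-liposome delivery vs conventional IPC.

Runs the fully coupled pipeline (flow -> acoustics -> controlled bioheat ->
four-compartment transport) for 100 nm carriers heated at 1 MHz, and the
conventional free-drug run on the same tumor, then compares the efficacy
metrics side by side.  Intermediate stages are reused where physics allows
(the same thermal field drives a second run with 5 nm carriers).
"""

from iptsl import ScenarioConfig, run_scenario
from iptsl.hindrance import liposome_coefficients

conv = run_scenario(ScenarioConfig(scenario_id="conventional"))

cfg_tsl = ScenarioConfig(mode="tsl", tsl_diameter=100e-9, hifu_frequency=1.0e6,
                         scenario_id="tsl_100nm_1MHz")
tsl = run_scenario(cfg_tsl)

cfg_small = ScenarioConfig(mode="tsl", tsl_diameter=5e-9, hifu_frequency=1.0e6,
                           scenario_id="tsl_5nm_1MHz")
small = run_scenario(cfg_small, grid=tsl.grid, flow=tsl.flow,
                     acoustic=tsl.acoustic, thermal=tsl.thermal)

hind = liposome_coefficients(cfg_tsl)
print(f"100 nm TSL coefficients: D_L = {hind.D_L:.2e} m^2/s, "
      f"P_eff = {hind.P_eff:.2e} m/s, sigma_f = {hind.sigma_f:.3f} "
      f"(lambda = {hind.lam:.2f})")
print(f"boundary temperature at 1 MHz: "
      f"{tsl.thermal.boundary_axis_temperature():.2f} C\n")

hdr = f"{'metric':28s} {'conventional':>14s} {'TSL 100 nm':>12s} {'TSL 5 nm':>10s}"
print(hdr + "\n" + "-" * len(hdr))
rows = [
    ("FK at 60 min", "FK_final", "{:.3e}"),
    ("AUC_F [mol.m-3.s]", "AUC_F", "{:.3f}"),
    ("AUC_B [mol.m-3.s]", "AUC_B", "{:.3f}"),
    ("W1/2 max [um]", None, "{:.1f}"),
]
for label, attr, fmt in rows:
    vals = []
    for res in (conv, tsl, small):
        v = res.metrics.W_half_max * 1e6 if attr is None else getattr(res.metrics, attr)
        vals.append(fmt.format(v))
    print(f"{label:28s} {vals[0]:>14s} {vals[1]:>12s} {vals[2]:>10s}")

ratio = tsl.metrics.W_half_max / conv.metrics.W_half_max
print(f"\npenetration ratio TSL/conventional: {ratio:.2f}")
print("\nWith the tabulated release rates and carrier diffusivities the "
      "liposomes themselves only reach a ~10-30 um shell before releasing, "
      "so encapsulation mainly shifts *where* drug appears (the heated "
      "border), not how deep it travels; smaller carriers enter faster and "
      "raise the free-drug exposure.")
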