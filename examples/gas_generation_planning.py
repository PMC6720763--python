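"""Plan generator settings for a binary mixture at a target odor intensity.

Computes bubbler saturation concentrations, inverts the Weber-Fechner laws
for the target concentrations, and splits the flow between the two source
streams and dilution air.
"""

from odormix import plan_mixture, saturation_concentration
from odormix.reference import reference_profile

toluene = reference_profile("toluene")
oxylene = reference_profile("o-xylene")

plan = plan_mixture(toluene, oxylene, target_oi_a=1.0, total_flow=5.0)

print("binary mixture at odor intensity 1 (total flow 5 mL/s = 300 mL/min):")
for name, c in plan.targets_ppm.items():
    print(f"  {name:10s} target {c:6.2f} ppm  "
          f"(bubbler saturation {plan.source_ppm[name]:9.0f} ppm, "
          f"source flow {plan.source_flows[name] * 1e3:7.3f} uL/s)")
print(f"  dilution air: {plan.dilution_flow:.4f} mL/s")

delivered = plan.delivered()
print(f"  delivered check: " + ", ".join(
    f"{k}={v:.3f} ppm" for k, v in delivered.concentrations.items()))
print()
print(f"toluene saturation sanity check: hard-coded 24.04 L/mol gives "
      f"{saturation_concentration(toluene.vapor_pressure):.0f} ppm vs "
      f"{saturation_concentration(toluene.vapor_pressure, strict=True):.0f} ppm "
      f"from the exact mole fraction (agreement < 0.3%).")
print()
print("The source flows are microliters per second because the bubbler")
print("stream is saturated; nearly all of the delivered flow is dilution")
print("air, as expected for ppm-level odor stimuli.")
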