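"""Solve the full sensor/Mg/ATP equilibrium and print every species.

Conditions mimic a cytosol-like cuvette: 20 uM sensor with 10 mM total
Mg and 10 mM total ATP, so most metal is sequestered as MgATP and only
a small fraction of the sensor carries Mg.
"""

from ionsense import solve_speciation
from ionsense.presets import magzet1_system

result = solve_speciation(magzet1_system(20e-6, mg_total=10e-3, atp_total=10e-3))

print(f"converged in {result.iterations} iterations "
      f"(max mass-balance residual {result.max_residual:.1e})")
for name, conc in {**result.free, **result.complexes}.items():
    print(f"  {name:<15s} {conc * 1e6:12.4f} uM")

frac = result.complexes["sensor_Mg_ATP"] / 20e-6
print(f"\nOnly {frac * 100:.3f}% of the sensor sits in the ternary complex: "
      "the weak (100 mM) ternary constant means the probe reads free Mg, "
      "not MgATP.")
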