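"""Dosing arithmetic and headspace partitioning for a sealed serum bottle.

Converts the standard feeding volumes to μmol, then shows how a headspace
GC reading maps to a whole-bottle (aqueous + gas) mass via the
dimensionless Henry constant.
"""

from dechlor import (
    BottleConfig,
    default_registry,
    neat_liquid_to_micromoles,
    syrup_dose_to_micromoles,
    two_phase_total_mass,
)
from dechlor.partitioning import aqueous_conc_if_fully_dissolved

registry = default_registry()
bottle = BottleConfig(sorbent_mass=0.0)  # 160 mL bottle, 100 mL medium
pce = registry["PCE"]

d10 = neat_liquid_to_micromoles(10.0, pce)
d15 = neat_liquid_to_micromoles(15.0, pce)
lactate = syrup_dose_to_micromoles(0.15, 0.60, 1.33, 112.06)
print(f"10 uL neat PCE  -> {d10:7.1f} umol/bottle")
print(f"15 uL neat PCE  -> {d15:7.1f} umol/bottle")
print(f"0.15 mL 60% w/w lactate syrup -> {lactate:7.0f} umol/bottle")

mg_l = aqueous_conc_if_fully_dissolved(d10, pce, bottle)
print(f"fully dissolved, the 10 uL dose would be {mg_l:.0f} mg/L "
      "(near PCE solubility, above Dehalococcoides inhibition thresholds)")

c_gas = 50.0  # μmol/L measured in the headspace
mass = two_phase_total_mass(c_gas, pce, bottle)
print(f"headspace reading {c_gas:.0f} umol/L -> {mass:.1f} umol PCE in the "
      "bottle (aqueous + gas, Hc = 0.64 at 23 degC)")
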