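"""Estimate a solid-water partition coefficient Kd by mass balance.

A sorption-equilibrium bottle receives a known mass; after equilibration
only the aqueous concentration Ce is measured. The mass not accounted for
by the aqueous + gas phases must be sorbed, which fixes Cs and Kd = Cs/Ce.
"""

from dechlor import BottleConfig, default_registry, estimate_kd
from dechlor.partitioning import SorptionExperiment, summarize_kd

registry = default_registry()
pce = registry["PCE"]
bottle = BottleConfig(sorbent_mass=0.2, sorbent_name="char")

# duplicate bottles: 100 μmol PCE added, Ce measured after a month
for ce in (25.0, 28.0):
    est = estimate_kd(SorptionExperiment(pce, 100.0, ce, bottle))
    print(f"Ce = {ce:5.1f} umol/L -> Cs = {est.sorbed_conc:6.1f} umol/g, "
          f"Kd = {est.kd:5.2f} L/g")

ests = [
    estimate_kd(SorptionExperiment(pce, 100.0, ce, bottle)) for ce in (25.0, 28.0)
]
mean, half_range = summarize_kd(ests)
print(f"duplicate summary: Kd = {mean:.2f} +/- {half_range:.2f} L/g "
      "(mean +/- half-range)")

# an impossible measurement: Ce above the no-sorption bound is flagged
bad = estimate_kd(SorptionExperiment(pce, 100.0, 760.0, bottle))
print(f"Ce above the no-sorption bound -> inconsistent = {bad.inconsistent} "
      "(negative sorbed mass is reported, never clipped)")
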