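"""Normalize qPCR biomarkers to copies/bottle and quantify growth.

Suspended measurements (copies/mL) scale by the 100 mL liquid volume;
biochar-attached measurements (copies/g) scale by the 0.2 g char load.
Values below the per-bottle quantification limits are censored at the
limit and growth estimates degrade to one-sided bounds.
"""

from dechlor import BottleConfig, copies_per_bottle, log10_fold_change
from dechlor.biomarkers import BiomarkerMeasurement, Fraction

bottle = BottleConfig(sorbent_mass=0.2, sorbent_name="Char500")

day1 = copies_per_bottle(
    BiomarkerMeasurement("Char500-1", 1.0, "vcrA", Fraction.suspended, 1.2e5),
    bottle,
)
day64 = copies_per_bottle(
    BiomarkerMeasurement("Char500-1", 64.0, "vcrA", Fraction.suspended, 1.3e7),
    bottle,
)
print(f"vcrA suspended day 1:  {day1.copies:.2e} copies/bottle")
print(f"vcrA suspended day 64: {day64.copies:.2e} copies/bottle")
fc = log10_fold_change(day1, day64)
print(f"growth: {fc} — vinyl-chloride-respiring Dehalococcoides expanded")

attached = copies_per_bottle(
    BiomarkerMeasurement("Char500-1", 64.0, "vcrA", Fraction.attached, 1.0e4),
    bottle,
)
print(f"vcrA attached day 64: {attached.copies:.2e} copies/bottle "
      f"(censored at the 3.0e3 LOQ: {attached.censored})")
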