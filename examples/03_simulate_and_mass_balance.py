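"""Simulate two treatment arms and compute mass-balance closure over time.

The Char900 char sorbs PCE strongly (Kd 36 L/g) and releases it slowly
(desorption hysteresis), so the equilibrium-assuming three-phase closure
dips below 1 while dechlorination outpaces desorption, then recovers as
the carbon pool shifts to weakly sorbing VC and ethene.
"""

import numpy as np

from dechlor import default_registry, three_phase_balance
from dechlor.core import ETHENE_SERIES
from dechlor.scenarios import scenario_kd_table, scenario_params
from dechlor.simulator import simulate_microcosm

registry = default_registry()
kd_table = scenario_kd_table()

for arm in ("sand", "Char900"):
    params = scenario_params(arm, noise_cv=0.05, n_replicates=1)
    ds = simulate_microcosm(params, seed=42)
    series = [s for s in ds.observations if s.compound in ETHENE_SERIES]
    nominal = {0.0: params.dose_schedule[0].amount}
    points = three_phase_balance(series, kd_table, params.bottle, nominal, registry)
    days = np.array([p.day for p in points])
    cf = np.array([p.closure_fraction for p in points])
    active = (days >= 10) & (days <= 56)
    print(f"{arm:8s}: closure min (days 10-56) = {cf[active].min():.2f}, "
          f"mean after day 70 = {cf[days >= 70].mean():.2f}")

print("A deep transient dip that heals late is the signature of sorbed mass "
      "hidden from the aqueous phase by slow desorption.")
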