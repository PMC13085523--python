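# Default compound registry for sealed-bottle chlorinated-ethene microcosms.
#
# henry_dimensionless: gas-phase / aqueous-phase concentration ratio at 23 degC.
# neat_density: g/mL at 23 degC, only for compounds dosed as neat liquid or syrup.
# donor_electrons: electrons released per mole on complete oxidation to CO2.
# acceptor_electrons_vs_PCE: electrons accepted per mole to form this species
#   starting from PCE (2 per chlorine removed); methane carries 8 e-/mol from CO2.
# lactate is registered as the sodium salt (syrup dosing convention).
compounds:
  PCE:
    molar_mass: 165.83
    henry_dimensionless: 0.64
    neat_density: 1.618
    chlorine_count: 4
    acceptor_electrons_vs_PCE: 0
    ethene_series: true
  TCE:
    molar_mass: 131.39
    henry_dimensionless: 0.35
    neat_density: 1.46
    chlorine_count: 3
    acceptor_electrons_vs_PCE: 2
    ethene_series: true
  cis-DCE:
    molar_mass: 96.94
    henry_dimensionless: 0.14
    chlorine_count: 2
    acceptor_electrons_vs_PCE: 4
    ethene_series: true
  VC:
    molar_mass: 62.50
    henry_dimensionless: 1.01
    chlorine_count: 1
    acceptor_electrons_vs_PCE: 6
    ethene_series: true
  ethene:
    molar_mass: 28.05
    henry_dimensionless: 7.24
    chlorine_count: 0
    acceptor_electrons_vs_PCE: 8
    ethene_series: true
  methane:
    molar_mass: 16.04
    henry_dimensionless: 27.03
    chlorine_count: 0
    acceptor_electrons_vs_PCE: 8
    donor_electrons: 8
  lactate:
    molar_mass: 112.06
    neat_density: 1.33
    chlorine_count: 0
    donor_electrons: 12
  acetate:
    molar_mass: 60.05
    chlorine_count: 0
    donor_electrons: 8
  propionate:
    molar_mass: 74.08
    chlorine_count: 0
    donor_electrons: 14
  butyrate:
    molar_mass: 88.11
    chlorine_count: 0
    donor_electrons: 20
  H2:
    molar_mass: 2.016
    chlorine_count: 0
    donor_electrons: 2
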