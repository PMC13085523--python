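# Methods

This note documents the models, parameter choices and numerical decisions
behind `dechlor`, and what the test suite does and does not demonstrate.

## System and units

The unit system is fixed package-wide: amounts in μmol per bottle,
concentrations in μmol/L, volumes in L, sorbent mass in g, time in days,
electron equivalents in eq (μeq internally in the simulator). The standard
bottle is 160 mL total, 100 mL liquid, 60 mL headspace at 23 °C with 0.2 g
sorbent (2 g/L); all of these are `BottleConfig` fields, not constants.

## Partitioning and the closure diagnostic

Gas–aqueous equilibrium uses single dimensionless Henry constants at 23 °C
with no temperature correction; the registry ships PCE 0.64, TCE 0.35,
*cis*-DCE 0.14, VC 1.01, ethene 7.24, methane 27.03. Sorption is a linear
(single-point) isotherm: Kd is concentration-independent, and nonlinear
(Freundlich/multi-site) fitting is out of scope. The three-phase closure
assumes sorption equilibrium at each sampling time *by construction* — that
is the point of the diagnostic: when the real (or simulated) system is
desorption-limited, the equilibrium-assuming sorbed estimate undershoots and
closure dips below 1, recovering as the carbon pool moves into weakly
sorbing species. Negative computed sorbed masses in `estimate_kd` are
reported with an `inconsistent` flag, never clipped; a non-detect aqueous
concentration produces an explicit Kd lower bound (given a detection limit)
rather than an infinite estimate.

The dispersion attached to duplicate Kd experiments is the half-range
(max − min)/2, and it is labelled as such; it is not a standard deviation.

## Dosing and stoichiometry conventions

Neat PCE density is fixed at 1.618 g/mL (23 °C), which maps the standard
10/15 μL feeding volumes to 97.6/146.4 μmol. The lactate syrup is treated
as 60% w/w *sodium* lactate (M = 112.06 g/mol, ρ = 1.33 g/mL), reproducing
the 1068 μmol spike; whether published μmol refer to the ion or the salt is
ambiguous, and the sodium-salt reading is the one that matches the printed
number. Electrons per mole on complete oxidation to CO2: lactate 12,
acetate 8, propionate 14, butyrate 20, H2 2; dechlorination takes 2 e− per
chlorine removed and methane books 8 e−/mol as the CO2-reduction product.
These follow standard half-reaction accounting (1068 μmol lactate × 12 e−
= 0.013 eeq). In the electron ledger, VFAs are counted as donor electrons
*parked* in fermentation products, not consumed; intermediate chlorinated
species (TCE, *cis*-DCE, VC) can be passed as products and are reported as
separate entries, so either accounting convention (with or without
intermediates) is recoverable from the output.

## Rate estimation and comparison

Production rates are ordinary least-squares slopes of per-bottle mass
against day over an explicit window. Below-detection points are excluded by
default; `censored_as_zero=True` includes them at 0, matching the
convention of plotting non-detects as zero. Both analysis modes are
provided: per-bottle fits summarized as mean ± half-range
(`treatment_rate`), and a single pooled regression per treatment
(`pooled_rate`). Treatment comparison uses a two-sided t statistic on the
difference of pooled-regression slopes with Welch–Satterthwaite degrees of
freedom; a per-bottle Welch t (`compare_rates_welch_bottles`) is offered as
an alternative but with duplicate bottles it has ~1 degree of freedom and
is very conservative. No standard rate-comparison test is established for
this design, so the choice is documented here rather than hidden.

Calibration caveat: OLS slope inference is exact under additive
homoscedastic noise. Headspace observations have roughly constant
*coefficient of variation*, i.e. heteroscedastic absolute error, under
which the slope t test is mildly anticonservative (empirically ~9% type-I
error at nominal 5% for a trajectory spanning two orders of magnitude).
The Monte-Carlo calibration suite therefore simulates the additive-noise
regression null; users comparing steep trajectories may prefer weighted
regression, which is deliberately left out of scope.

## Correlation and PCA

Spearman rho uses average ranks (tie-corrected). With fewer than 8 complete
pairs the permutation null is enumerated exactly (all n! orderings,
two-sided on |rho|); from 8 pairs upward the t approximation is used.
Significance is reported in raw tiers (p < 0.01, p < 0.05, ns) with no
multiple-testing correction by default, since the tier display convention
is exploratory; a Benjamini–Hochberg flag is available. "PCA of significant
variables" is standardized PCA — eigendecomposition of the correlation
matrix of z-scored variables — which is equivalent to principal coordinate
analysis with Euclidean distances on the standardized data. The sign
convention (largest-magnitude loading positive per component) makes
repeated runs bit-identical.

## The simulator

The synthetic-data generator exists so that every downstream estimator can
be validated by parameter recovery; it is a minimal mechanism, not a
calibrated biogeochemical model.

State per bottle: dissolved (aqueous + gas, always at Henry equilibrium)
and sorbed pools for the five ethene-series species, dissolved methane, an
H2 electron pool (μeq), and VFA pools. Processes:

* **Dechlorination** — each step converts moles at `k_i · Caq_i · Vl`
  (first-order in aqueous concentration) after a per-step revival lag,
  consuming 2 μeq/μmol from the H2 pool. First-order-with-lag is the
  minimal rate law that reproduces both observed phenotypes: a culture that
  stalls at *cis*-DCE (`k_cDCE = 0`) and one that revives after a lag. A
  `zero_order` mode instead interprets `k_i` as plateau rates in μmol/day;
  it exists because recovery tests need trajectories whose true production
  rate is a known constant, which no purely first-order chain provides.
* **Fermentation** — each lactate dose instantly splits its electron
  content into acetate/propionate/butyrate pools and the H2 pool. Defaults
  (6/4/50/40% of lactate electrons) were chosen once as realistic for a
  lactate-fed mixed culture in which butyrate dominates the VFA pool; the
  remainder of any split summing below 1 is unfermented/assimilated and
  stays unaccounted.
* **Methanogenesis** — first-order drain of the H2 pool (8 μeq per μmol
  CH4). Arm defaults (0.0035–0.006 /day) give methane production of
  roughly 15–30 μmol/bottle/day mid-experiment.
* **Sorption** — first-order mass transfer of the dissolved pool toward
  the linear-isotherm equilibrium, with separate adsorption and desorption
  coefficients; desorption ≤ adsorption encodes hysteresis (pore-filling
  release is slower than uptake). In the fast symmetric limit this reduces
  exactly to the closed-form three-phase distribution.

The observation model applies multiplicative Gaussian noise (default CV
5%) to gas-phase concentrations at the sampling days and reports readings
below per-compound detection limits as 0 with a censored flag.

### Numerics

Integration is a fixed-grid (default dt = 0.01 d) Strang split: the
sorption exchange — linear in (dissolved, sorbed) with the per-species
total conserved, and stiff for strongly sorbing chars (relaxation rate
`c(1+β)` with `β = Kd·m/Veff` up to ~260/day) — is advanced by its exact
exponential solution in half-steps; the non-stiff reaction network is
advanced by an explicit Heun step in between. Electron and substrate
limitation enter as Monod-type smooth switches with tiny half-saturation
constants (0.01 μeq, 1e-4 μmol) so the vector field stays differentiable
at exhaustion; the plateau-rate bias they introduce is below 1e-6 relative.
Mole and electron bookkeeping is flux-based — the same transfer amount is
subtracted from one pool and added to the next — so the C2 skeleton and the
electron ledger balance to machine precision at any step size. Per-step
transfer amounts are clamped to pool availability; a predictor step
overshooting negative by more than 1% of the dosed mass aborts with advice
to reduce dt. Halving dt changes trajectories by well under 0.1% for all
bundled scenarios.

### Bundled scenarios

Six arms mirror a standard design: no-material and sand controls (97.6
μmol PCE, stall at *cis*-DCE), Char350/Char500 (97.6 μmol + 48.8 μmol
re-spike at day 46), Char700/Char900 (146.4 μmol, later revival, stronger
sorption and hysteresis); lactate (1068 μmol) every 4 days; sampling every
2 days to day 80. The Kd table shipped for these arms is *synthetic*
(`data/kd_synthetic.csv`): a full compound × char matrix is not publicly
available, so values are constrained by the published PCE ordering
(1.4/2.0/3.9/36 L/g for Char350→Char900) with daughter products
progressively less sorptive. Rate constants and revival lags are scenario
parameters chosen once so the arms reproduce the qualitative study
phenotypes (ethene at ~5.1–5.6 μmol/bottle/day over days 28–44 for the
low-temperature chars, ~3 μmol/bottle/day after day 46 for the
high-temperature chars, >80% conversion of dosed PCE to ethene in every
biochar arm, controls stalled); they are frozen, not fitted to data. The
synthetic qPCR generator (`synthetic_qpcr_frame`) likewise emulates ~2
orders of magnitude of dechlorinator-marker growth in biochar arms and is
labelled synthetic.

### What passing tests show — and what they don't

The simulator shares its partitioning equations with the analysis stages
but *not* its kinetics: the analysis never assumes a rate law, so rate and
Kd recovery are genuine inversions, not circular checks. What the
synthetic data do not contain: biomass growth and decay (no Monod yields),
pH/redox chemistry, abiotic losses to butyl-rubber stoppers (a known
killed-control artifact), temperature excursions, carry-over between GC
injections, or biological variability between replicate bottles (duplicates
share the deterministic trajectory and differ only in observation noise).
Passing recovery tests therefore demonstrates correctness of the
accounting and estimation machinery under the stated observation model —
not that the kinetic parameters of any real microcosm are identifiable
from its data.

## Problem sizes used in validation

The validation suites use 1,000 random draws for the Kd-inversion
property, 100 seeded observation replicates for rate-recovery coverage,
500 replicates for type-I-error calibration (200 for the p-uniformity KS
check), exact enumeration up to n = 6 for the Spearman oracle, and the
six-arm scenario at its default 80-day, dt = 0.01 resolution for the
end-to-end phenotype check. These sizes give comfortable statistical
resolution for the asserted bounds while keeping the whole suite fast.

## Known limitations

* Kd is single-point linear; strongly nonlinear isotherms will bias the
  closure diagnostic in ways the simulator does not emulate.
* The eeq ledger treats the fermentation split as instantaneous;
  cross-feeding dynamics (propionate → acetate + H2, butyrate oxidation)
  are not modelled, so the VFA percentages are snapshots, not fluxes.
* The rate-comparison t test assumes homoscedastic regression errors (see
  above).
* Attached-biomass qPCR is normalized to the *total* sorbent mass; if an
  assay samples a fixed aliquot of solids instead, scale raw values before
  input.
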