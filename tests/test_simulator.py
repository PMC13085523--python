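"""Microcosm simulator: conservation laws, convergence, observation model."""

import dataclasses

import numpy as np
import pytest

from dechlor.core import BottleConfig, DoseEvent
from dechlor.partitioning import KdTable
from dechlor.scenarios import scenario_kd_table, scenario_params
from dechlor.simulator import (
    SimulationParams,
    observe,
    recovery_report,
    simulate_microcosm,
)


def minimal_params(**overrides):
    defaults = dict(
        bottle=BottleConfig(sorbent_mass=0.0, sorbent_name="none"),
        dose_schedule=(
            DoseEvent(day=0.0, compound="PCE", amount=97.6),
            DoseEvent(day=0.0, compound="lactate", amount=1068.0),
        ),
        k_dechlor=(0.5, 0.5, 0.5, 0.5),
        t_end=20.0,
        sampling_days=tuple(float(d) for d in range(0, 21, 2)),
        noise_cv=0.0,
        n_replicates=1,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


class TestValidation:
    def test_hysteresis_convention_enforced(self):
        with pytest.raises(ValueError, match="desorption"):
            minimal_params(sorption_adsorption=1.0, sorption_desorption=2.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            minimal_params(k_dechlor=(-1.0, 0, 0, 0))

    def test_fermentation_split_bounded(self):
        with pytest.raises(ValueError, match="sum"):
            minimal_params(
                fermentation_split={"acetate": 0.8, "butyrate": 0.8, "H2": 0.1}
            )


class TestConservation:
    def test_inert_pce_stays_at_dose(self):
        """With all rate constants zero and no sorbent, the PCE two-phase mass
        is the dose at every sampling time."""
        ds = simulate_microcosm(minimal_params(k_dechlor=(0, 0, 0, 0)), seed=1)
        assert np.allclose(ds.true_state.dissolved["PCE"], 97.6, rtol=1e-12)

    @pytest.mark.parametrize("arm", ["no-material", "Char500", "Char900"])
    def test_c2_skeleton_conserved(self, arm):
        """Σ (dissolved + sorbed) over the ethene series equals cumulative dose
        to < 1e-9 relative on noise-free runs."""
        params = scenario_params(arm, noise_cv=0.0, n_replicates=1)
        ds = simulate_microcosm(params, seed=2)
        tr = ds.true_state
        for i, day in enumerate(tr.days):
            dosed = tr.c2_dosed[i]
            assert tr.total_c2(i) == pytest.approx(dosed, rel=1e-9)

    def test_electron_ledger_conserved(self):
        """H2 supplied − H2 remaining = dechlorination + methane eeq exactly."""
        params = scenario_params("Char500", noise_cv=0.0, n_replicates=1)
        tr = simulate_microcosm(params, seed=3).true_state
        for i in range(len(tr.days)):
            lhs = tr.h2_supplied_eeq[i] - tr.h2_pool[i]
            rhs = tr.dechlor_eeq[i] + tr.methane_eeq(i)
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_chlorine_release_consistent_with_speciation(self):
        """Electrons consumed by dechlorination equal 2 × chlorines removed,
        recomputed independently from the speciation profile."""
        params = scenario_params("Char350", noise_cv=0.0, n_replicates=1)
        tr = simulate_microcosm(params, seed=4).true_state
        removed_per_mol = {"PCE": 0, "TCE": 1, "cis-DCE": 2, "VC": 3, "ethene": 4}
        i = len(tr.days) - 1
        cl_removed = sum(
            (tr.dissolved[c][i] + tr.sorbed[c][i]) * n
            for c, n in removed_per_mol.items()
        )
        assert tr.dechlor_eeq[i] == pytest.approx(2.0 * cl_removed, rel=1e-9)


class TestConvergence:
    def test_dt_halving_changes_results_below_tenth_percent(self):
        params = scenario_params("Char500", noise_cv=0.0, n_replicates=1, dt=0.01)
        coarse = simulate_microcosm(params, seed=5).true_state
        fine = simulate_microcosm(
            dataclasses.replace(params, dt=0.005), seed=5
        ).true_state
        scale = coarse.c2_dosed[-1]
        for key in ("PCE", "cis-DCE", "ethene", "methane"):
            diff = np.max(np.abs(coarse.dissolved[key] - fine.dissolved[key]))
            assert diff / scale < 1e-3

    def test_equilibrium_sorption_limit_matches_closed_form(self, registry):
        """With fast symmetric mass transfer, the sorbed phase sits on the
        closed-form linear-isotherm distribution."""
        kd = KdTable({("charX", "PCE"): (2.0, 0.0), ("charX", "TCE"): (0.0, 0.0),
                      ("charX", "cis-DCE"): (0.0, 0.0), ("charX", "VC"): (0.0, 0.0),
                      ("charX", "ethene"): (0.0, 0.0)})
        params = minimal_params(
            bottle=BottleConfig(sorbent_mass=0.2, sorbent_name="charX"),
            k_dechlor=(0, 0, 0, 0),
            kd_table=kd,
            sorption_adsorption=500.0,
            sorption_desorption=500.0,
            t_end=4.0,
            sampling_days=(0.0, 2.0, 4.0),
        )
        tr = simulate_microcosm(params, seed=6).true_state
        pce = registry["PCE"]
        veff = 0.100 + pce.henry_dimensionless * 0.060
        # closed form: Ce = M/(Veff + Kd m); sorbed = Kd·Ce·m
        ce = 97.6 / (veff + 2.0 * 0.2)
        assert tr.aqueous_conc["PCE"][-1] == pytest.approx(ce, rel=1e-9)
        assert tr.sorbed["PCE"][-1] == pytest.approx(2.0 * ce * 0.2, rel=1e-9)

    def test_instability_aborts_with_advice(self):
        params = minimal_params(k_dechlor=(500.0, 0.0, 0.0, 0.0), dt=0.5,
                                t_end=2.0, sampling_days=(0.0, 2.0))
        with pytest.raises(RuntimeError, match="reduce dt"):
            simulate_microcosm(params, seed=7)


class TestObservationModel:
    def test_zero_noise_reproduces_truth(self):
        ds = simulate_microcosm(minimal_params(), seed=8)
        tr = ds.true_state
        obs = {s.compound: s for s in ds.observations}
        for name in ("PCE", "ethene"):
            for (day, value, censored), true in zip(
                obs[name].points, tr.gas_conc[name]
            ):
                if not censored:
                    assert value == pytest.approx(true, rel=1e-12)
                else:
                    assert true == 0.0

    def test_fixed_seed_bit_identical(self):
        params = minimal_params(noise_cv=0.05)
        a = simulate_microcosm(params, seed=9)
        b = simulate_microcosm(params, seed=9)
        assert a.observations == b.observations

    def test_seeds_differ(self):
        params = minimal_params(noise_cv=0.05)
        a = simulate_microcosm(params, seed=9)
        b = simulate_microcosm(params, seed=10)
        assert a.observations != b.observations

    def test_noise_cv_calibrated(self):
        """10,000 noisy draws of one true value have sample CV within 5% of
        the configured CV."""
        ds = simulate_microcosm(minimal_params(k_dechlor=(0, 0, 0, 0)), seed=11)
        tr = ds.true_state
        cv = 0.08
        draws = []
        for rep_seed in range(100):
            for s in observe(tr, noise_cv=cv, detection_limits={}, seed=rep_seed,
                             n_replicates=1, compounds=["PCE"]):
                draws.extend(v for _, v, c in s.points if not c)
        draws = np.asarray(draws)
        sample_cv = draws.std(ddof=1) / draws.mean()
        assert len(draws) >= 1000
        assert sample_cv == pytest.approx(cv, rel=0.05)

    def test_detection_limit_censors_to_zero(self):
        ds = simulate_microcosm(minimal_params(k_dechlor=(0, 0, 0, 0)), seed=12)
        series = observe(ds.true_state, noise_cv=0.0,
                         detection_limits={"PCE": 1e9}, seed=0)
        pce = next(s for s in series if s.compound == "PCE")
        assert all(c for _, _, c in pce.points)
        assert all(v == 0.0 for _, v, _ in pce.points)


class TestRecoveryReport:
    def test_noise_free_recovery_is_exact(self, registry, kd_table):
        """Closing the loop on a noise-free dataset: Kd and production-rate
        estimates recovered by the analysis stages match the simulator truth."""
        from dechlor.partitioning import SorptionExperiment, estimate_kd
        from dechlor.rates import production_rate
        from dechlor.core import MassSeries, PhaseBasis
        from dechlor.partitioning import two_phase_total_mass

        # Kd: forward equilibrium from the simulator's sorption model
        params = scenario_params("Char500", noise_cv=0.0, n_replicates=1)
        bottle = params.bottle
        pce = registry["PCE"]
        kd_true = kd_table.kd("Char500", "PCE")
        veff = 0.100 + pce.henry_dimensionless * 0.060
        ce = 100.0 / (veff + kd_true * bottle.sorbent_mass)
        est_kd = estimate_kd(SorptionExperiment(pce, 100.0, ce, bottle)).kd

        # rate: noise-free zero-order trajectory
        zp = minimal_params(
            dose_schedule=(DoseEvent(day=0.0, compound="PCE", amount=320.0),
                           DoseEvent(day=0.0, compound="lactate", amount=5000.0)),
            k_dechlor=(50.0, 50.0, 50.0, 5.6), zero_order=True,
            t_end=40.0, sampling_days=tuple(float(d) for d in range(0, 41, 2)),
        )
        tr = simulate_microcosm(zp, seed=13).true_state
        mass = MassSeries(
            "b1", "ethene",
            tuple((float(d), float(m), False)
                  for d, m in zip(tr.days, tr.dissolved["ethene"])),
            PhaseBasis.two_phase_mass,
        )
        est_rate = production_rate(mass, (10.0, 30.0)).slope

        report = recovery_report(
            truths={"kd/Char500/PCE": kd_true, "rate/ethene": 5.6},
            estimates={"kd/Char500/PCE": est_kd, "rate/ethene": est_rate},
            tolerance=1e-6,
        )
        assert not report["exceeds_tolerance"].any()
        assert (report["relative_error"] < 1e-6).all()
        assert abs(est_kd - kd_true) / kd_true < 1e-9

    def test_unknown_estimate_rejected(self):
        with pytest.raises(KeyError, match="mystery"):
            recovery_report({"a": 1.0}, {"mystery": 2.0})

    def test_hysteresis_produces_transient_closure_deficit(self, registry, kd_table):
        """Slow desorption makes the equilibrium-assuming closure fall below 1
        while sorbed mass is hidden, recovering as products shift to
        low-Kd species."""
        from dechlor.core import ETHENE_SERIES
        from dechlor.partitioning import three_phase_balance

        params = scenario_params("Char900", noise_cv=0.0, n_replicates=1)
        ds = simulate_microcosm(params, seed=14)
        series = [s for s in ds.observations if s.compound in ETHENE_SERIES]
        nominal = {0.0: 146.4}
        points = three_phase_balance(series, kd_table, params.bottle, nominal,
                                     registry)
        days = np.array([bp.day for bp in points])
        cf = np.array([bp.closure_fraction for bp in points])
        active = (days >= 40) & (days <= 56)  # desorption-limited conversion
        assert cf[active].min() < 0.9
        assert cf[days >= 70].mean() > cf[active].min() + 0.05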