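"""Henry partitioning, Kd estimation by mass balance, and closure diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dechlor.core import BottleConfig, MassSeries, PhaseBasis
from dechlor.partitioning import (
    KdTable,
    SorptionExperiment,
    aqueous_conc_from_total,
    aqueous_conc_if_fully_dissolved,
    aqueous_from_gas,
    estimate_kd,
    summarize_kd,
    three_phase_balance,
    two_phase_total_mass,
)


@pytest.fixture
def sorbent_bottle():
    return BottleConfig(sorbent_mass=0.2, sorbent_name="charX")


def forward_equilibrium_ce(added_mass, kd, compound, bottle):
    """Independent closed-form oracle: equilibrium Ce for a linear isotherm.

    Mass balance: added = Ce·(Vl + Hc·Vg) + Ce·Kd·m  →  Ce = added / (Veff + Kd·m).
    """
    veff = bottle.liquid_volume + compound.henry_dimensionless * bottle.headspace_volume
    return added_mass / (veff + kd * bottle.sorbent_mass)


class TestHenryConversions:
    @pytest.mark.parametrize(
        "compound, c_gas, expected",
        [("PCE", 6.4, 10.0), ("methane", 27.03, 1.0)],
    )
    def test_aqueous_from_gas_divides_by_hc(self, registry, compound, c_gas, expected):
        assert aqueous_from_gas(c_gas, registry[compound]) == pytest.approx(expected)

    def test_identity_at_unit_henry(self):
        from dechlor.core import Compound
        c = Compound(name="unit", molar_mass=10.0, henry_dimensionless=1.0)
        assert aqueous_from_gas(5.0, c) == 5.0

    def test_nonvolatile_rejected(self, registry):
        with pytest.raises(Exception, match="lactate"):
            aqueous_from_gas(1.0, registry["lactate"])

    def test_two_phase_mass_pce_dose(self, registry, bottle):
        """Caq 705.2 μmol/L of PCE in the standard bottle holds the 97.6 μmol dose."""
        caq = 705.2
        c_gas = caq * 0.64
        mass = two_phase_total_mass(c_gas, registry["PCE"], bottle)
        assert mass == pytest.approx(caq * (0.100 + 0.64 * 0.060), rel=1e-12)
        assert mass == pytest.approx(97.6, abs=0.05)

    def test_two_phase_zero_and_monotone(self, registry, bottle):
        pce = registry["PCE"]
        assert two_phase_total_mass(0.0, pce, bottle) == 0.0
        masses = [two_phase_total_mass(c, pce, bottle) for c in (1.0, 2.0, 5.0)]
        assert masses == sorted(masses)

    def test_gas_dominated_limit(self, bottle):
        """As Hc grows the two-phase mass approaches Cgas × headspace volume."""
        from dechlor.core import Compound
        c = Compound(name="vol", molar_mass=10.0, henry_dimensionless=1e9)
        mass = two_phase_total_mass(100.0, c, bottle)
        assert mass == pytest.approx(100.0 * bottle.headspace_volume, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(caq=st.floats(min_value=1e-6, max_value=1e4),
           hc=st.floats(min_value=1e-3, max_value=100.0))
    def test_mass_conc_round_trip(self, caq, hc):
        """aqueous_conc_from_total inverts two_phase_total_mass exactly."""
        from dechlor.core import Compound
        c = Compound(name="rt", molar_mass=50.0, henry_dimensionless=hc)
        b = BottleConfig(sorbent_mass=0.0)
        mass = two_phase_total_mass(caq * hc, c, b)
        assert aqueous_conc_from_total(mass, c, b) == pytest.approx(caq, rel=1e-12)


class TestFullyDissolvedConvention:
    def test_pce_dose_concentration(self, registry, bottle):
        """97.6 μmol PCE in 100 mL corresponds to ~162 mg/L if fully dissolved."""
        mg_l = aqueous_conc_if_fully_dissolved(97.6, registry["PCE"], bottle)
        assert mg_l == pytest.approx(162, abs=1.0)

    def test_zero_and_linearity(self, registry, bottle):
        pce = registry["PCE"]
        assert aqueous_conc_if_fully_dissolved(0.0, pce, bottle) == 0.0
        one = aqueous_conc_if_fully_dissolved(10.0, pce, bottle)
        assert aqueous_conc_if_fully_dissolved(20.0, pce, bottle) == pytest.approx(2 * one)


class TestKdEstimation:
    def test_inverts_forward_model_example(self, registry, sorbent_bottle):
        """Forward Kd = 2 L/g distribution is recovered exactly from Ce."""
        pce = registry["PCE"]
        ce = forward_equilibrium_ce(100.0, 2.0, pce, sorbent_bottle)
        assert ce == pytest.approx(185.7, abs=0.05)
        est = estimate_kd(SorptionExperiment(pce, 100.0, ce, sorbent_bottle))
        assert est.kd == pytest.approx(2.0, rel=1e-12)
        assert est.sorbed_conc == pytest.approx(2.0 * ce, rel=1e-12)
        assert not est.inconsistent

    def test_no_sorption_gives_zero_kd(self, registry, sorbent_bottle):
        pce = registry["PCE"]
        ce = forward_equilibrium_ce(100.0, 0.0, pce, sorbent_bottle)
        est = estimate_kd(SorptionExperiment(pce, 100.0, ce, sorbent_bottle))
        assert est.kd == pytest.approx(0.0, abs=1e-12)

    def test_ce_above_bound_flags_inconsistent(self, registry, sorbent_bottle):
        pce = registry["PCE"]
        ce = 100.0 / (0.100 + 0.64 * 0.060) * 1.05  # 5% above the no-sorption bound
        exp = SorptionExperiment(pce, 100.0, ce, sorbent_bottle)
        assert not exp.consistent
        est = estimate_kd(exp)
        assert est.inconsistent
        assert est.sorbed_conc < 0

    def test_nondetect_ce_yields_lower_bound(self, registry, sorbent_bottle):
        pce = registry["PCE"]
        exp = SorptionExperiment(pce, 100.0, 0.0, sorbent_bottle)
        with pytest.raises(ValueError, match="detection"):
            estimate_kd(exp)
        est = estimate_kd(exp, ce_detection_limit=0.5)
        assert est.lower_bound
        assert np.isfinite(est.kd) and est.kd > 0

    def test_duplicates_summarized_as_mean_half_range(self, registry, sorbent_bottle):
        pce = registry["PCE"]
        ests = [
            estimate_kd(SorptionExperiment(
                pce, 100.0, forward_equilibrium_ce(100.0, kd, pce, sorbent_bottle),
                sorbent_bottle))
            for kd in (1.8, 2.2)
        ]
        mean, half_range = summarize_kd(ests)
        assert mean == pytest.approx(2.0, rel=1e-9)
        assert half_range == pytest.approx(0.2, rel=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        kd=st.floats(min_value=0.0, max_value=100.0),
        hc=st.floats(min_value=1e-3, max_value=50.0),
        added=st.floats(min_value=1.0, max_value=1e4),
        msorb=st.floats(min_value=0.01, max_value=5.0),
    )
    def test_estimator_inverts_forward_model(self, kd, hc, added, msorb):
        """estimate_kd is the exact inverse of the three-phase equilibrium."""
        from dechlor.core import Compound
        c = Compound(name="prop", molar_mass=100.0, henry_dimensionless=hc)
        b = BottleConfig(sorbent_mass=msorb, sorbent_name="s")
        ce = forward_equilibrium_ce(added, kd, c, b)
        est = estimate_kd(SorptionExperiment(c, added, ce, b))
        assert est.kd == pytest.approx(kd, rel=1e-9, abs=1e-9)


class TestKdTable:
    def test_nonsorbing_defaults(self):
        table = KdTable({("charX", "PCE"): (2.0, 0.1)})
        assert table.kd("sand", "PCE") == 0.0
        assert table.kd("none", "ethene") == 0.0
        assert table.kd("charX", "PCE") == 2.0
        with pytest.raises(KeyError):
            table.kd("charY", "PCE")

    def test_negative_kd_rejected(self):
        with pytest.raises(ValueError):
            KdTable({("c", "PCE"): (-1.0, 0.0)})

    def test_csv_round_trip(self, tmp_path, kd_table):
        path = tmp_path / "kd.csv"
        kd_table.to_csv(path)
        loaded = KdTable.from_csv(path)
        for (sorbent, compound), (kd, hr) in kd_table.items():
            assert loaded.kd(sorbent, compound) == pytest.approx(kd)
            assert loaded.half_range(sorbent, compound) == pytest.approx(hr)


class TestThreePhaseBalance:
    def _gas_series(self, registry, bottle, masses_by_compound, days):
        """Build gas-conc series from per-compound two-phase masses (no sorption)."""
        out = []
        for name, masses in masses_by_compound.items():
            c = registry[name]
            veff = bottle.liquid_volume + c.henry_dimensionless * bottle.headspace_volume
            pts = tuple(
                (d, m / veff * c.henry_dimensionless, False)
                for d, m in zip(days, masses)
            )
            out.append(MassSeries("b1", name, pts, PhaseBasis.gas_conc))
        return out

    def test_zero_kd_reduces_to_two_phase(self, registry, bottle):
        days = (0.0, 2.0)
        series = self._gas_series(
            registry, bottle, {"PCE": (60.0, 40.0), "TCE": (0.0, 20.0)}, days
        )
        table = KdTable({})
        points = three_phase_balance(series, table, bottle, 100.0, registry)
        for bp, expected_sum in zip(points, (60.0, 60.0)):
            assert bp.estimated_sorbed == 0.0
            assert bp.measured_two_phase_sum == pytest.approx(expected_sum, rel=1e-9)
            assert bp.closure_fraction == pytest.approx(expected_sum / 100.0, rel=1e-9)

    def test_equilibrium_sorption_closes_exactly(self, registry, kd_table):
        """With true equilibrium partitioning the Kd-corrected closure is 1."""
        bottle = BottleConfig(sorbent_mass=0.2, sorbent_name="Char700")
        added = 100.0
        days = (0.0,)
        series = []
        for name in ("PCE", "TCE"):
            c = registry[name]
            kd = kd_table.kd("Char700", name)
            ce = forward_equilibrium_ce(added / 2, kd, c, bottle)
            series.append(
                MassSeries("b1", name,
                           ((0.0, ce * c.henry_dimensionless, False),),
                           PhaseBasis.gas_conc)
            )
        (bp,) = three_phase_balance(series, kd_table, bottle, added, registry)
        assert bp.closure_fraction == pytest.approx(1.0, abs=1e-9)

    def test_hidden_sorbed_mass_underestimates_closure(self, registry, kd_table):
        """Aqueous levels below equilibrium make the sorbed estimate too small."""
        bottle = BottleConfig(sorbent_mass=0.2, sorbent_name="Char900")
        pce = registry["PCE"]
        added = 146.4
        ce_eq = forward_equilibrium_ce(added, kd_table.kd("Char900", "PCE"), pce, bottle)
        series = [
            MassSeries("b1", "PCE",
                       ((0.0, 0.1 * ce_eq * pce.henry_dimensionless, False),),
                       PhaseBasis.gas_conc)
        ]
        (bp,) = three_phase_balance(series, kd_table, bottle, added, registry)
        assert bp.closure_fraction < 0.5

    def test_missing_kd_lists_compounds(self, registry):
        bottle = BottleConfig(sorbent_mass=0.2, sorbent_name="mystery")
        series = [MassSeries("b1", "PCE", ((0.0, 1.0, False),), PhaseBasis.gas_conc)]
        with pytest.raises(KeyError, match="PCE"):
            three_phase_balance(series, KdTable({}), bottle, 100.0, registry)

    def test_respike_raises_nominal(self, registry, bottle):
        days = (44.0, 48.0)
        series = self._gas_series(registry, bottle, {"ethene": (97.6, 97.6)}, days)
        points = three_phase_balance(
            series, KdTable({}), bottle, {0.0: 97.6, 46.0: 146.4}, registry
        )
        assert points[0].nominal_added == 97.6
        assert points[1].nominal_added == 146.4
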