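"""Gas–aqueous–sorbed equilibrium partitioning and mass-balance closure.

A sealed bottle holds a volatile analyte in three pools: headspace gas,
aqueous solution, and (when a sorbent is present) a sorbed phase. At
equilibrium the pools are linked by the dimensionless Henry constant
``Hc = Cgas / Caq`` and the linear partition coefficient ``Kd = Cs / Ce``
(L/g). A single headspace reading therefore fixes the two-phase (aqueous +
gas) mass, and an independently measured Kd extends it to a three-phase
estimate. The closure fraction — (measured two-phase mass + estimated sorbed
mass) / nominal dosed mass — is the mass-balance diagnostic used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    BottleConfig,
    Compound,
    CompoundRegistry,
    ConfigurationError,
    MassSeries,
    PhaseBasis,
    default_registry,
)

__all__ = [
    "SorptionExperiment",
    "KdEstimate",
    "KdTable",
    "BalancePoint",
    "aqueous_from_gas",
    "two_phase_total_mass",
    "aqueous_conc_from_total",
    "aqueous_conc_if_fully_dissolved",
    "estimate_kd",
    "summarize_kd",
    "three_phase_balance",
]


def _require_volatile(compound: Compound) -> float:
    if compound.henry_dimensionless is None:
        raise ConfigurationError(
            f"{compound.name} is non-volatile; headspace partitioning undefined"
        )
    return compound.henry_dimensionless


def effective_volume(compound: Compound, bottle: BottleConfig) -> float:
    """Two-phase 'effective volume' Vl + Hc·Vg (L).

    Multiplying an aqueous concentration by this volume gives the total
    aqueous + gas mass in the bottle.
    """
    hc = _require_volatile(compound)
    return bottle.liquid_volume + hc * bottle.headspace_volume


def aqueous_from_gas(c_gas: float, compound: Compound) -> float:
    """Aqueous concentration (μmol/L) in equilibrium with headspace ``c_gas``."""
    hc = _require_volatile(compound)
    if c_gas < 0:
        raise ValueError("gas concentration must be >= 0")
    return c_gas / hc


def two_phase_total_mass(c_gas: float, compound: Compound, bottle: BottleConfig) -> float:
    """Total aqueous + gas mass (μmol/bottle) from a headspace reading.

    ``M = Caq (Vl + Hc·Vg)`` with ``Caq = Cgas / Hc`` — equivalently
    ``Cgas·Vg + Caq·Vl``.
    """
    caq = aqueous_from_gas(c_gas, compound)
    return caq * effective_volume(compound, bottle)


def aqueous_conc_from_total(mass: float, compound: Compound, bottle: BottleConfig) -> float:
    """Invert :func:`two_phase_total_mass`: Caq (μmol/L) from two-phase mass."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    return mass / effective_volume(compound, bottle)


def aqueous_conc_if_fully_dissolved(
    mass: float, compound: Compound, bottle: BottleConfig
) -> float:
    """Nominal aqueous concentration (mg/L) if the whole dose were dissolved.

    Ignores headspace and sorbed partitioning — the convention used to compare
    a dose against aqueous solubility or toxicity thresholds (97.6 μmol PCE in
    100 mL → ~162 mg/L).
    """
    if mass < 0:
        raise ValueError("mass must be >= 0")
    return mass / bottle.liquid_volume * compound.molar_mass / 1000.0


@dataclass(frozen=True)
class SorptionExperiment:
    """One abiotic sorption-equilibrium bottle.

    ``added_mass`` μmol of ``compound`` equilibrated with ``bottle.sorbent_mass``
    g of sorbent; ``equilibrium_aqueous_conc`` (Ce, μmol/L) measured at the end.
    """

    compound: Compound
    added_mass: float  # μmol
    equilibrium_aqueous_conc: float  # μmol/L
    bottle: BottleConfig

    def __post_init__(self) -> None:
        if self.added_mass <= 0:
            raise ValueError("added_mass must be > 0")
        if self.equilibrium_aqueous_conc < 0:
            raise ValueError("Ce must be >= 0")
        if self.bottle.sorbent_mass <= 0:
            raise ValueError("sorption experiment requires sorbent_mass > 0")

    @property
    def dissolved_mass(self) -> float:
        """Aqueous + gas mass at equilibrium (μmol)."""
        return self.equilibrium_aqueous_conc * effective_volume(
            self.compound, self.bottle
        )

    @property
    def consistent(self) -> bool:
        """False when Ce alone accounts for more than the added mass."""
        return self.dissolved_mass <= self.added_mass


@dataclass(frozen=True)
class KdEstimate:
    """Mass-balance Kd estimate from one sorption experiment.

    ``inconsistent`` marks a negative computed sorbed mass (Ce exceeding the
    no-sorption bound); ``lower_bound`` marks a Ce at/below detection, where
    only ``Kd >= value`` can be claimed.
    """

    compound: str
    kd: float  # L/g
    sorbed_conc: float  # Cs, μmol/g
    inconsistent: bool = False
    lower_bound: bool = False


def estimate_kd(
    exp: SorptionExperiment, ce_detection_limit: float | None = None
) -> KdEstimate:
    """Estimate Kd (L/g) by mass balance from a sorption-equilibrium bottle.

    Sorbed mass is the added mass minus the dissolved (aqueous + gas) mass:
    ``Cs = (M_added − Ce (Vl + Hc·Vg)) / m_sorbent``; ``Kd = Cs / Ce``.
    A negative Cs is flagged inconsistent (never clipped). A non-detect
    (Ce = 0) cannot fix Kd; with ``ce_detection_limit`` (μmol/L) supplied the
    estimate is returned as the lower bound ``Cs / limit`` with
    ``lower_bound=True``, otherwise it is an error — Kd is never reported
    as infinite.
    """
    sorbed = (exp.added_mass - exp.dissolved_mass) / exp.bottle.sorbent_mass
    ce = exp.equilibrium_aqueous_conc
    if sorbed < 0:
        return KdEstimate(exp.compound.name, kd=sorbed / ce if ce > 0 else float("nan"),
                          sorbed_conc=sorbed, inconsistent=True)
    if ce == 0:
        if ce_detection_limit is None or ce_detection_limit <= 0:
            raise ValueError(
                f"{exp.compound.name}: Ce below detection; supply "
                "ce_detection_limit to obtain a Kd lower bound"
            )
        return KdEstimate(exp.compound.name, kd=sorbed / ce_detection_limit,
                          sorbed_conc=sorbed, lower_bound=True)
    return KdEstimate(exp.compound.name, kd=sorbed / ce, sorbed_conc=sorbed)


def summarize_kd(estimates: Sequence[KdEstimate]) -> tuple[float, float]:
    """Mean ± half-range over replicate experiments (the duplicate convention)."""
    if not estimates:
        raise ValueError("no estimates to summarize")
    if any(e.inconsistent for e in estimates):
        raise ValueError("cannot summarize inconsistent estimates; inspect them")
    kds = [e.kd for e in estimates]
    return sum(kds) / len(kds), (max(kds) - min(kds)) / 2.0


class KdTable:
    """(sorbent, compound) → linear partition coefficient Kd (L/g).

    Unlisted sorbents named ``"sand"`` or ``"none"`` default to 0 (no
    measurable sorption); anything else missing raises ``KeyError``.
    """

    _NONSORBING = {"sand", "none", "no-material", ""}

    def __init__(self, entries: Mapping[tuple[str, str], tuple[float, float]]):
        for (sorbent, compound), (kd, hr) in entries.items():
            if kd < 0 or hr < 0:
                raise ValueError(f"negative Kd or half-range for {sorbent}/{compound}")
        self._entries = dict(entries)

    def kd(self, sorbent: str, compound: str) -> float:
        key = (sorbent, compound)
        if key in self._entries:
            return self._entries[key][0]
        if sorbent in self._NONSORBING:
            return 0.0
        raise KeyError(f"no Kd for sorbent {sorbent!r}, compound {compound!r}")

    def half_range(self, sorbent: str, compound: str) -> float:
        key = (sorbent, compound)
        if key in self._entries:
            return self._entries[key][1]
        if sorbent in self._NONSORBING:
            return 0.0
        raise KeyError(f"no Kd for sorbent {sorbent!r}, compound {compound!r}")

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries or key[0] in self._NONSORBING

    def items(self):
        return self._entries.items()

    @classmethod
    def from_csv(cls, path: "str | Path") -> "KdTable":
        df = pd.read_csv(path)
        required = {"sorbent", "compound", "kd"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: KdTable CSV needs columns {sorted(required)}")
        entries = {}
        for _, row in df.iterrows():
            hr = float(row["half_range"]) if "half_range" in df.columns else 0.0
            entries[(str(row["sorbent"]), str(row["compound"]))] = (
                float(row["kd"]), hr,
            )
        return cls(entries)

    def to_csv(self, path: "str | Path") -> None:
        rows = [
            {"sorbent": s, "compound": c, "kd": kd, "half_range": hr}
            for (s, c), (kd, hr) in sorted(self._entries.items())
        ]
        pd.DataFrame(rows, columns=["sorbent", "compound", "kd", "half_range"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class BalancePoint:
    """Mass-balance closure at one sampling day."""

    day: float
    measured_two_phase_sum: float  # μmol, Σ over CE + ethene
    estimated_sorbed: float  # μmol, Σ Caq·Kd·m
    nominal_added: float  # μmol dosed up to this day
    closure_fraction: float


def three_phase_balance(
    series: Sequence[MassSeries],
    kd_table: KdTable,
    bottle: BottleConfig,
    nominal_added: "float | Mapping[float, float]",
    registry: CompoundRegistry | None = None,
) -> list[BalancePoint]:
    """Three-phase mass-balance closure over time for one bottle.

    ``series`` holds one trajectory per chlorinated-ethene-series compound
    (gas-phase concentration or two-phase mass basis), sampled on a common
    day grid. Per day: the measured two-phase masses are summed, the sorbed
    mass is estimated as ``Σ_c Caq_c · Kd_c · m_sorbent`` assuming sorption
    equilibrium, and the closure fraction is computed against the nominal
    dosed mass. ``nominal_added`` is either a constant or a mapping
    day → cumulative μmol dosed by that day (re-spikes).

    Censored (below-detection) points contribute 0 mass, the plotting
    convention for non-detects.
    """
    registry = registry or default_registry()
    if not series:
        raise ValueError("no series supplied")
    missing = [
        s.compound
        for s in series
        if (bottle.sorbent_name, s.compound) not in kd_table
    ]
    if missing:
        raise KeyError(
            f"no Kd for sorbent {bottle.sorbent_name!r} and compounds {sorted(set(missing))}"
        )
    days = series[0].days
    for s in series[1:]:
        if s.days != days:
            raise ValueError(
                f"series day grids differ ({s.compound} vs {series[0].compound})"
            )

    def nominal_at(day: float) -> float:
        if isinstance(nominal_added, Mapping):
            dosed = [m for d, m in nominal_added.items() if d <= day]
            if not dosed:
                raise ValueError(f"no dose on record by day {day}")
            return max(dosed)
        return float(nominal_added)

    points: list[BalancePoint] = []
    for i, day in enumerate(days):
        two_phase = 0.0
        sorbed = 0.0
        for s in series:
            compound = registry[s.compound]
            _, value, censored = s.points[i]
            if censored:
                continue
            if s.phase_basis is PhaseBasis.gas_conc:
                mass = two_phase_total_mass(value, compound, bottle)
                caq = aqueous_from_gas(value, compound)
            elif s.phase_basis is PhaseBasis.two_phase_mass:
                mass = value
                caq = aqueous_conc_from_total(value, compound, bottle)
            else:
                raise ValueError(
                    f"{s.compound}: three-phase balance needs gas_conc or "
                    "two_phase_mass series"
                )
            two_phase += mass
            sorbed += caq * kd_table.kd(bottle.sorbent_name, s.compound) * bottle.sorbent_mass
        nominal = nominal_at(day)
        points.append(
            BalancePoint(
                day=day,
                measured_two_phase_sum=two_phase,
                estimated_sorbed=sorbed,
                nominal_added=nominal,
                closure_fraction=(two_phase + sorbed) / nominal,
            )
        )
    return points
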