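"""Electron-equivalent (eeq) accounting for donor and product pools.

Electron equivalents are moles of transferable electrons: a donor
contributes ``amount × donor_electrons`` (electrons released on complete
oxidation to CO2 — lactate 12, acetate 8, propionate 14, butyrate 20,
H2 2 per mole), and a dechlorination product books ``amount ×
acceptor_electrons_vs_PCE`` (2 electrons per chlorine removed from PCE;
methane books 8 as the CO2-reduction product). The distribution ledger
expresses each product's eeq as a percentage of the donor eeq supplied;
fermentation products (VFAs) count as donor electrons parked, not consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import Compound, CompoundRegistry, DoseEvent, default_registry

__all__ = ["EeqEntry", "EeqLedger", "donor_eeq", "acceptor_eeq", "eeq_distribution"]

MICRO = 1e-6


def donor_eeq(amount_umol: float, compound: Compound) -> float:
    """Electron equivalents (eq) supplied by ``amount_umol`` of a donor.

    1068 μmol lactate (12 e−/mol) → 0.0128 eq ≈ 0.013 eeq.
    """
    if amount_umol < 0:
        raise ValueError("amount must be >= 0")
    if compound.donor_electrons is None:
        raise ValueError(f"{compound.name} is not registered as an electron donor")
    return amount_umol * MICRO * compound.donor_electrons


def acceptor_eeq(
    product_amounts: Mapping[str, float],
    registry: CompoundRegistry | None = None,
) -> float:
    """Electron equivalents (eq) accepted to form the given products from PCE.

    Ethene books 8 e−/mol, VC 6, cis-DCE 4, TCE 2 (PCE itself 0); methane 8.
    """
    registry = registry or default_registry()
    total = 0.0
    for name, amount in product_amounts.items():
        compound = registry[name]
        if compound.acceptor_electrons_vs_PCE is None:
            raise ValueError(f"{name} has no acceptor electron stoichiometry")
        if amount < 0:
            raise ValueError(f"{name}: amount must be >= 0")
        total += amount * MICRO * compound.acceptor_electrons_vs_PCE
    return total


@dataclass(frozen=True)
class EeqEntry:
    compound: str
    amount_umol: float
    eeq: float
    percent_of_donor: float


@dataclass(frozen=True)
class EeqLedger:
    """Distribution of donor electrons over measured product pools.

    ``over_closure`` flags accounted eeq exceeding donor eeq (measurement
    inconsistency); the unaccounted percentage is then negative and reported
    as-is rather than clipped.
    """

    donor_eeq_total: float
    entries: tuple[EeqEntry, ...]
    unaccounted_percent: float

    @property
    def over_closure(self) -> bool:
        return self.unaccounted_percent < 0

    @property
    def accounted_percent(self) -> float:
        return sum(e.percent_of_donor for e in self.entries)

    def percent(self, compound: str) -> float:
        for e in self.entries:
            if e.compound == compound:
                return e.percent_of_donor
        raise KeyError(compound)


def eeq_distribution(
    donor_doses: Sequence[DoseEvent],
    product_amounts: Mapping[str, float],
    registry: CompoundRegistry | None = None,
) -> EeqLedger:
    """Build the eeq ledger: percent of donor electrons in each product pool.

    ``donor_doses`` are the feeding events (e.g. repeated lactate spikes);
    ``product_amounts`` maps product compounds (VFAs, ethene, methane, and
    optionally intermediate CEs) to μmol present at the accounting day.
    VFA products book their full donor-electron content (electrons parked in
    fermentation products); dechlorination products and methane book their
    acceptor stoichiometry.
    """
    registry = registry or default_registry()
    donor_total = 0.0
    for dose in donor_doses:
        donor_total += donor_eeq(dose.amount, registry[dose.compound])
    if donor_total <= 0:
        raise ValueError("zero donor eeq; supply at least one donor dose")
    entries = []
    for name, amount in product_amounts.items():
        compound = registry[name]
        if compound.ethene_series or name == "methane":
            eeq = acceptor_eeq({name: amount}, registry)
        elif compound.donor_electrons is not None:
            eeq = donor_eeq(amount, compound)
        else:
            raise ValueError(f"{name}: no eeq stoichiometry registered")
        entries.append(
            EeqEntry(
                compound=name,
                amount_umol=amount,
                eeq=eeq,
                percent_of_donor=eeq / donor_total * 100.0,
            )
        )
    accounted = sum(e.percent_of_donor for e in entries)
    return EeqLedger(
        donor_eeq_total=donor_total,
        entries=tuple(entries),
        unaccounted_percent=100.0 - accounted,
    )
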