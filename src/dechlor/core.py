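"""Domain types, compound registry and dosing arithmetic for sealed-bottle microcosms.

Canonical internal units throughout the package: amounts in μmol per bottle,
concentrations in μmol/L, volumes in L, sorbent mass in g, time in days.
All unit conversions happen at the I/O boundary (dosing helpers, CSV readers).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Compound",
    "CompoundRegistry",
    "default_registry",
    "BottleConfig",
    "DoseEvent",
    "PhaseBasis",
    "MassSeries",
    "ConfigurationError",
    "ParseError",
    "neat_liquid_to_micromoles",
    "syrup_dose_to_micromoles",
    "read_timeseries",
    "write_timeseries",
]

# Dechlorination sequence of the C2 chlorinated-ethene series, parent first.
ETHENE_SERIES = ("PCE", "TCE", "cis-DCE", "VC", "ethene")


class ConfigurationError(ValueError):
    """A compound definition or bottle configuration is invalid or incomplete."""


class ParseError(ValueError):
    """A tabular input file could not be parsed; message carries the line number."""


@dataclass(frozen=True)
class Compound:
    """Physicochemical and stoichiometric constants for one analyte.

    Parameters
    ----------
    name
        Registry identifier (e.g. ``"PCE"``, ``"cis-DCE"``).
    molar_mass
        g/mol.
    henry_dimensionless
        Gas-phase over aqueous-phase concentration ratio at 23 °C;
        ``None`` for non-volatile species (organic acids).
    neat_density
        g/mL at 23 °C for species dosed as a neat liquid or syrup.
    chlorine_count
        Number of chlorine substituents (0 for non-chlorinated species).
    donor_electrons
        Electrons released per mole on complete oxidation to CO2;
        ``None`` for species not used as electron donors.
    acceptor_electrons_vs_PCE
        Electrons accepted per mole to form this species from PCE
        (2 per chlorine removed: PCE 0, TCE 2, cis-DCE 4, VC 6, ethene 8);
        methane carries 8 as the CO2-reduction product. ``None`` if the
        species does not appear on the acceptor side.
    ethene_series
        True for members of the PCE → ethene dechlorination chain.
    """

    name: str
    molar_mass: float
    henry_dimensionless: float | None = None
    neat_density: float | None = None
    chlorine_count: int = 0
    donor_electrons: int | None = None
    acceptor_electrons_vs_PCE: int | None = None
    ethene_series: bool = False

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ConfigurationError(f"{self.name}: molar_mass must be > 0")
        if self.henry_dimensionless is not None and self.henry_dimensionless <= 0:
            raise ConfigurationError(
                f"{self.name}: henry_dimensionless must be > 0 when present"
            )
        if self.chlorine_count < 0:
            raise ConfigurationError(f"{self.name}: chlorine_count must be >= 0")
        if self.ethene_series:
            expected = 2 * (4 - self.chlorine_count)
            if self.acceptor_electrons_vs_PCE != expected:
                raise ConfigurationError(
                    f"{self.name}: acceptor_electrons_vs_PCE "
                    f"{self.acceptor_electrons_vs_PCE} inconsistent with "
                    f"2 x (4 - chlorine_count) = {expected}"
                )

    @property
    def is_volatile(self) -> bool:
        return self.henry_dimensionless is not None


class CompoundRegistry(Mapping[str, Compound]):
    """Immutable name → :class:`Compound` mapping with validation on load."""

    def __init__(self, compounds: Iterable[Compound]):
        self._compounds = {c.name: c for c in compounds}

    def __getitem__(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise KeyError(
                f"unknown compound {name!r}; registered: "
                f"{sorted(self._compounds)}"
            ) from None

    def __iter__(self):
        return iter(self._compounds)

    def __len__(self) -> int:
        return len(self._compounds)

    def resolve(self, compound: "str | Compound") -> Compound:
        if isinstance(compound, Compound):
            return compound
        return self[compound]

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "CompoundRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw["compounds"])

    @classmethod
    def _from_mapping(cls, mapping: Mapping[str, Mapping]) -> "CompoundRegistry":
        return cls(Compound(name=name, **entry) for name, entry in mapping.items())


def default_registry() -> CompoundRegistry:
    """Registry shipped with the package (constants at 23 °C)."""
    ref = importlib.resources.files("dechlor.data").joinpath("compounds.yaml")
    raw = yaml.safe_load(ref.read_text())
    return CompoundRegistry._from_mapping(raw["compounds"])


@dataclass(frozen=True)
class BottleConfig:
    """Sealed serum-bottle geometry and sorbent load.

    Defaults mirror the standard setup: 160 mL bottle, 100 mL liquid medium,
    60 mL headspace, 23 °C, 0.2 g sorbent (2 g/L). Controls without material
    and sand controls use ``sorbent_mass = 0`` (sand) or the ``sorbent_name``
    ``"sand"`` with a zero partition coefficient.
    """

    total_volume: float = 0.160  # L
    liquid_volume: float = 0.100  # L
    temperature: float = 23.0  # °C
    sorbent_mass: float = 0.2  # g
    sorbent_name: str = "none"

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0 or self.total_volume <= self.liquid_volume:
            raise ConfigurationError(
                "need 0 < liquid_volume < total_volume "
                f"(got {self.liquid_volume} / {self.total_volume} L)"
            )
        if self.sorbent_mass < 0:
            raise ConfigurationError("sorbent_mass must be >= 0")

    @property
    def headspace_volume(self) -> float:
        """L of gas phase (total − liquid)."""
        return self.total_volume - self.liquid_volume

    def with_sorbent(self, name: str, mass: float) -> "BottleConfig":
        return replace(self, sorbent_name=name, sorbent_mass=mass)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BottleConfig":
        d = dict(d)
        d.pop("headspace_volume", None)  # derived
        return cls(**d)


class DoseMethod(str, Enum):
    neat_liquid = "neat_liquid"
    syrup = "syrup"
    gas = "gas"


@dataclass(frozen=True)
class DoseEvent:
    """One feeding event: ``amount`` μmol of ``compound`` added on ``day``."""

    day: float
    compound: str
    amount: float  # μmol
    how: DoseMethod = DoseMethod.neat_liquid

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.day < 0:
            raise ValueError("dose day must be >= 0")


class PhaseBasis(str, Enum):
    """What a series' values represent."""

    gas_conc = "gas_conc"  # headspace concentration, μmol/L
    two_phase_mass = "two_phase_mass"  # aqueous + gas mass, μmol/bottle
    three_phase_mass = "three_phase_mass"  # aqueous + gas + sorbed, μmol/bottle


@dataclass(frozen=True)
class MassSeries:
    """Per-bottle, per-compound trajectory.

    ``points`` are ``(day, value, censored)`` triples with strictly increasing
    days. Below-detection observations are stored with value 0 and the
    censored flag set, matching the convention of plotting non-detects as 0.
    """

    bottle_id: str
    compound: str
    points: tuple[tuple[float, float, bool], ...]
    phase_basis: PhaseBasis = PhaseBasis.gas_conc

    def __post_init__(self) -> None:
        days = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"{self.bottle_id}/{self.compound}: days must be strictly increasing"
            )
        for day, value, censored in self.points:
            if censored and value != 0.0:
                raise ValueError(
                    f"{self.bottle_id}/{self.compound}: censored point at day "
                    f"{day} must carry value 0"
                )

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.points)

    @property
    def censored(self) -> tuple[bool, ...]:
        return tuple(p[2] for p in self.points)


# ---------------------------------------------------------------------------
# Dosing arithmetic
# ---------------------------------------------------------------------------

def neat_liquid_to_micromoles(volume_uL: float, compound: Compound) -> float:
    """μmol delivered by ``volume_uL`` μL of a neat liquid.

    ``volume_uL × ρ [g/mL] × 1000 / M [g/mol]``; e.g. 10 μL of neat PCE
    (ρ 1.618 g/mL, M 165.83 g/mol) is 97.6 μmol.
    """
    if volume_uL <= 0:
        raise ValueError("volume must be > 0 μL")
    if compound.neat_density is None:
        raise ConfigurationError(
            f"{compound.name} has no neat_density; cannot dose as neat liquid"
        )
    return volume_uL * compound.neat_density * 1000.0 / compound.molar_mass


def syrup_dose_to_micromoles(
    volume_mL: float,
    mass_fraction: float,
    density: float,
    molar_mass: float,
) -> float:
    """μmol of solute delivered by a w/w syrup dose.

    ``volume [mL] × ρ [g/mL] × w × 1e6 / M [g/mol]``; e.g. 0.15 mL of 60% w/w
    sodium-lactate syrup (ρ 1.33 g/mL, M 112.06 g/mol) is 1068 μmol.
    """
    if volume_mL <= 0 or density <= 0 or molar_mass <= 0:
        raise ValueError("volume, density and molar mass must be > 0")
    if not 0 < mass_fraction <= 1:
        raise ValueError("mass_fraction must be in (0, 1]")
    return volume_mL * density * mass_fraction * 1e6 / molar_mass


# ---------------------------------------------------------------------------
# Time-series CSV I/O
# ---------------------------------------------------------------------------

_TS_HEADER = ["bottle", "day", "compound", "value", "censored"]
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def read_timeseries(
    path: "str | Path",
    registry: CompoundRegistry | None = None,
    phase_basis: PhaseBasis = PhaseBasis.gas_conc,
) -> list[MassSeries]:
    """Load a long-format time-series CSV into :class:`MassSeries` objects.

    Expected header: ``bottle,day,compound,value,censored``. Rows naming a
    compound absent from ``registry`` and malformed rows raise
    :class:`ParseError` carrying the offending line number. Censored rows
    load with value 0 regardless of the stored value column.
    """
    registry = registry or default_registry()
    groups: dict[tuple[str, str], list[tuple[float, float, bool]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _TS_HEADER:
            raise ParseError(
                f"{path}:1: expected header {','.join(_TS_HEADER)}, "
                f"got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            bottle, day_s, compound, value_s, cens_s = (c.strip() for c in row)
            if compound not in registry:
                raise ParseError(
                    f"{path}:{lineno}: unregistered compound {compound!r}"
                )
            try:
                day = float(day_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad day {day_s!r}") from None
            cens_l = cens_s.lower()
            if cens_l in _TRUE:
                censored = True
            elif cens_l in _FALSE:
                censored = False
            else:
                raise ParseError(f"{path}:{lineno}: bad censored flag {cens_s!r}")
            if censored:
                value = 0.0
            else:
                try:
                    value = float(value_s)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: bad value {value_s!r}"
                    ) from None
            groups.setdefault((bottle, compound), []).append((day, value, censored))
    out = []
    for (bottle, compound), pts in groups.items():
        out.append(
            MassSeries(
                bottle_id=bottle,
                compound=compound,
                points=tuple(pts),
                phase_basis=phase_basis,
            )
        )
    return out


def write_timeseries(series: Sequence[MassSeries], path: "str | Path") -> None:
    """Write :class:`MassSeries` to the long-format CSV dialect.

    Values are rendered with 17 significant digits so read→write→read
    round-trips are lossless at double precision.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TS_HEADER)
        for s in series:
            for day, value, censored in s.points:
                writer.writerow(
                    [
                        s.bottle_id,
                        format(day, ".17g"),
                        s.compound,
                        format(value, ".17g"),
                        "true" if censored else "false",
                    ]
                )
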