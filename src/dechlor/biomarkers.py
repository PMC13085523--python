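"""qPCR biomarker normalization to copies per bottle, with quantification limits.

Suspended-fraction measurements arrive as copies/mL of liquid and scale by
the bottle's liquid volume; attached-fraction measurements arrive as
copies/g of sorbent and scale by the total sorbent mass. Results below the
per-bottle quantification limit (1.5e5 copies/bottle suspended, 3.0e3
attached) are censored at the limit. Growth is summarized as log10 fold
change (orders of magnitude), with censored endpoints degraded to one-sided
bounds rather than silently used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .core import BottleConfig

__all__ = [
    "Fraction",
    "BiomarkerMeasurement",
    "CopiesPerBottle",
    "FoldChange",
    "LOQ_PER_BOTTLE",
    "copies_per_bottle",
    "log10_fold_change",
    "read_qpcr",
    "copies_table",
]


class Fraction(str, Enum):
    suspended = "suspended"  # raw unit: copies/mL liquid
    attached = "attached"  # raw unit: copies/g sorbent


#: Per-bottle quantification limits (copies/bottle).
LOQ_PER_BOTTLE = {Fraction.suspended: 1.5e5, Fraction.attached: 3.0e3}


@dataclass(frozen=True)
class BiomarkerMeasurement:
    bottle_id: str
    day: float
    gene: str  # e.g. Dhc16S, vcrA, tceA, Dsf-pceA, mcrA
    fraction: Fraction
    raw_value: float  # copies/mL (suspended) or copies/g (attached)
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.raw_value < 0:
            raise ValueError("raw_value must be >= 0")


@dataclass(frozen=True)
class CopiesPerBottle:
    bottle_id: str
    day: float
    gene: str
    fraction: Fraction
    copies: float  # copies/bottle; equals the LOQ when censored
    censored: bool


def copies_per_bottle(
    m: BiomarkerMeasurement, bottle: BottleConfig
) -> CopiesPerBottle:
    """Scale a raw qPCR result to whole-bottle copies, applying the LOQ.

    Suspended: copies/mL × liquid volume in mL. Attached: copies/g × total
    sorbent mass in g (normalization to the whole sorbent load). Values
    below the fraction's per-bottle quantification limit — or already
    flagged below-LOQ upstream — are reported at the limit with the
    censored flag set; censoring is idempotent.
    """
    if m.fraction is Fraction.suspended:
        copies = m.raw_value * bottle.liquid_volume * 1000.0
    else:
        if bottle.sorbent_mass <= 0:
            raise ValueError(
                f"{m.bottle_id}: attached-fraction measurement but bottle has "
                "no sorbent"
            )
        copies = m.raw_value * bottle.sorbent_mass
    loq = LOQ_PER_BOTTLE[m.fraction]
    if m.below_loq or copies < loq:
        return CopiesPerBottle(m.bottle_id, m.day, m.gene, m.fraction, loq, True)
    return CopiesPerBottle(m.bottle_id, m.day, m.gene, m.fraction, copies, False)


class BoundKind(str, Enum):
    exact = "exact"
    at_least = "at_least"  # censored initial: true change >= value
    at_most = "at_most"  # censored final: true change <= value


@dataclass(frozen=True)
class FoldChange:
    """log10 fold change in copies/bottle (orders of magnitude)."""

    value: float
    bound: BoundKind

    def __str__(self) -> str:
        prefix = {BoundKind.exact: "", BoundKind.at_least: ">= ", BoundKind.at_most: "<= "}
        return f"{prefix[self.bound]}{self.value:.2f} orders of magnitude"


def log10_fold_change(initial: CopiesPerBottle, final: CopiesPerBottle) -> FoldChange:
    """Orders-of-magnitude change between two copies/bottle values.

    A censored initial value (at its LOQ) makes the true change at least the
    computed value; a censored final value makes it at most the computed
    value. Both censored is rejected — no information about direction.
    """
    if initial.copies <= 0 or final.copies <= 0:
        raise ValueError("fold change requires positive copy numbers")
    value = math.log10(final.copies / initial.copies)
    if initial.censored and final.censored:
        raise ValueError("both endpoints censored; fold change undefined")
    if initial.censored:
        return FoldChange(value, BoundKind.at_least)
    if final.censored:
        return FoldChange(value, BoundKind.at_most)
    return FoldChange(value, BoundKind.exact)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_qpcr(path: "str | Path") -> list[BiomarkerMeasurement]:
    """Load a qPCR CSV: bottle, day, gene, fraction, value, below_loq."""
    df = pd.read_csv(path)
    required = ["bottle", "day", "gene", "fraction", "value", "below_loq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            BiomarkerMeasurement(
                bottle_id=str(row["bottle"]),
                day=float(row["day"]),
                gene=str(row["gene"]),
                fraction=Fraction(str(row["fraction"])),
                raw_value=float(row["value"]),
                below_loq=bool(row["below_loq"]),
            )
        )
    return out


def copies_table(
    measurements: "list[BiomarkerMeasurement]", bottle: BottleConfig
) -> pd.DataFrame:
    """Normalize a batch of measurements; long-format copies/bottle table."""
    rows = []
    for m in measurements:
        c = copies_per_bottle(m, bottle)
        rows.append(
            {
                "bottle": c.bottle_id,
                "day": c.day,
                "gene": c.gene,
                "fraction": c.fraction.value,
                "copies_per_bottle": c.copies,
                "censored": c.censored,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bottle", "day", "gene", "fraction", "copies_per_bottle", "censored"],
    )
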