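"""Experimental design: fractions, preparation methods and sample descriptors.

The experiment compares a flow-sorted, GFP-positive midbody-remnant fraction
(MBR+) against three control fractions — size-matched GFP-negative particles
(MBR−), a centrifugation-enriched fraction (MBRE) and the total cell lysate
(Total) — each prepared for mass spectrometry by two independent routes
(in-gel digestion and eFASP in-solution digestion).  A *condition* is a
fraction × preparation pair; the two preparations are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Fraction(str, Enum):
    """The four analysed particle fractions."""

    MBR_PLUS = "MBR_plus"
    MBR_MINUS = "MBR_minus"
    MBRE = "MBRE"
    TOTAL = "Total"


class Prep(str, Enum):
    """Sample-preparation route for mass spectrometry."""

    GEL = "gel"
    EFASP = "eFASP"


#: Control fractions that MBR+ is compared against.
CONTROL_FRACTIONS = (Fraction.MBR_MINUS, Fraction.MBRE, Fraction.TOTAL)


@dataclass(frozen=True)
class SampleDescriptor:
    """Binds one intensity column to its fraction, preparation and replicate."""

    sample_id: str
    fraction: Fraction
    prep: Prep
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def condition(self) -> tuple[Fraction, Prep]:
        return (self.fraction, self.prep)


def validate_design(design: list[SampleDescriptor]) -> None:
    """Check (fraction, prep, replicate) uniqueness and sample_id uniqueness."""
    keys = [(d.fraction, d.prep, d.replicate) for d in design]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (fraction, prep, replicate) in design")
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")


def _block(prefix: str, fraction: Fraction, prep: Prep, n: int) -> list[SampleDescriptor]:
    return [
        SampleDescriptor(f"{prefix}_{fraction.value}_{r}", fraction, prep, r)
        for r in range(1, n + 1)
    ]


def full_design() -> list[SampleDescriptor]:
    """The study's replicate layout across both preparations.

    In-gel digestion: five independent preparations per fraction, plus one
    experimental replicate of the MBR+/MBR− pair run as an internal control
    (treated here as an ordinary sixth replicate of its condition).  eFASP:
    three replicates for Total and MBRE, two for MBR+ and MBR−.
    """
    design: list[SampleDescriptor] = []
    design += _block("gel", Fraction.MBR_PLUS, Prep.GEL, 6)
    design += _block("gel", Fraction.MBR_MINUS, Prep.GEL, 6)
    design += _block("gel", Fraction.MBRE, Prep.GEL, 5)
    design += _block("gel", Fraction.TOTAL, Prep.GEL, 5)
    design += _block("efasp", Fraction.MBR_PLUS, Prep.EFASP, 2)
    design += _block("efasp", Fraction.MBR_MINUS, Prep.EFASP, 2)
    design += _block("efasp", Fraction.MBRE, Prep.EFASP, 3)
    design += _block("efasp", Fraction.TOTAL, Prep.EFASP, 3)
    return design


def gel_design(replicates: int = 5) -> list[SampleDescriptor]:
    """A single-preparation layout: all four fractions at equal replication."""
    design: list[SampleDescriptor] = []
    for fraction in Fraction:
        design += _block("gel", fraction, Prep.GEL, replicates)
    return design


def comparisons_for(design: list[SampleDescriptor]) -> list[tuple[Fraction, Prep]]:
    """Enumerate the MBR+ vs control comparisons the design supports.

    One comparison per (control fraction, prep) pair for which the design
    contains both MBR+ samples and control samples of that prep.
    """
    conditions = {(d.fraction, d.prep) for d in design}
    out: list[tuple[Fraction, Prep]] = []
    for prep in Prep:
        if (Fraction.MBR_PLUS, prep) not in conditions:
            continue
        for control in CONTROL_FRACTIONS:
            if (control, prep) in conditions:
                out.append((control, prep))
    return out


def comparison_label(control: Fraction, prep: Prep) -> str:
    return f"MBR_plus_vs_{control.value}_{prep.value}"
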