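"""Lipid shorthand nomenclature for phosphatidylcholines and sphingomyelins.

Three label dialects coexist in cross-platform PC data and are parsed into a
single :class:`LipidEntity` representation:

* **kit sum level** — ``PC aa C36:2`` / ``PC ae C36:2``: the Biocrates-style
  annotation of a bulk measure carrying only total side-chain carbons ``x``
  and double bonds ``y`` (``aa`` = diacyl assumption, ``ae`` = acyl-alkyl).
* **species level** — ``PC 36:2``, ``PC O-33:1``, ``SM 36:0``,
  ``[13C1]SM 36:0``: bond type resolved, side chains not.
* **fatty acid level** — ``PC 18:0_18:2``, ``PC O-17:0_16:1``: both side
  chains resolved by carbons:double-bonds, sn-positions still unknown.

Only PC (with at most one alkyl chain) and SM (optionally as the first
13C isotopologue) are in scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple


class ParseError(ValueError):
    """Raised when a lipid label does not belong to any supported dialect."""


class Bond(str, Enum):
    ACYL = "acyl"
    ALKYL = "alkyl"


class Resolution(str, Enum):
    SUM = "sum_level"
    SPECIES = "species_level"
    FATTY_ACID = "fatty_acid_level"


# A species-level "PC x:y" with fewer total carbons than this is rejected as
# an incomplete label: it cannot be told apart from a lone fatty-acid token
# (e.g. "PC 16:0" lacking its second chain).  Every label in the kit universe
# has x >= 24.
MIN_SPECIES_CARBONS = 20


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """One side chain: carbon count, double-bond count, and bond type."""

    carbons: int
    double_bonds: int
    bond: Bond = Bond.ACYL

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(
                f"chain double bonds must be >= 0, got {self.double_bonds}"
            )

    @property
    def label(self) -> str:
        prefix = "O-" if self.bond is Bond.ALKYL else ""
        return f"{prefix}{self.carbons}:{self.double_bonds}"


def canonical_chain_order(chains: Tuple[FattyAcyl, ...]) -> Tuple[FattyAcyl, ...]:
    """Order an unordered chain pair deterministically.

    The alkyl chain (if any) comes first; otherwise chains are sorted
    ascending by (carbons, double_bonds).
    """
    return tuple(
        sorted(
            chains,
            key=lambda c: (c.bond is not Bond.ALKYL, c.carbons, c.double_bonds),
        )
    )


@dataclass(frozen=True)
class LipidEntity:
    """A PC or SM at sum, species, or fatty-acid resolution."""

    lipid_class: str  # "PC" | "SM"
    resolution: Resolution
    total_carbons: int
    total_double_bonds: int
    chains: Tuple[FattyAcyl, ...] = ()
    ether: bool = False
    isotope_label: Optional[str] = None  # None | "13C1"
    kit_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lipid_class not in ("PC", "SM"):
            raise ValueError(f"unsupported lipid class {self.lipid_class!r}")
        if self.total_carbons < 1 or self.total_double_bonds < 0:
            raise ValueError(
                f"invalid totals {self.total_carbons}:{self.total_double_bonds}"
            )
        if self.isotope_label not in (None, "13C1"):
            raise ValueError(f"unsupported isotope label {self.isotope_label!r}")
        if self.isotope_label == "13C1" and self.lipid_class != "SM":
            raise ValueError("13C1 isotopologues are modeled for SM only")
        if self.chains:
            if len(self.chains) != 2:
                raise ValueError("fatty-acid-level entities carry exactly 2 chains")
            n_alkyl = sum(c.bond is Bond.ALKYL for c in self.chains)
            if n_alkyl > 1:
                raise ValueError("at most one alkyl chain per lipid")
            if (n_alkyl == 1) != self.ether:
                raise ValueError("ether flag inconsistent with chain bond types")
            if sum(c.carbons for c in self.chains) != self.total_carbons:
                raise ValueError("chain carbons do not sum to total carbons")
            if sum(c.double_bonds for c in self.chains) != self.total_double_bonds:
                raise ValueError("chain double bonds do not sum to total")
            object.__setattr__(self, "chains", canonical_chain_order(self.chains))

    @property
    def label(self) -> str:
        """Canonical label in the entity's own resolution."""
        if self.resolution is Resolution.SUM:
            return format_lipid_name(self, "kit")
        if self.resolution is Resolution.FATTY_ACID:
            return format_lipid_name(self, "fatty_acid")
        return format_lipid_name(self, "species")


# Typographic hyphen/minus variants that occur in extracted text.
_HYPHENS = {"‐": "-", "‑": "-", "‒": "-", "–": "-",
            "—": "-", "−": "-"}

_KIT_RE = re.compile(r"^PC\s+(aa|ae)\s+C\s*(\d+)\s*:\s*(\d+)$")
_SPECIES_PC_RE = re.compile(r"^PC\s+(O-)?\s*(\d+)\s*:\s*(\d+)$")
_SPECIES_SM_RE = re.compile(r"^(\[13C1\])?\s*SM\s+(\d+)\s*:\s*(\d+)$")
_FA_RE = re.compile(
    r"^PC\s+(O-)?\s*(\d+)\s*:\s*(\d+)\s*_\s*(\d+)\s*:\s*(\d+)$"
)


def _normalize(label: str) -> str:
    out = label
    for variant, ascii_hyphen in _HYPHENS.items():
        out = out.replace(variant, ascii_hyphen)
    return " ".join(out.split())


def parse_lipid_name(label: str) -> LipidEntity:
    """Parse a lipid label from any supported dialect into a LipidEntity.

    Raises :class:`ParseError` naming the offending token for labels outside
    the dialects (including incomplete species such as ``PC 16:0``).
    """
    if not isinstance(label, str):
        raise ParseError(f"expected text label, got {type(label).__name__}")
    text = _normalize(label)

    m = _KIT_RE.match(text)
    if m:
        annotation, x, y = m.group(1), int(m.group(2)), int(m.group(3))
        return LipidEntity(
            lipid_class="PC",
            resolution=Resolution.SUM,
            total_carbons=x,
            total_double_bonds=y,
            ether=(annotation == "ae"),
            kit_annotation=f"PC {annotation} C{x}:{y}",
        )

    m = _FA_RE.match(text)
    if m:
        ether = m.group(1) is not None
        c1 = FattyAcyl(int(m.group(2)), int(m.group(3)),
                       Bond.ALKYL if ether else Bond.ACYL)
        c2 = FattyAcyl(int(m.group(4)), int(m.group(5)), Bond.ACYL)
        return LipidEntity(
            lipid_class="PC",
            resolution=Resolution.FATTY_ACID,
            total_carbons=c1.carbons + c2.carbons,
            total_double_bonds=c1.double_bonds + c2.double_bonds,
            chains=(c1, c2),
            ether=ether,
        )

    m = _SPECIES_PC_RE.match(text)
    if m:
        ether, x, y = m.group(1) is not None, int(m.group(2)), int(m.group(3))
        if x < MIN_SPECIES_CARBONS:
            raise ParseError(
                f"incomplete species-level label {label!r}: total carbons {x} "
                f"look like a single fatty-acid token (need >= "
                f"{MIN_SPECIES_CARBONS} for two side chains)"
            )
        return LipidEntity(
            lipid_class="PC",
            resolution=Resolution.SPECIES,
            total_carbons=x,
            total_double_bonds=y,
            ether=ether,
        )

    m = _SPECIES_SM_RE.match(text)
    if m:
        isotope = "13C1" if m.group(1) else None
        x, y = int(m.group(2)), int(m.group(3))
        if x < MIN_SPECIES_CARBONS:
            raise ParseError(
                f"incomplete species-level label {label!r}: total carbons {x} "
                f"too small for a sphingomyelin"
            )
        return LipidEntity(
            lipid_class="SM",
            resolution=Resolution.SPECIES,
            total_carbons=x,
            total_double_bonds=y,
            isotope_label=isotope,
        )

    raise ParseError(f"unrecognized lipid label {label!r}")


def format_lipid_name(entity: LipidEntity, dialect: str) -> str:
    """Format an entity in the requested dialect (kit, species, fatty_acid).

    Formatting is the inverse of parsing on canonical labels.  Requesting a
    finer dialect than the entity's resolution raises ValueError.
    """
    x, y = entity.total_carbons, entity.total_double_bonds
    if dialect == "kit":
        if entity.lipid_class != "PC":
            raise ValueError("kit dialect exists for PC only")
        annotation = "ae" if entity.ether else "aa"
        return f"PC {annotation} C{x}:{y}"
    if dialect == "species":
        if entity.lipid_class == "SM":
            prefix = "[13C1]" if entity.isotope_label == "13C1" else ""
            return f"{prefix}SM {x}:{y}"
        return f"PC O-{x}:{y}" if entity.ether else f"PC {x}:{y}"
    if dialect == "fatty_acid":
        if not entity.chains:
            raise ValueError(
                f"cannot format {entity.resolution.value} entity at "
                "fatty-acid resolution: side chains unknown"
            )
        chains = canonical_chain_order(entity.chains)
        first, second = chains
        prefix = "O-" if first.bond is Bond.ALKYL else ""
        return (
            f"PC {prefix}{first.carbons}:{first.double_bonds}"
            f"_{second.carbons}:{second.double_bonds}"
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def canonical_label(label: str) -> str:
    """Canonical form of any supported label (chain order normalized)."""
    return parse_lipid_name(label).label


def kit_to_species(entity: LipidEntity) -> LipidEntity:
    """Map a kit sum annotation to the species it names.

    ``PC aa Cx:y`` denotes the diacyl species ``PC x:y``; ``PC ae Cx:y``
    denotes the ether species ``PC O-x:y`` (the kit labeling convention:
    even-x measures are annotated aa, odd-x measures ae with x+1).
    """
    if entity.resolution is not Resolution.SUM:
        raise ValueError("kit_to_species expects a sum-level entity")
    return LipidEntity(
        lipid_class="PC",
        resolution=Resolution.SPECIES,
        total_carbons=entity.total_carbons,
        total_double_bonds=entity.total_double_bonds,
        ether=entity.ether,
    )
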