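"""Exact-mass algebra for PC/SM species.

Neutral sum formulas follow standard glycerophosphocholine and sphingomyelin
chemistry:

* diacyl PC x:y      -> C(x+8)  H(2x-2y+16) N O8 P
* acyl-alkyl PC x:y  -> C(x+8)  H(2x-2y+18) N O7 P   (ether bond: +2H -O)
* SM x:y             -> C(x+5)  H(2x-2y+13) N2 O6 P

The [13C1] isotopologue replaces one 12C by 13C.  Masses use the five printed
monoisotopic atom weights plus the standard w(P); the nominal mass (the
parenthesized value in kit documentation) is the floor of the monoisotopic
neutral mass.

Isobar rules give the constant composition change between a PC x:y (or
PC O-x:y) anchor and each species that falls on the same nominal mass within
the instrument resolution; ``mass_delta`` returns the exact mass of that
change, independent of x and y.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Mapping

from .nomenclature import LipidEntity, Resolution

#: Monoisotopic atom weights in Da.  H/C/13C/O/N are the printed reference
#: values; P is the standard monoisotopic value (needed to reproduce the
#: printed nominal neutral masses).
MONOISOTOPIC_WEIGHTS: Dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "13C": 13.003355,
    "O": 15.994915,
    "N": 14.003074,
    "P": 30.973762,
}


class SumFormula(Counter):
    """Element -> signed integer count; 13C is a distinct element entry.

    Subtraction of two formulas yields a signed delta formula, which is how
    isobar mass deltas are derived.
    """

    def __sub__(self, other: "SumFormula") -> "SumFormula":  # type: ignore[override]
        out = SumFormula(self)
        for el, n in other.items():
            out[el] -= n
        return SumFormula({el: n for el, n in out.items() if n != 0})

    def __add__(self, other: "SumFormula") -> "SumFormula":  # type: ignore[override]
        out = SumFormula(self)
        for el, n in other.items():
            out[el] += n
        return SumFormula({el: n for el, n in out.items() if n != 0})


def sum_formula(entity: LipidEntity) -> SumFormula:
    """Neutral sum formula of a species- or fatty-acid-level PC/SM."""
    if entity.resolution is Resolution.SUM:
        raise ValueError(
            "sum-level measures have no single sum formula; map the kit "
            "annotation to a species first (kit_to_species)"
        )
    x, y = entity.total_carbons, entity.total_double_bonds
    if entity.lipid_class == "PC":
        h = 2 * x - 2 * y + (18 if entity.ether else 16)
        formula = SumFormula(
            {"C": x + 8, "H": h, "N": 1, "O": 7 if entity.ether else 8, "P": 1}
        )
    else:  # SM
        h = 2 * x - 2 * y + 13
        formula = SumFormula({"C": x + 5, "H": h, "N": 2, "O": 6, "P": 1})
    if formula["H"] < 0:
        raise ValueError(
            f"unphysical composition {entity.label}: negative hydrogen count"
        )
    if entity.isotope_label == "13C1":
        formula["C"] -= 1
        formula["13C"] += 1
    return formula


def monoisotopic_mass(
    formula: Mapping[str, int],
    weights: Mapping[str, float] = MONOISOTOPIC_WEIGHTS,
) -> float:
    """Exact weighted sum of atom counts, in Da."""
    mass = 0.0
    for element, count in formula.items():
        if element not in weights:
            raise KeyError(f"no monoisotopic weight for element {element!r}")
        mass += weights[element] * count
    return mass


def nominal_mass(entity: LipidEntity) -> int:
    """Floor of the monoisotopic neutral mass (the printed parenthetical)."""
    return math.floor(monoisotopic_mass(sum_formula(entity)))


#: Delta sum formulas of the eight isobar rules (relative to the anchor).
#: Upper block: anchors PC x:y.  Lower block: anchors PC O-x:y.
ISOBAR_DELTA_FORMULAS: Dict[str, SumFormula] = {
    # from PC x:y
    "pc_plus1_plus7": SumFormula({"C": 1, "H": -12}),        # PC x+1:y+7
    "pcO_plus1": SumFormula({"C": 1, "H": 4, "O": -1}),      # PC O-x+1:y
    "pcO_plus2_plus7": SumFormula({"C": 2, "H": -8, "O": -1}),  # PC O-x+2:y+7
    "sm13C_plus4": SumFormula({"13C": 1, "H": 5, "N": 1, "O": -2}),  # [13C1]SM x+4:y
    # from PC O-x:y
    "pcO_plus1_plus7": SumFormula({"C": 1, "H": -12}),       # PC O-x+1:y+7
    "pc_minus1": SumFormula({"C": -1, "H": -4, "O": 1}),     # PC x-1:y
    "pc_plus7": SumFormula({"O": 1, "H": -16}),              # PC x:y+7
    "sm13C_plus3": SumFormula({"13C": 1, "C": -1, "H": 1, "N": 1, "O": -1}),
}


def mass_delta(rule: str, weights: Mapping[str, float] = MONOISOTOPIC_WEIGHTS) -> float:
    """Signed mass (Da) of an isobar rule's composition change."""
    if rule not in ISOBAR_DELTA_FORMULAS:
        raise KeyError(
            f"unknown isobar rule {rule!r}; known: "
            f"{sorted(ISOBAR_DELTA_FORMULAS)}"
        )
    return monoisotopic_mass(ISOBAR_DELTA_FORMULAS[rule], weights)
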