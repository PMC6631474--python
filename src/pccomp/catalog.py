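"""Enumeration of isobaric constituents of kit-style PC sum measures.

For each bulk PC measure (``PC aa Cx:y`` / ``PC ae Cx:y``) the theoretical
catalog contains every fatty-acid-level species that falls on the same
nominal mass: all chain splits of the anchor species itself plus the isobar
series (PC x+1:y+7, PC O-x+1:y, PC O-x+2:y+7 for a diacyl anchor; the
analogous set for an ether anchor), and the first-isotope sphingomyelin peak
when the corresponding SM is not itself quantified (and hence not isotope-
corrected away) by the kit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .mass import mass_delta, monoisotopic_mass, sum_formula
from .nomenclature import (
    Bond,
    FattyAcyl,
    LipidEntity,
    Resolution,
    kit_to_species,
    parse_lipid_name,
)

REMAINDER_TAG = "R"


def _chemical_max_double_bonds(carbons: int) -> int:
    # carbon chain with a terminal carboxyl/ether carbon: at most one C=C per
    # two chain carbons
    return max(0, (carbons - 1) // 2)


@dataclass(frozen=True)
class EnumerationConstraints:
    """Bounds applied to each side chain during enumeration.

    ``max_chain_carbons=None`` means "total minus min_chain_carbons", i.e. the
    partner chain must still be at least the minimum.  The double-bond bound
    may be an integer or the rule ``"chemical"`` (<= floor((carbons-1)/2)).
    """

    min_chain_carbons: int = 2
    max_chain_carbons: Optional[int] = None
    max_double_bonds_per_chain: Union[int, str] = "chemical"
    include_ether: bool = True
    include_sm_isotopologue: bool = True

    def __post_init__(self) -> None:
        if self.min_chain_carbons < 1:
            raise ValueError("min_chain_carbons must be >= 1")
        if (
            self.max_chain_carbons is not None
            and self.max_chain_carbons < self.min_chain_carbons
        ):
            raise ValueError("max_chain_carbons < min_chain_carbons")
        if isinstance(self.max_double_bonds_per_chain, str):
            if self.max_double_bonds_per_chain != "chemical":
                raise ValueError(
                    "max_double_bonds_per_chain must be an int or 'chemical'"
                )
        elif self.max_double_bonds_per_chain < 0:
            raise ValueError("max_double_bonds_per_chain must be >= 0")

    def chain_bounds(self, total_carbons: int) -> Tuple[int, int]:
        hi = (
            total_carbons - self.min_chain_carbons
            if self.max_chain_carbons is None
            else self.max_chain_carbons
        )
        return self.min_chain_carbons, hi

    def max_db(self, carbons: int) -> int:
        if self.max_double_bonds_per_chain == "chemical":
            return _chemical_max_double_bonds(carbons)
        return int(self.max_double_bonds_per_chain)


def enumerate_chain_pairs(
    x: int,
    y: int,
    constraints: EnumerationConstraints = EnumerationConstraints(),
    ether: bool = False,
) -> Set[Tuple[FattyAcyl, FattyAcyl]]:
    """All chain splits {(x1,y1),(x2,y2)} with x1+x2=x and y1+y2=y.

    For diacyl species the two chains are interchangeable and symmetric
    splits are deduplicated.  For ether species exactly one chain is alkyl;
    the alkyl chain is distinguishable, so (alkyl a:b, acyl c:d) and
    (alkyl c:d, acyl a:b) are distinct species.
    """
    lo, hi = constraints.chain_bounds(x)
    pairs: Set[Tuple[FattyAcyl, FattyAcyl]] = set()
    for x1 in range(lo, hi + 1):
        x2 = x - x1
        if not (lo <= x2 <= hi):
            continue
        if not ether and x1 > x2:
            continue  # unordered diacyl pair: keep x1 <= x2
        for y1 in range(0, y + 1):
            y2 = y - y1
            if y1 > constraints.max_db(x1) or y2 > constraints.max_db(x2):
                continue
            if not ether and x1 == x2 and y1 > y2:
                continue  # same carbons: keep y1 <= y2
            c1 = FattyAcyl(x1, y1, Bond.ALKYL if ether else Bond.ACYL)
            c2 = FattyAcyl(x2, y2, Bond.ACYL)
            pairs.add((c1, c2))
    return pairs


def _species(x: int, y: int, ether: bool) -> Optional[LipidEntity]:
    """Species-level PC entity, or None if implied counts are unphysical."""
    if x < 1 or y < 0:
        return None
    h = 2 * x - 2 * y + (18 if ether else 16)
    if h < 0:
        return None
    return LipidEntity(
        lipid_class="PC",
        resolution=Resolution.SPECIES,
        total_carbons=x,
        total_double_bonds=y,
        ether=ether,
    )


def _sm(x: int, y: int, isotope: Optional[str] = None) -> Optional[LipidEntity]:
    if x < 1 or y < 0 or 2 * x - 2 * y + 13 < 0:
        return None
    return LipidEntity(
        lipid_class="SM",
        resolution=Resolution.SPECIES,
        total_carbons=x,
        total_double_bonds=y,
        isotope_label=isotope,
    )


def _normalize_sm_set(kit_quantified_sms: Iterable) -> FrozenSet[Tuple[int, int]]:
    out = set()
    for sm in kit_quantified_sms:
        entity = parse_lipid_name(sm) if isinstance(sm, str) else sm
        if entity.lipid_class != "SM":
            raise ValueError(f"{entity.label!r} is not an SM species")
        out.add((entity.total_carbons, entity.total_double_bonds))
    return frozenset(out)


def isobaric_series(
    sum_entity: LipidEntity,
    kit_quantified_sms: Iterable = (),
) -> List[Tuple[str, LipidEntity]]:
    """The isobar series of a PC/PC-O anchor as (rule, species) pairs.

    The anchor itself is returned first under the rule name ``anchor``.  The
    [13C1]SM member is included only when the interfering SM was *not*
    quantified by the kit (no isotope correction applied).  Members whose
    implied atom counts would be negative are dropped.
    """
    if sum_entity.lipid_class != "PC":
        raise ValueError("isobar series are defined for PC/PC-O anchors only")
    anchor = (
        kit_to_species(sum_entity)
        if sum_entity.resolution is Resolution.SUM
        else sum_entity
    )
    x, y = anchor.total_carbons, anchor.total_double_bonds
    quantified = _normalize_sm_set(kit_quantified_sms)
    if anchor.ether:
        members = [
            ("anchor", _species(x, y, True)),
            ("pcO_plus1_plus7", _species(x + 1, y + 7, True)),
            ("pc_minus1", _species(x - 1, y, False)),
            ("pc_plus7", _species(x, y + 7, False)),
        ]
        sm_x = x + 3
    else:
        members = [
            ("anchor", _species(x, y, False)),
            ("pc_plus1_plus7", _species(x + 1, y + 7, False)),
            ("pcO_plus1", _species(x + 1, y, True)),
            ("pcO_plus2_plus7", _species(x + 2, y + 7, True)),
        ]
        sm_x = x + 4
    if (sm_x, y) not in quantified:
        rule = "sm13C_plus3" if anchor.ether else "sm13C_plus4"
        members.append((rule, _sm(sm_x, y, isotope="13C1")))
    return [(rule, entity) for rule, entity in members if entity is not None]


@dataclass
class ConstituentCatalog:
    """All theoretical isobaric constituents of one kit PC sum.

    ``theoretical`` holds fatty-acid-level PCs (all chain splits of every
    series member) plus the SM isotopologue where applicable; ``measured``
    is the subset mapped onto available fatty-acid-level analytes.  The
    unmeasured remainder is the aggregate tag ``R``.
    """

    sum_entity: LipidEntity
    theoretical: Tuple[LipidEntity, ...]
    measured: Tuple[LipidEntity, ...] = ()
    origin_rules: Dict[str, str] = field(default_factory=dict)  # label -> rule
    unmeasured_remainder_tag: str = REMAINDER_TAG

    @property
    def sum_label(self) -> str:
        return self.sum_entity.label

    @property
    def theoretical_labels(self) -> Tuple[str, ...]:
        return tuple(e.label for e in self.theoretical)

    @property
    def measured_labels(self) -> Tuple[str, ...]:
        return tuple(e.label for e in self.measured)


def _catalog_for_sum(
    sum_entity: LipidEntity,
    constraints: EnumerationConstraints,
    kit_quantified_sms: Iterable,
) -> ConstituentCatalog:
    theoretical: List[LipidEntity] = []
    origin: Dict[str, str] = {}
    for rule, member in isobaric_series(sum_entity, kit_quantified_sms):
        if member.lipid_class == "SM":
            if constraints.include_sm_isotopologue:
                theoretical.append(member)
                origin[member.label] = rule
            continue
        if member.ether and not constraints.include_ether:
            continue
        for chains in sorted(
            enumerate_chain_pairs(
                member.total_carbons,
                member.total_double_bonds,
                constraints,
                ether=member.ether,
            )
        ):
            entity = LipidEntity(
                lipid_class="PC",
                resolution=Resolution.FATTY_ACID,
                total_carbons=member.total_carbons,
                total_double_bonds=member.total_double_bonds,
                chains=chains,
                ether=member.ether,
            )
            if entity.label not in origin:
                theoretical.append(entity)
                origin[entity.label] = rule
    return ConstituentCatalog(
        sum_entity=sum_entity,
        theoretical=tuple(theoretical),
        origin_rules=origin,
    )


def assemble_constituent_catalog(
    kit_labels: Sequence[str],
    measured_analytes: Sequence[str] = (),
    constraints: EnumerationConstraints = EnumerationConstraints(),
    kit_quantified_sms: Iterable = (),
) -> List[ConstituentCatalog]:
    """One catalog per kit label, with measured analytes mapped onto sums.

    Every measured analyte must map to exactly one sum across the whole
    catalog set (the catalogs partition the measured analytes); an analyte
    mapping to zero or more than one sum raises ValueError naming it.
    """
    catalogs = [
        _catalog_for_sum(parse_lipid_name(lbl), constraints, kit_quantified_sms)
        for lbl in kit_labels
    ]
    if measured_analytes:
        measured_entities = [
            parse_lipid_name(a) if isinstance(a, str) else a
            for a in measured_analytes
        ]
        assignment: Dict[str, List[int]] = {}
        for entity in measured_entities:
            hits = [
                i
                for i, cat in enumerate(catalogs)
                if entity.label in cat.theoretical_labels
            ]
            assignment[entity.label] = hits
        bad_multi = [lbl for lbl, hits in assignment.items() if len(hits) > 1]
        bad_zero = [lbl for lbl, hits in assignment.items() if not hits]
        if bad_multi:
            raise ValueError(
                f"analytes map to more than one PC sum: {sorted(bad_multi)}"
            )
        if bad_zero:
            raise ValueError(
                f"analytes map to no PC sum: {sorted(bad_zero)}"
            )
        for entity in measured_entities:
            i = assignment[entity.label][0]
            catalogs[i].measured = catalogs[i].measured + (entity,)
    return catalogs


def catalog_frame(catalogs: Sequence[ConstituentCatalog]) -> pd.DataFrame:
    """Flat export: one row per (sum, constituent) with rule and mass delta."""
    rows = []
    for cat in catalogs:
        anchor = kit_to_species(cat.sum_entity) if (
            cat.sum_entity.resolution is Resolution.SUM
        ) else cat.sum_entity
        anchor_mass = monoisotopic_mass(sum_formula(anchor))
        measured = set(cat.measured_labels)
        for entity in cat.theoretical:
            rule = cat.origin_rules[entity.label]
            delta = 0.0 if rule == "anchor" else mass_delta(rule)
            rows.append(
                {
                    "sum_label": cat.sum_label,
                    "constituent_label": entity.label,
                    "origin_rule": rule,
                    "mass_delta_da": delta,
                    "constituent_mass_da": anchor_mass + delta,
                    "measured": entity.label in measured,
                }
            )
    return pd.DataFrame(rows)
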