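"""The packaged reference composition table and imputation from PC sums.

The reference table holds, for 38 kit-style PC sums, the characteristic
proportions (mean q with 5%/95% percentile interval and category) of the 69
fatty-acid-level constituents quantified alongside them in a deep
multi-timepoint plasma study, plus the per-sum explained variance (R², %)
of the through-origin concordance fit.  It is the machine-readable product
of the cross-platform composition analysis and the basis for imputing
fatty-acid-level PC concentrations from kit PC sums:

    imputed conc(PC_j) = mean_q(i, j) · conc(PC sum i)
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .cohort import ConcentrationMatrix
from .composition import categorize
from .nomenclature import parse_lipid_name

REQUIRED_COLUMNS = (
    "kit_label",
    "species_label",
    "nominal_mass",
    "constituent_label",
    "r_squared_pct",
    "mean_q",
    "ci5",
    "ci95",
    "category",
    "sum_of_proportions",
)

#: Tolerance for the printed sum-of-proportions vs the sum of printed member
#: proportions.  4-decimal rounding of up to 4 members would allow ~2.5e-4,
#: but one reference row (PC aa C36:3) is internally inconsistent by 1e-3 in
#: the source table; values are stored verbatim, so the check allows it.
_SUMPROP_TOL = 1.5e-3

EXPECTED_N_SUMS = 38
EXPECTED_N_CONSTITUENTS = 69


@dataclass
class ReferenceCompositionTable:
    """Validated reference table; one row per (sum, constituent)."""

    frame: pd.DataFrame
    provenance: str = "packaged"

    @property
    def n_sums(self) -> int:
        return int(self.frame["kit_label"].nunique())

    @property
    def n_constituents(self) -> int:
        return int(len(self.frame))

    @property
    def sum_labels(self) -> List[str]:
        return list(dict.fromkeys(self.frame["kit_label"]))

    def per_sum(self) -> pd.DataFrame:
        """One row per sum with its R² and sum of proportions."""
        return (
            self.frame.groupby("kit_label", sort=False)
            .agg(
                species_label=("species_label", "first"),
                nominal_mass=("nominal_mass", "first"),
                r_squared_pct=("r_squared_pct", "first"),
                sum_of_proportions=("sum_of_proportions", "first"),
                n_constituents=("constituent_label", "size"),
                max_q=("mean_q", "max"),
            )
            .reset_index()
        )

    def proportions(self, kit_label: str) -> Dict[str, float]:
        """Constituent -> mean q for one sum, keyed by canonical labels
        (the table prints chains in source order, e.g. ``PC 18:2_16:1``)."""
        block = self.frame[self.frame["kit_label"] == kit_label]
        return {
            parse_lipid_name(c).label: q
            for c, q in zip(block["constituent_label"], block["mean_q"])
        }


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    for idx, row in df.iterrows():
        where = f"row {idx} ({row['kit_label']} / {row['constituent_label']})"
        parse_lipid_name(row["kit_label"])
        parse_lipid_name(row["species_label"])
        parse_lipid_name(row["constituent_label"])
        if not 0 <= row["mean_q"]:
            raise ValueError(f"{where}: negative proportion")
        if row["ci5"] > row["ci95"]:
            raise ValueError(f"{where}: ci5 > ci95")
        if row["category"] != categorize(row["mean_q"]):
            raise ValueError(
                f"{where}: category {row['category']!r} inconsistent with "
                f"mean_q={row['mean_q']}"
            )
    sums = df.groupby("kit_label", sort=False)
    for kit_label, block in sums:
        total = block["mean_q"].sum()
        printed = block["sum_of_proportions"].iloc[0]
        if block["sum_of_proportions"].nunique() != 1:
            raise ValueError(f"{kit_label}: inconsistent sum_of_proportions")
        if abs(total - printed) > _SUMPROP_TOL:
            raise ValueError(
                f"{kit_label}: sum of member proportions {total:.4f} != "
                f"printed {printed:.4f}"
            )
        if block["constituent_label"].duplicated().any():
            raise ValueError(f"{kit_label}: duplicate constituent rows")
    if df["kit_label"].nunique() != EXPECTED_N_SUMS:
        raise ValueError(
            f"expected {EXPECTED_N_SUMS} sums, found {df['kit_label'].nunique()}"
        )
    if len(df) != EXPECTED_N_CONSTITUENTS:
        raise ValueError(
            f"expected {EXPECTED_N_CONSTITUENTS} constituent rows, found {len(df)}"
        )


def load_reference(
    path: Optional[Union[str, Path]] = None,
) -> ReferenceCompositionTable:
    """Load and validate a reference composition table (packaged default)."""
    if path is None:
        source = resources.files("pccomp.data").joinpath(
            "reference_composition.tsv"
        )
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
        provenance = "packaged"
    else:
        df = pd.read_csv(path, sep="\t")
        provenance = str(path)
    df["category"] = df["category"].fillna("none")
    _validate(df)
    return ReferenceCompositionTable(frame=df, provenance=provenance)


def _has_odd_chain(constituent_label: str) -> bool:
    entity = parse_lipid_name(constituent_label)
    return any(c.carbons % 2 == 1 for c in entity.chains)


def summarize_reference(table: ReferenceCompositionTable) -> Dict[str, float]:
    """Headline summary statistics of a reference composition table.

    Thresholds are strict (>0.2, >0.8); the concordant band for the sum of
    proportions is the closed interval [0.8, 1.2].  Counts are per sum (a
    sum with two members above a threshold counts once).
    """
    df = table.frame
    per_sum = table.per_sum()
    n_gt_02 = df.groupby("kit_label")["mean_q"].apply(lambda q: (q > 0.2).sum())
    ae_mask = df["kit_label"].str.contains(" ae ")
    ae_odd = df[ae_mask & df["constituent_label"].map(_has_odd_chain)]
    return {
        "n_sums": table.n_sums,
        "n_constituent_rows": table.n_constituents,
        "n_sums_ge1_gt02": int((n_gt_02 >= 1).sum()),
        "n_sums_ge2_gt02": int((n_gt_02 >= 2).sum()),
        "n_sums_major_gt08": int((per_sum["max_q"] > 0.8).sum()),
        "n_sums_sumprop_80_120": int(
            per_sum["sum_of_proportions"].between(0.8, 1.2, inclusive="both").sum()
        ),
        "n_sums_sumprop_gt_120": int((per_sum["sum_of_proportions"] > 1.2).sum()),
        "r2_median_pct": float(per_sum["r_squared_pct"].median()),
        "r2_mean_pct": float(per_sum["r_squared_pct"].mean()),
        "r2_sd_pct": float(per_sum["r_squared_pct"].std(ddof=1)),
        "mean_q_ae_rows": float(df.loc[ae_mask, "mean_q"].mean()),
        "mean_q_ae_odd_chain": float(ae_odd["mean_q"].mean()),
    }


def impute_constituents(
    species_matrix: ConcentrationMatrix,
    table: ReferenceCompositionTable,
) -> ConcentrationMatrix:
    """Impute fatty-acid-level concentrations from kit PC sums.

    For every kit analyte present in the table, each constituent gets
    mean_q(i,j) × conc(sum i) per sample; missing sums propagate missing.
    Kit analytes absent from the table are skipped (collected in the
    ``skipped_analytes`` attribute of the returned matrix's meta — a list
    attached as ``.attrs``).  Output values carry an ``imputed`` provenance
    flag in ``.attrs``.
    """
    known = set(table.sum_labels)
    imputed: Dict[str, pd.Series] = {}
    skipped: List[str] = []
    for analyte in species_matrix.analytes:
        if analyte not in known:
            skipped.append(analyte)
            continue
        conc = species_matrix.values[analyte]
        for constituent, q in table.proportions(analyte).items():
            imputed[constituent] = conc * q
    values = pd.DataFrame(imputed, index=species_matrix.values.index)
    out = ConcentrationMatrix(
        values=values,
        meta=species_matrix.meta.copy(),
        platform="fatty_acid_level",
    )
    out.values.attrs["provenance"] = "imputed"
    out.values.attrs["skipped_analytes"] = skipped
    return out
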