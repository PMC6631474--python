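"""Per-sample constituent ratios and characteristic compositions of PC sums.

For constituent j of PC sum i, the per-sample ratio is

    q_ijst = conc(PC_j, fatty-acid level)_st / conc(PC_i, species level)_st

over subjects s and timepoints t.  The characteristic proportion of j in i
is the mean of these ratios; variation is summarized by the empirical 5th
and 95th percentiles.  Constituents are categorized I (mean q > 0.2) or II
(mean q > 0.8), and each sum's measured proportions are totalled (a total
above 1 indicates platform efficiency differences, not a logical error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import ConstituentCatalog
from .cohort import ConcentrationMatrix


@dataclass
class RatioSet:
    """Per-sample ratios q_ijst for one (sum i, constituent j) pair."""

    sum_label: str
    constituent_label: str
    ratios: pd.Series  # indexed by sample_id, NaN-free

    @property
    def n_used(self) -> int:
        return int(self.ratios.size)


@dataclass
class CompositionEstimate:
    sum_label: str
    constituent_label: str
    mean_q: float
    ci5: float
    ci95: float
    category: str  # "none" | "I" | "II"
    is_main: bool
    n_used: int


@dataclass
class SumComposition:
    sum_label: str
    estimates: List[CompositionEstimate]
    sum_of_proportions: float
    main_constituent: Optional[str]


def categorize(mean_q: float) -> str:
    """Step categories with strict thresholds: II above 0.8, I above 0.2."""
    if mean_q > 0.8:
        return "II"
    if mean_q > 0.2:
        return "I"
    return "none"


def compute_ratio_set(
    species_matrix: ConcentrationMatrix,
    fa_matrix: ConcentrationMatrix,
    catalogs: Sequence[ConstituentCatalog],
) -> List[RatioSet]:
    """Ratios q_ijst for every measured constituent of every catalog.

    A sample contributes to a pair only when both concentrations are present
    and the sum-level denominator is positive (zero denominators are treated
    as missing, not infinite).
    """
    shared = [s for s in species_matrix.sample_ids if s in set(fa_matrix.sample_ids)]
    if not shared:
        raise ValueError("matrices share no sample_ids")
    sp = species_matrix.values.loc[shared]
    fa = fa_matrix.values.loc[shared]
    out: List[RatioSet] = []
    for cat in catalogs:
        if cat.sum_label not in sp.columns:
            raise ValueError(
                f"sum analyte {cat.sum_label!r} absent from species-level matrix"
            )
        denom = sp[cat.sum_label].where(sp[cat.sum_label] > 0)
        for constituent in cat.measured_labels:
            if constituent not in fa.columns:
                raise ValueError(
                    f"constituent {constituent!r} absent from fatty-acid matrix"
                )
            q = (fa[constituent] / denom).dropna()
            out.append(
                RatioSet(
                    sum_label=cat.sum_label,
                    constituent_label=constituent,
                    ratios=q,
                )
            )
    return out


def summarize_composition(
    ratio_sets: Sequence[RatioSet],
    sample_filter: Optional[Sequence] = None,
) -> Tuple[List[SumComposition], List[str]]:
    """Mean q, percentile intervals, categories and main constituent per sum.

    ``sample_filter`` optionally restricts all ratio sets to the given
    sample ids (e.g. a metadata-defined subgroup).  Pairs left empty after
    filtering are omitted and reported in the warnings list.
    """
    warnings: List[str] = []
    by_sum: Dict[str, List[CompositionEstimate]] = {}
    order: List[str] = []
    for rs in ratio_sets:
        q = rs.ratios
        if sample_filter is not None:
            q = q[q.index.isin(set(sample_filter))]
        if q.empty:
            warnings.append(
                f"no usable samples for {rs.sum_label} ~ {rs.constituent_label}"
            )
            continue
        vals = q.to_numpy(dtype=float)
        mean_q = float(vals.mean())
        ci5, ci95 = np.percentile(vals, [5.0, 95.0])
        est = CompositionEstimate(
            sum_label=rs.sum_label,
            constituent_label=rs.constituent_label,
            mean_q=mean_q,
            ci5=float(ci5),
            ci95=float(ci95),
            category=categorize(mean_q),
            is_main=False,
            n_used=len(vals),
        )
        if rs.sum_label not in by_sum:
            by_sum[rs.sum_label] = []
            order.append(rs.sum_label)
        by_sum[rs.sum_label].append(est)
    compositions: List[SumComposition] = []
    for sum_label in order:
        ests = by_sum[sum_label]
        # main constituent: largest mean q; ties broken by canonical label
        main = min(ests, key=lambda e: (-e.mean_q, e.constituent_label))
        for e in ests:
            e.is_main = e is main
        compositions.append(
            SumComposition(
                sum_label=sum_label,
                estimates=sorted(ests, key=lambda e: e.constituent_label),
                sum_of_proportions=float(sum(e.mean_q for e in ests)),
                main_constituent=main.constituent_label,
            )
        )
    return compositions, warnings


def composition_frame(compositions: Sequence[SumComposition]) -> pd.DataFrame:
    rows = []
    for comp in compositions:
        for e in comp.estimates:
            rows.append(
                {
                    "sum_label": comp.sum_label,
                    "constituent_label": e.constituent_label,
                    "mean_q": e.mean_q,
                    "ci5": e.ci5,
                    "ci95": e.ci95,
                    "category": e.category,
                    "is_main": e.is_main,
                    "n_used": e.n_used,
                    "sum_of_proportions": comp.sum_of_proportions,
                }
            )
    return pd.DataFrame(rows)


def lipidyzer_fractions(
    fa_matrix: ConcentrationMatrix,
    catalogs: Sequence[ConstituentCatalog],
) -> pd.DataFrame:
    """Within-platform fractions of each measured constituent per sum.

    Uses only the side-chain-resolving platform: for each sample the
    fraction of constituent j among all measured constituents of sum i,
    e.g. PC 16:0_20:2 / (PC 16:0_20:2 + PC 18:0_18:2 + PC 18:1_18:1).
    Samples missing some (but not all) constituents get fractions over the
    remaining ones and are flagged ``partial``; all-zero or all-missing
    denominators yield missing fractions.  Tidy output: one row per
    (sample, sum, constituent).
    """
    rows = []
    for cat in catalogs:
        measured = [c for c in cat.measured_labels if c in fa_matrix.values.columns]
        if not measured:
            continue
        block = fa_matrix.values[measured]
        denom = block.sum(axis=1, min_count=1)
        partial = block.isna().any(axis=1)
        for constituent in measured:
            frac = block[constituent] / denom.where(denom > 0)
            for sample_id, value in frac.items():
                if np.isnan(value):
                    continue
                rows.append(
                    {
                        "sample_id": sample_id,
                        "sum_label": cat.sum_label,
                        "constituent_label": constituent,
                        "fraction": float(value),
                        "partial": bool(partial[sample_id]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "sum_label", "constituent_label", "fraction", "partial"],
    )
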