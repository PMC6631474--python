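"""Concordance of PC sum measures with their cumulated measured constituents.

Two complementary views quantify how much of a bulk PC measure is explained
by the constituents quantified on the side-chain-resolving platform:

* a least-squares fit through the origin, sum ~ b · Σ(constituents), with
  the explained variance R²;
* Bland–Altman statistics on the per-sample difference between the bulk
  measure and the cumulated constituents against their per-sample mean,
  classifying each sum by whether the mean difference lies within 1 or 2
  SD of the bulk measure.

Samples missing any mapped constituent are excluded (complete case), so the
cumulated concentration is never taken over a partial constituent set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import ConstituentCatalog
from .cohort import ConcentrationMatrix


@dataclass
class ProportionalFit:
    sum_label: str
    slope: float
    r_squared: float  # fraction in [0, 1] under the centered definition
    n: int
    r_squared_uncentered: float


@dataclass
class BlandAltmanResult:
    sum_label: str
    differences: pd.Series  # d_st = conc_i - Σ conc_j
    means: pd.Series  # m_st = (conc_i + Σ conc_j) / 2
    mean_difference: float
    sd_reference: float  # SD of the species-level (bulk) measure
    sd_differences: float
    loa_low: float  # conventional limits of agreement (reported, not used
    loa_high: float  # for classification)
    classification: str  # within_1SD | within_2SD | beyond_2SD
    n: int


def _complete_cases(
    species_matrix: ConcentrationMatrix,
    fa_matrix: ConcentrationMatrix,
    catalog: ConstituentCatalog,
) -> Tuple[pd.Series, pd.Series]:
    """(bulk measure, cumulated constituents) over complete-case samples."""
    measured = list(catalog.measured_labels)
    if not measured:
        raise ValueError(f"{catalog.sum_label}: no measured constituents")
    shared = [
        s for s in species_matrix.sample_ids if s in set(fa_matrix.sample_ids)
    ]
    y = species_matrix.values.loc[shared, catalog.sum_label]
    block = fa_matrix.values.loc[shared, measured]
    ok = y.notna() & block.notna().all(axis=1)
    return y[ok], block[ok].sum(axis=1)


def fit_proportional_model(
    species_matrix: ConcentrationMatrix,
    fa_matrix: ConcentrationMatrix,
    catalog: ConstituentCatalog,
) -> ProportionalFit:
    """Through-origin least squares of the bulk measure on Σ(constituents).

    R² is reported as the squared Pearson correlation between observed and
    fitted values (centered definition; through-origin fits inflate the
    uncentered variant, which is carried along for reference).
    """
    y, x = _complete_cases(species_matrix, fa_matrix, catalog)
    if len(y) < 3:
        raise ValueError(
            f"{catalog.sum_label}: need >=3 complete-case samples, have {len(y)}"
        )
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    sxx = float(xv @ xv)
    if sxx == 0 or np.isclose(xv.std(), 0.0):
        raise ValueError(f"{catalog.sum_label}: zero-variance predictor")
    b = float(xv @ yv) / sxx
    if np.isclose(yv.std(), 0.0):
        r2_centered = 0.0
    else:
        r2_centered = float(np.corrcoef(yv, xv)[0, 1] ** 2)
    ss_res = float(((yv - b * xv) ** 2).sum())
    ss_tot_uncentered = float((yv**2).sum())
    r2_uncentered = 1.0 - ss_res / ss_tot_uncentered if ss_tot_uncentered else 0.0
    return ProportionalFit(
        sum_label=catalog.sum_label,
        slope=b,
        r_squared=r2_centered,
        n=len(y),
        r_squared_uncentered=r2_uncentered,
    )


def bland_altman_stats(
    species_matrix: ConcentrationMatrix,
    fa_matrix: ConcentrationMatrix,
    catalog: ConstituentCatalog,
) -> BlandAltmanResult:
    """Bland–Altman difference statistics for one PC sum.

    The classification reference SD is the SD of the bulk species-level
    measure itself; a negative mean difference means the cumulated
    constituents exceed the bulk measure.
    """
    y, x = _complete_cases(species_matrix, fa_matrix, catalog)
    if len(y) < 2:
        raise ValueError(
            f"{catalog.sum_label}: need >=2 complete-case samples, have {len(y)}"
        )
    d = y - x
    m = (y + x) / 2.0
    mean_diff = float(d.mean())
    sd_ref = float(y.std(ddof=1))
    sd_d = float(d.std(ddof=1))
    if abs(mean_diff) <= sd_ref:
        classification = "within_1SD"
    elif abs(mean_diff) <= 2 * sd_ref:
        classification = "within_2SD"
    else:
        classification = "beyond_2SD"
    return BlandAltmanResult(
        sum_label=catalog.sum_label,
        differences=d,
        means=m,
        mean_difference=mean_diff,
        sd_reference=sd_ref,
        sd_differences=sd_d,
        loa_low=mean_diff - 1.96 * sd_d,
        loa_high=mean_diff + 1.96 * sd_d,
        classification=classification,
        n=len(y),
    )


def concordance_frame(
    species_matrix: ConcentrationMatrix,
    fa_matrix: ConcentrationMatrix,
    catalogs: Sequence[ConstituentCatalog],
) -> pd.DataFrame:
    """Per-sum concordance report over all catalogs with measured members."""
    rows = []
    for cat in catalogs:
        if not cat.measured_labels:
            continue
        try:
            fit = fit_proportional_model(species_matrix, fa_matrix, cat)
            ba = bland_altman_stats(species_matrix, fa_matrix, cat)
        except ValueError as exc:
            rows.append({"sum_label": cat.sum_label, "error": str(exc)})
            continue
        rows.append(
            {
                "sum_label": cat.sum_label,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "r_squared_uncentered": fit.r_squared_uncentered,
                "n": fit.n,
                "mean_difference": ba.mean_difference,
                "sd_reference": ba.sd_reference,
                "classification": ba.classification,
                "error": "",
            }
        )
    return pd.DataFrame(rows)
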