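"""Intra-/inter-individual variation of constituent ratios and replication.

Two average standard deviations summarize how stable the composition ratios
q_ij are: SD over the challenge timepoints of one subject (averaged over
pairs and subjects — intra-individual, "SD_challenges") and SD over
subjects at a fixed timepoint (averaged over pairs and timepoints —
inter-individual, "SD_subjects").

Challenge responses are tested with a two-sided paired Wilcoxon signed-rank
test (baseline vs intervention, paired by subject).  Differences between
subjects use one-way ANOVA when a Shapiro–Wilk gate accepts normality of
the residuals, Kruskal–Wallis otherwise.  Cross-cohort replication compares
the identified main constituent of each sum and its q distribution between
cohorts with Kruskal–Wallis at a Bonferroni-corrected level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .composition import RatioSet, SumComposition

LIPID_CHALLENGES = ("FASTING", "PAT", "OLTT")


@dataclass
class VariationSummary:
    sd_challenges: float  # average within-subject SD across timepoints
    sd_subjects: float  # average between-subject SD at fixed timepoints
    per_pair: pd.DataFrame  # per (sum, constituent) components
    n_skipped_cells: int


@dataclass(frozen=True)
class ComparisonConfig:
    alpha_total: float = 0.05
    n_tests: int = 1
    normality_alpha: float = 0.05

    @property
    def alpha(self) -> float:
        return self.alpha_total / self.n_tests


@dataclass
class ComparisonResult:
    sum_label: str
    main_a: Optional[str]
    main_b: Optional[str]
    main_agreement: Optional[bool]  # None when <2 constituents measured
    statistic: float
    p_value: float
    significant: bool


def _challenge_samples(meta: pd.DataFrame, challenges: Sequence[str]) -> pd.DataFrame:
    mask = meta["challenge"].isin(list(challenges)) & meta["phase"].isin(
        ["baseline", "intervention"]
    )
    return meta.loc[mask.fillna(False)]


def variation_sds(
    ratio_sets: Sequence[RatioSet],
    meta: pd.DataFrame,
    challenges: Sequence[str] = LIPID_CHALLENGES,
) -> VariationSummary:
    """Average intra-individual and inter-individual SD of q_ij.

    Restricted to the baseline/intervention timepoints of the given
    challenges.  Cells (a subject's timepoint series, or a timepoint's
    subject series) with fewer than two observations are skipped.
    """
    selected = _challenge_samples(meta, challenges)
    rows = []
    skipped = 0
    for rs in ratio_sets:
        q = rs.ratios[rs.ratios.index.isin(selected.index)]
        if q.empty:
            skipped += 1
            continue
        sub = selected.loc[q.index]
        within: List[float] = []
        for _, grp in q.groupby(sub["subject"]):
            if len(grp) >= 2:
                within.append(float(grp.std(ddof=1)))
            else:
                skipped += 1
        between: List[float] = []
        for _, grp in q.groupby(sub["timepoint"]):
            if len(grp) >= 2:
                between.append(float(grp.std(ddof=1)))
            else:
                skipped += 1
        rows.append(
            {
                "sum_label": rs.sum_label,
                "constituent_label": rs.constituent_label,
                "sd_challenges": np.mean(within) if within else np.nan,
                "sd_subjects": np.mean(between) if between else np.nan,
                "n_within_cells": len(within),
                "n_between_cells": len(between),
            }
        )
    per_pair = pd.DataFrame(rows)
    all_within = per_pair["sd_challenges"].dropna()
    all_between = per_pair["sd_subjects"].dropna()
    return VariationSummary(
        sd_challenges=float(all_within.mean()) if len(all_within) else np.nan,
        sd_subjects=float(all_between.mean()) if len(all_between) else np.nan,
        per_pair=per_pair,
        n_skipped_cells=skipped,
    )


def paired_challenge_test(
    ratio_set: RatioSet,
    meta: pd.DataFrame,
    challenge: str,
) -> Optional[float]:
    """Two-sided paired Wilcoxon signed-rank p for baseline vs intervention.

    Subjects contribute one baseline and one intervention value (averaged if
    a subject has several samples in a phase); unpaired subjects are
    dropped.  All-zero difference vectors return p = 1 (no-effect
    convention); fewer than two pairs return None (test skipped).
    """
    sel = meta[(meta["challenge"] == challenge)]
    q = ratio_set.ratios[ratio_set.ratios.index.isin(sel.index)]
    if q.empty:
        return None
    sub = sel.loc[q.index]
    table = (
        pd.DataFrame({"q": q, "subject": sub["subject"], "phase": sub["phase"]})
        .groupby(["subject", "phase"])["q"]
        .mean()
        .unstack()
    )
    if "baseline" not in table.columns or "intervention" not in table.columns:
        return None
    paired = table[["baseline", "intervention"]].dropna()
    if len(paired) < 2:
        return None
    diffs = paired["baseline"].to_numpy() - paired["intervention"].to_numpy()
    if np.allclose(diffs, 0.0):
        return 1.0
    res = stats.wilcoxon(
        paired["baseline"],
        paired["intervention"],
        alternative="two-sided",
        zero_method="wilcox",
    )
    return float(res.pvalue)


@dataclass
class AcrossSubjectResult:
    test_name: str  # "anova" | "kruskal" | "skipped"
    p_value: float
    shapiro_p: float
    reason: str = ""


def across_subject_test(
    ratio_set: RatioSet,
    meta: pd.DataFrame,
    normality_alpha: float = 0.05,
    group_by: str = "subject",
) -> AcrossSubjectResult:
    """Compare q_ij distributions across subjects (or another grouping).

    A Shapiro–Wilk gate on the group-mean-centered residuals selects
    one-way ANOVA (normality not rejected) or Kruskal–Wallis.  Degenerate
    inputs (constant data, <2 usable groups) are skipped with a reason.
    """
    q = ratio_set.ratios[ratio_set.ratios.index.isin(meta.index)]
    sub = meta.loc[q.index, group_by]
    groups = [g.to_numpy(dtype=float) for _, g in q.groupby(sub) if len(g) >= 2]
    if len(groups) < 2:
        return AcrossSubjectResult("skipped", np.nan, np.nan, "<2 usable groups")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return AcrossSubjectResult("skipped", np.nan, np.nan, "constant data")
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(residuals, 0.0):
        return AcrossSubjectResult("skipped", np.nan, np.nan, "zero residuals")
    shapiro_p = float(stats.shapiro(residuals).pvalue)
    if shapiro_p >= normality_alpha:
        stat = stats.f_oneway(*groups)
        return AcrossSubjectResult("anova", float(stat.pvalue), shapiro_p)
    stat = stats.kruskal(*groups)
    return AcrossSubjectResult("kruskal", float(stat.pvalue), shapiro_p)


def _ratio_lookup(
    ratio_sets: Sequence[RatioSet],
) -> Dict[Tuple[str, str], RatioSet]:
    return {(rs.sum_label, rs.constituent_label): rs for rs in ratio_sets}


def compare_cohorts(
    composition_a: Sequence[SumComposition],
    ratio_sets_a: Sequence[RatioSet],
    composition_b: Sequence[SumComposition],
    ratio_sets_b: Sequence[RatioSet],
    config: Optional[ComparisonConfig] = None,
) -> Tuple[List[ComparisonResult], ComparisonConfig]:
    """Replication of compositions between two cohorts.

    For every sum testable in both cohorts the q distribution of cohort A's
    main constituent is compared between cohorts with Kruskal–Wallis at a
    Bonferroni level alpha_total/n_tests, with n_tests recomputed from the
    data (the number of sums testable in both cohorts).  Main-constituent
    agreement is reported for sums with at least two measured constituents
    in both cohorts, and is None otherwise.
    """
    comp_a = {c.sum_label: c for c in composition_a}
    comp_b = {c.sum_label: c for c in composition_b}
    lookup_a = _ratio_lookup(ratio_sets_a)
    lookup_b = _ratio_lookup(ratio_sets_b)
    testable: List[str] = []
    for sum_label in comp_a:
        if sum_label not in comp_b:
            continue
        main = comp_a[sum_label].main_constituent
        if (sum_label, main) in lookup_a and (sum_label, main) in lookup_b:
            testable.append(sum_label)
    if config is None:
        config = ComparisonConfig(n_tests=max(1, len(testable)))
    elif config.n_tests != max(1, len(testable)):
        config = ComparisonConfig(
            alpha_total=config.alpha_total,
            n_tests=max(1, len(testable)),
            normality_alpha=config.normality_alpha,
        )
    results: List[ComparisonResult] = []
    for sum_label in testable:
        a, b = comp_a[sum_label], comp_b[sum_label]
        main = a.main_constituent
        qa = lookup_a[(sum_label, main)].ratios.to_numpy(dtype=float)
        qb = lookup_b[(sum_label, main)].ratios.to_numpy(dtype=float)
        pooled = np.concatenate([qa, qb])
        if np.allclose(pooled, pooled[0]):
            stat, p = 0.0, 1.0
        else:
            kw = stats.kruskal(qa, qb)
            stat, p = float(kw.statistic), float(kw.pvalue)
        agreement: Optional[bool] = None
        if len(a.estimates) >= 2 and len(b.estimates) >= 2:
            agreement = a.main_constituent == b.main_constituent
        results.append(
            ComparisonResult(
                sum_label=sum_label,
                main_a=a.main_constituent,
                main_b=b.main_constituent,
                main_agreement=agreement,
                statistic=stat,
                p_value=p,
                significant=bool(p < config.alpha),
            )
        )
    return results, config


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sum_label": r.sum_label,
                "main_a": r.main_a,
                "main_b": r.main_b,
                "main_agreement": r.main_agreement,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
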