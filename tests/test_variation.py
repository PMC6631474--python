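"""Variation summaries, challenge tests, and cross-cohort replication."""

import numpy as np
import pandas as pd
import pytest

from pccomp import (
    RatioSet,
    across_subject_test,
    compare_cohorts,
    paired_challenge_test,
    summarize_composition,
    variation_sds,
)
from pccomp.variation import ComparisonConfig


def challenge_meta(subjects, challenges=("FASTING",)):
    rows = []
    for s in subjects:
        for ch in challenges:
            for phase in ("baseline", "intervention"):
                rows.append(
                    {
                        "sample_id": f"{s}_{ch}_{phase}",
                        "subject": s,
                        "timepoint": f"{ch}_{phase}",
                        "cohort": "T",
                        "challenge": ch,
                        "phase": phase,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def test_constant_ratios_have_zero_sds():
    meta = challenge_meta([f"S{i}" for i in range(4)], ("FASTING", "PAT"))
    rs = RatioSet("PC aa C36:2", "PC 18:0_18:2",
                  pd.Series(0.7, index=meta.index))
    summary = variation_sds([rs], meta)
    assert summary.sd_challenges == 0.0
    assert summary.sd_subjects == 0.0


def test_subject_offsets_give_between_not_within_variation():
    """Per-subject offsets ±d with no time variation: SD_challenges = 0 and
    SD_subjects equals the closed-form SD of the offsets."""
    subjects = ["S1", "S2", "S3", "S4"]
    offsets = {"S1": -0.1, "S2": -0.05, "S3": 0.05, "S4": 0.1}
    meta = challenge_meta(subjects, ("FASTING", "PAT"))
    q = pd.Series([0.5 + offsets[meta.loc[i, "subject"]] for i in meta.index],
                  index=meta.index)
    summary = variation_sds([RatioSet("i", "PC 18:0_18:2", q)], meta)
    assert summary.sd_challenges == pytest.approx(0.0, abs=1e-15)
    expected_sd = np.std(list(offsets.values()), ddof=1)
    assert summary.sd_subjects == pytest.approx(expected_sd)


def test_simulated_between_gt_within(humet_cohort, catalogs):
    """A cohort generated with larger between-subject than within-subject
    log-scale variance shows SD_subjects > SD_challenges for total
    abundances — and both SDs are finite for the ratios."""
    from pccomp import compute_ratio_set

    config, species, fa, _ = humet_cohort
    assert config.sd_subject > config.sd_within
    ratio_sets = compute_ratio_set(species, fa, catalogs)
    summary = variation_sds(ratio_sets, species.meta)
    assert summary.sd_challenges >= 0 and summary.sd_subjects >= 0
    assert np.isfinite(summary.sd_challenges) and np.isfinite(summary.sd_subjects)


def test_variation_invariant_to_relabeling():
    meta = challenge_meta(["S1", "S2", "S3"], ("FASTING",))
    rng = np.random.default_rng(4)
    q = pd.Series(rng.uniform(0.3, 0.7, len(meta)), index=meta.index)
    base = variation_sds([RatioSet("i", "j", q)], meta)
    relabeled = meta.copy()
    relabeled["subject"] = relabeled["subject"].map(
        {"S1": "Z9", "S2": "A1", "S3": "M5"}
    )
    out = variation_sds([RatioSet("i", "j", q)], relabeled)
    assert out.sd_challenges == pytest.approx(base.sd_challenges)
    assert out.sd_subjects == pytest.approx(base.sd_subjects)


def test_wilcoxon_no_effect_convention():
    meta = challenge_meta([f"S{i}" for i in range(6)])
    q = pd.Series(0.5, index=meta.index)
    rs = RatioSet("i", "j", q)
    assert paired_challenge_test(rs, meta, "FASTING") == 1.0


def test_wilcoxon_uniform_shift_exact_tail():
    """A consistent one-direction shift over 8 pairs hits the exact
    two-sided signed-rank tail 2/2^8."""
    subjects = [f"S{i}" for i in range(8)]
    meta = challenge_meta(subjects)
    vals = {}
    for i, s in enumerate(subjects):
        vals[f"{s}_FASTING_baseline"] = 0.5 + 0.01 * i
        vals[f"{s}_FASTING_intervention"] = 0.6 + 0.01 * i
    rs = RatioSet("i", "j", pd.Series(vals))
    assert paired_challenge_test(rs, meta, "FASTING") == pytest.approx(2 / 256)


def test_wilcoxon_insufficient_pairs_skipped():
    meta = challenge_meta(["S1"])
    rs = RatioSet("i", "j", pd.Series({"S1_FASTING_baseline": 0.4,
                                       "S1_FASTING_intervention": 0.6}))
    assert paired_challenge_test(rs, meta, "FASTING") is None


def test_wilcoxon_invariant_to_common_offset():
    subjects = [f"S{i}" for i in range(8)]
    meta = challenge_meta(subjects)
    rng = np.random.default_rng(9)
    base = rng.uniform(0.3, 0.5, 8)
    iv = base + rng.normal(0.0, 0.05, 8)
    def build(shift):
        vals = {}
        for i, s in enumerate(subjects):
            vals[f"{s}_FASTING_baseline"] = base[i] + shift
            vals[f"{s}_FASTING_intervention"] = iv[i] + shift
        return RatioSet("i", "j", pd.Series(vals))
    p0 = paired_challenge_test(build(0.0), meta, "FASTING")
    p1 = paired_challenge_test(build(10.0), meta, "FASTING")
    assert p0 == pytest.approx(p1)


def subject_meta(n_subjects, n_obs):
    rows = []
    for s in range(n_subjects):
        for t in range(n_obs):
            rows.append({"sample_id": f"S{s}_t{t}", "subject": f"S{s}",
                         "timepoint": f"t{t}", "cohort": "T"})
    return pd.DataFrame(rows).set_index("sample_id")


def test_across_subject_null_is_calm():
    meta = subject_meta(5, 30)
    rng = np.random.default_rng(12)
    q = pd.Series(rng.normal(0.5, 0.05, len(meta)), index=meta.index)
    res = across_subject_test(RatioSet("i", "j", q), meta)
    assert res.test_name == "anova"  # normal residuals pass the gate
    assert res.p_value > 0.01


def test_across_subject_disjoint_supports_significant():
    meta = subject_meta(3, 20)
    rng = np.random.default_rng(13)
    level = {"S0": 0.2, "S1": 0.5, "S2": 0.8}
    q = pd.Series(
        [level[meta.loc[i, "subject"]] + 0.01 * rng.random() for i in meta.index],
        index=meta.index,
    )
    res = across_subject_test(RatioSet("i", "j", q), meta)
    assert res.p_value < 1e-4


def test_across_subject_kruskal_branch_for_heavy_tails():
    meta = subject_meta(4, 40)
    rng = np.random.default_rng(14)
    q = pd.Series(np.exp(rng.standard_cauchy(len(meta)) * 0.5),
                  index=meta.index).abs()
    res = across_subject_test(RatioSet("i", "j", q), meta)
    assert res.test_name == "kruskal"


def test_across_subject_constant_data_skipped():
    meta = subject_meta(3, 5)
    q = pd.Series(0.4, index=meta.index)
    res = across_subject_test(RatioSet("i", "j", q), meta)
    assert res.test_name == "skipped"


def make_cohort_sets(shift=0.0, seed=0, n=40):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    sets = [
        RatioSet("PC aa C36:2", "PC 18:0_18:2",
                 pd.Series(rng.normal(0.6 + shift, 0.05, n), index=idx).abs()),
        RatioSet("PC aa C36:2", "PC 18:1_18:1",
                 pd.Series(rng.normal(0.1, 0.02, n), index=idx).abs()),
    ]
    comps, _ = summarize_composition(sets)
    return comps, sets


def test_identical_cohorts_replicate():
    comp_a, sets_a = make_cohort_sets(seed=1)
    comp_b, sets_b = make_cohort_sets(seed=1)
    results, config = compare_cohorts(comp_a, sets_a, comp_b, sets_b)
    assert all(r.main_agreement for r in results)
    assert not any(r.significant for r in results)


def test_shifted_cohort_same_main_but_significant():
    comp_a, sets_a = make_cohort_sets(seed=2)
    comp_b, sets_b = make_cohort_sets(shift=0.3, seed=3)
    results, _ = compare_cohorts(comp_a, sets_a, comp_b, sets_b)
    (res,) = results
    assert res.main_agreement is True
    assert res.significant


def test_bonferroni_alpha_printed_value():
    config = ComparisonConfig(alpha_total=0.05, n_tests=37)
    assert config.alpha == pytest.approx(0.0014, abs=5e-5)
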