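"""Variation of composition ratios and replication across cohorts.

On the deep synthetic cohort: average intra-individual (across challenge
timepoints) and inter-individual (across subjects) SD of q_ij, paired
Wilcoxon signed-rank tests of baseline vs intervention per lipid challenge,
and Shapiro-gated ANOVA/Kruskal–Wallis comparisons across subjects.  Then
the main constituents identified in the deep cohort are checked in the
male-control subset of the cross-sectional cohort, with Bonferroni-corrected
Kruskal–Wallis tests on the main-constituent ratio distributions.

Writes results/variation_deep.tsv and results/replication.tsv.
"""

from pathlib import Path

from pccomp import (
    across_subject_test,
    assemble_constituent_catalog,
    compare_cohorts,
    compute_ratio_set,
    coverage_filter,
    paired_challenge_test,
    read_concentration_table,
    summarize_composition,
    variation_sds,
)
from pccomp.variation import LIPID_CHALLENGES, comparison_frame

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_cohort(name: str):
    d = ROOT / "synthetic" / name
    species = read_concentration_table(d / "species_level.tsv", "species_level_kit")
    fa = coverage_filter(
        read_concentration_table(d / "fatty_acid_level.tsv", "fatty_acid_level")
    )
    return species, fa


def main() -> None:
    species, fa = load_cohort("deep")
    catalogs = assemble_constituent_catalog(species.analytes, fa.analytes)
    ratio_sets = compute_ratio_set(species, fa, catalogs)
    compositions, _ = summarize_composition(ratio_sets)

    summary = variation_sds(ratio_sets, species.meta)
    summary.per_pair.to_csv(ROOT / "variation_deep.tsv", sep="\t", index=False)
    print(f"SD_challenges (avg within-subject): {summary.sd_challenges:.3f}")
    print(f"SD_subjects  (avg between-subject): {summary.sd_subjects:.3f}")

    mains = {c.sum_label: c.main_constituent for c in compositions}
    lookup = {(r.sum_label, r.constituent_label): r for r in ratio_sets}
    n_trend = 0
    n_tested = 0
    for ch in LIPID_CHALLENGES:
        for sum_label, main in mains.items():
            p = paired_challenge_test(lookup[(sum_label, main)], species.meta, ch)
            if p is not None:
                n_tested += 1
                if p < 0.05 / len(mains):
                    n_trend += 1
    print(f"challenge trends (paired Wilcoxon, Bonferroni): "
          f"{n_trend}/{n_tested} significant")

    gated = [across_subject_test(lookup[(s, m)], species.meta)
             for s, m in mains.items()]
    n_anova = sum(r.test_name == "anova" for r in gated)
    n_kw = sum(r.test_name == "kruskal" for r in gated)
    print(f"across-subject tests: {n_anova} ANOVA / {n_kw} Kruskal–Wallis "
          f"(Shapiro–Wilk gate)")

    species_b, fa_b = load_cohort("cross_sectional")
    meta_b = species_b.meta
    subset = meta_b[(meta_b.sex == "male") & (meta_b.group == "control")].index
    ratio_sets_b = compute_ratio_set(
        species_b.subset_samples(subset), fa_b.subset_samples(subset), catalogs
    )
    comp_b, _ = summarize_composition(ratio_sets_b)
    results, config = compare_cohorts(
        compositions, ratio_sets, comp_b, ratio_sets_b
    )
    comparison_frame(results).to_csv(ROOT / "replication.tsv", sep="\t",
                                     index=False)
    agree = [r.main_agreement for r in results if r.main_agreement is not None]
    print(f"replication subset: {len(subset)} male controls")
    print(f"main-constituent agreement: {sum(agree)}/{len(agree)} sums "
          f"(>=2 measured constituents)")
    print(f"significant cohort differences: "
          f"{sum(r.significant for r in results)}/{config.n_tests} sums at "
          f"alpha={config.alpha:.4g}")


if __name__ == "__main__":
    main()
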