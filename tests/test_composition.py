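"""Constituent ratios q_ijst and characteristic composition summaries."""

import numpy as np
import pandas as pd
import pytest

from pccomp import (
    ConcentrationMatrix,
    RatioSet,
    assemble_constituent_catalog,
    compute_ratio_set,
    lipidyzer_fractions,
    summarize_composition,
)
from pccomp.composition import categorize


def paired_matrices(species_vals, fa_vals, index):
    meta = pd.DataFrame(
        {"subject": [f"S{i}" for i in range(len(index))], "timepoint": "t1",
         "cohort": "T"},
        index=index,
    )
    sp = ConcentrationMatrix(pd.DataFrame(species_vals, index=index),
                             meta.copy(), "species_level_kit")
    fa = ConcentrationMatrix(pd.DataFrame(fa_vals, index=index),
                             meta.copy(), "fatty_acid_level")
    return sp, fa


@pytest.fixture()
def toy_catalog():
    return assemble_constituent_catalog(
        ["PC aa C36:2"], ["PC 16:0_20:2", "PC 18:0_18:2", "PC 18:1_18:1"]
    )


def test_elementwise_ratios(toy_catalog):
    idx = ["a", "b", "c"]
    sp, fa = paired_matrices(
        {"PC aa C36:2": [2.0, 4.0, 6.0]},
        {"PC 16:0_20:2": [1.0, 2.0, 3.0],
         "PC 18:0_18:2": [2.0, 4.0, 6.0],
         "PC 18:1_18:1": [0.2, 0.4, 0.6]},
        idx,
    )
    ratio_sets = compute_ratio_set(sp, fa, toy_catalog)
    by = {rs.constituent_label: rs for rs in ratio_sets}
    assert np.allclose(by["PC 16:0_20:2"].ratios, 0.5)
    assert np.allclose(by["PC 18:0_18:2"].ratios, 1.0)
    assert np.allclose(by["PC 18:1_18:1"].ratios, 0.1)


def test_missing_and_zero_denominators_excluded(toy_catalog):
    idx = ["a", "b", "c", "d"]
    sp, fa = paired_matrices(
        {"PC aa C36:2": [1.0, np.nan, 0.0, 2.0]},
        {"PC 16:0_20:2": [0.5, 0.5, 0.5, np.nan],
         "PC 18:0_18:2": [1.0, 1.0, 1.0, 1.0],
         "PC 18:1_18:1": [0.1, 0.1, 0.1, 0.1]},
        idx,
    )
    by = {rs.constituent_label: rs
          for rs in compute_ratio_set(sp, fa, toy_catalog)}
    # missing numerator, missing denominator and zero denominator all drop
    assert list(by["PC 16:0_20:2"].ratios.index) == ["a"]
    assert by["PC 16:0_20:2"].n_used == 1
    assert list(by["PC 18:0_18:2"].ratios.index) == ["a", "d"]


def test_absent_analyte_raises(toy_catalog):
    sp, fa = paired_matrices(
        {"PC aa C36:2": [1.0]}, {"PC 16:0_20:2": [0.5]}, ["a"]
    )
    with pytest.raises(ValueError, match="PC 18:0_18:2"):
        compute_ratio_set(sp, fa, toy_catalog)


def test_scale_invariance(toy_catalog):
    idx = [f"s{i}" for i in range(10)]
    rng = np.random.default_rng(3)
    species = {"PC aa C36:2": rng.uniform(0.5, 2.0, 10)}
    fa = {c: rng.uniform(0.1, 1.0, 10)
          for c in ["PC 16:0_20:2", "PC 18:0_18:2", "PC 18:1_18:1"]}
    sp1, fa1 = paired_matrices(species, fa, idx)
    sp2, fa2 = paired_matrices(
        {k: 7.3 * v for k, v in species.items()},
        {k: 7.3 * v for k, v in fa.items()}, idx,
    )
    r1 = compute_ratio_set(sp1, fa1, toy_catalog)
    r2 = compute_ratio_set(sp2, fa2, toy_catalog)
    for a, b in zip(r1, r2):
        assert np.allclose(a.ratios, b.ratios)


def test_categories_are_strict_step_function():
    assert categorize(0.9670) == "II"
    assert categorize(0.3584) == "I"
    assert categorize(0.0820) == "none"
    assert categorize(0.2) == "none"  # strictly greater than
    assert categorize(0.8) == "I"
    assert categorize(np.nextafter(0.2, 1)) == "I"
    assert categorize(np.nextafter(0.8, 1)) == "II"


def test_summary_of_constant_ratios():
    rs = RatioSet("PC aa C36:2", "PC 18:0_18:2",
                  pd.Series([0.4] * 6, index=[f"s{i}" for i in range(6)]))
    comps, warnings = summarize_composition([rs])
    est = comps[0].estimates[0]
    assert est.mean_q == pytest.approx(0.4)
    assert est.ci5 == est.ci95 == pytest.approx(0.4)
    assert est.category == "I"
    assert comps[0].main_constituent == "PC 18:0_18:2"
    assert not warnings


def test_summary_mean_bounds_and_sum_of_proportions():
    idx = [f"s{i}" for i in range(50)]
    rng = np.random.default_rng(8)
    sets = [
        RatioSet("PC aa C36:2", c, pd.Series(rng.uniform(lo, hi, 50), index=idx))
        for c, (lo, hi) in {
            "PC 16:0_20:2": (0.02, 0.06),
            "PC 18:0_18:2": (0.8, 1.1),
            "PC 18:1_18:1": (0.05, 0.15),
        }.items()
    ]
    comps, _ = summarize_composition(sets)
    comp = comps[0]
    for est, rs in zip(comp.estimates, sets):
        assert rs.ratios.min() <= est.mean_q <= rs.ratios.max()
        assert est.ci5 <= est.ci95
    assert comp.main_constituent == "PC 18:0_18:2"
    assert comp.sum_of_proportions == pytest.approx(
        sum(e.mean_q for e in comp.estimates)
    )


def test_sample_filter_and_empty_warning():
    rs = RatioSet("PC aa C36:2", "PC 18:0_18:2",
                  pd.Series([0.5, 0.9], index=["a", "b"]))
    comps, warnings = summarize_composition([rs], sample_filter=["a"])
    assert comps[0].estimates[0].mean_q == 0.5
    comps2, warnings2 = summarize_composition([rs], sample_filter=["zz"])
    assert comps2 == []
    assert len(warnings2) == 1


def test_main_constituent_tie_breaks_by_label():
    idx = ["a", "b"]
    sets = [
        RatioSet("PC aa C34:3", "PC 16:0_18:3", pd.Series([0.5, 0.5], index=idx)),
        RatioSet("PC aa C34:3", "PC 14:0_20:3", pd.Series([0.5, 0.5], index=idx)),
    ]
    comps, _ = summarize_composition(sets)
    assert comps[0].main_constituent == "PC 14:0_20:3"


def test_lipidyzer_fractions_arithmetic(toy_catalog):
    idx = ["a"]
    sp, fa = paired_matrices(
        {"PC aa C36:2": [1.0]},
        {"PC 16:0_20:2": [1.0], "PC 18:0_18:2": [1.0], "PC 18:1_18:1": [2.0]},
        idx,
    )
    frame = lipidyzer_fractions(fa, toy_catalog)
    by = frame.set_index("constituent_label")["fraction"]
    assert by["PC 16:0_20:2"] == pytest.approx(0.25)
    assert by["PC 18:0_18:2"] == pytest.approx(0.25)
    assert by["PC 18:1_18:1"] == pytest.approx(0.5)
    assert not frame["partial"].any()


def test_lipidyzer_fractions_partial_and_single(toy_catalog):
    idx = ["a", "b"]
    sp, fa = paired_matrices(
        {"PC aa C36:2": [1.0, 1.0]},
        {"PC 16:0_20:2": [1.0, np.nan],
         "PC 18:0_18:2": [3.0, 3.0],
         "PC 18:1_18:1": [np.nan, np.nan]},
        idx,
    )
    frame = lipidyzer_fractions(fa, toy_catalog)
    a = frame[frame.sample_id == "a"].set_index("constituent_label")
    assert a.loc["PC 16:0_20:2", "fraction"] == pytest.approx(0.25)
    assert a["partial"].all()  # one constituent missing in sample a
    single_cat = assemble_constituent_catalog(["PC aa C32:2"], ["PC 14:0_18:2"])
    sp2, fa2 = paired_matrices(
        {"PC aa C32:2": [1.0, 2.0]}, {"PC 14:0_18:2": [0.7, 0.9]}, idx
    )
    frame2 = lipidyzer_fractions(fa2, single_cat)
    assert np.allclose(frame2["fraction"], 1.0)
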