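"""Concentration-table IO and the CV / run-day / coverage filters."""

import numpy as np
import pandas as pd
import pytest

from pccomp import (
    ConcentrationMatrix,
    QCConfig,
    coverage_filter,
    qc_filter,
    read_concentration_table,
)


def make_matrix(values: pd.DataFrame, platform="fatty_acid_level"):
    meta = pd.DataFrame(
        {
            "subject": [f"S{i}" for i in range(len(values))],
            "timepoint": "t1",
            "cohort": "TEST",
        },
        index=values.index,
    )
    return ConcentrationMatrix(values, meta, platform)


def test_read_concentration_table(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "sample_id\tsubject\ttimepoint\tPC aa C36:2\tPC 18:0_18:2\n"
        "a\tS1\tt1\t1.0\t0.5\n"
        "b\tS2\tt1\tNA\t0.7\n"
    )
    m = read_concentration_table(path, "species_level_kit")
    assert m.values.shape == (2, 2)
    assert m.analytes == ["PC aa C36:2", "PC 18:0_18:2"]
    assert m.missing_mask.loc["a"].sum() == 0
    assert bool(m.missing_mask.loc["b", "PC aa C36:2"])
    assert list(m.meta["subject"]) == ["S1", "S2"]


def test_read_rejects_bad_labels_and_duplicates(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\tnot a lipid\na\t1.0\n")
    with pytest.raises(ValueError, match="not a lipid"):
        read_concentration_table(bad, "species_level_kit")
    dup = tmp_path / "dup.tsv"
    dup.write_text("sample_id\tPC aa C36:2\na\t1.0\na\t2.0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_concentration_table(dup, "species_level_kit")


def test_columns_normalized_to_canonical_chain_order(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample_id\tPC 18:2_16:1\na\t1.0\n")
    m = read_concentration_table(path, "fatty_acid_level")
    assert m.analytes == ["PC 16:1_18:2"]


def test_negative_concentrations_rejected():
    values = pd.DataFrame({"PC aa C36:2": [1.0, -0.1]}, index=["a", "b"])
    with pytest.raises(ValueError, match="negative"):
        make_matrix(values, "species_level_kit")


def _reference_replicates(rng, cv_by_analyte, n=20, drift=()):
    data = {}
    for analyte, cv in cv_by_analyte.items():
        base = 1.0
        vals = base * (1 + cv * rng.standard_normal(n))
        if analyte in drift:
            vals = base * (1 + cv * np.linspace(-1.5, 1.5, n))
        data[analyte] = vals
    idx = [f"r{i}" for i in range(n)]
    return pd.DataFrame(data, index=idx), pd.Series(np.arange(n), index=idx)


def test_qc_filter_rules():
    rng = np.random.default_rng(5)
    cvs = {"PC aa C30:0": 0.30, "PC aa C32:0": 0.22, "PC aa C32:1": 0.10}
    ref, run_day = _reference_replicates(rng, cvs, drift={"PC aa C32:0"})
    values = pd.DataFrame(
        {a: [1.0, 1.1, 0.9] for a in cvs}, index=["a", "b", "c"]
    )
    matrix = ConcentrationMatrix(
        values,
        pd.DataFrame({"subject": ["S1", "S2", "S3"], "timepoint": "t1",
                      "cohort": "T"}, index=values.index),
        "species_level_kit",
    )
    filtered, report = qc_filter(matrix, ref, QCConfig(), run_day=run_day)
    decisions = report.set_index("analyte")["decision"]
    # CV > 25%: out regardless of run day
    assert decisions["PC aa C30:0"] == "remove"
    # CV in (20%, 25%] with significant run-day correlation: out
    assert decisions["PC aa C32:0"] == "remove"
    assert "run-day" in report.set_index("analyte")["reason"]["PC aa C32:0"]
    # low-CV analyte survives
    assert filtered.analytes == ["PC aa C32:1"]


def test_qc_filter_monotone_in_cv_threshold():
    rng = np.random.default_rng(6)
    cvs = {f"PC aa C{30 + 2 * i}:0": cv
           for i, cv in enumerate([0.05, 0.15, 0.22, 0.28, 0.35])}
    ref, run_day = _reference_replicates(rng, cvs)
    values = pd.DataFrame({a: [1.0, 1.0] for a in cvs}, index=["a", "b"])
    matrix = ConcentrationMatrix(
        values,
        pd.DataFrame({"subject": ["S1", "S2"], "timepoint": "t1",
                      "cohort": "T"}, index=values.index),
        "species_level_kit",
    )
    kept = []
    for thr in (0.10, 0.20, 0.30, 0.40):
        cfg = QCConfig(cv_exclude_threshold=thr)
        out, _ = qc_filter(matrix, ref, cfg, run_day=run_day,
                           apply_runday_rule=False)
        kept.append(set(out.analytes))
    for smaller, larger in zip(kept, kept[1:]):
        assert smaller <= larger


def test_qc_requires_runday_when_rule_active():
    ref, _ = _reference_replicates(np.random.default_rng(0), {"PC aa C30:0": 0.1})
    values = pd.DataFrame({"PC aa C30:0": [1.0]}, index=["a"])
    matrix = ConcentrationMatrix(
        values,
        pd.DataFrame({"subject": ["S1"], "timepoint": "t1", "cohort": "T"},
                     index=values.index),
        "species_level_kit",
    )
    with pytest.raises(ValueError, match="run_day"):
        qc_filter(matrix, ref, QCConfig(), run_day=None)


def test_coverage_filter_boundaries():
    values = pd.DataFrame(
        {
            "PC 16:0_18:1": [1.0, np.nan, np.nan, np.nan],  # 25% exactly
            "PC 16:0_18:2": [np.nan] * 4,  # never observed
            "PC 16:0_20:4": [1.0, 2.0, np.nan, np.nan],  # 50%
        },
        index=list("abcd"),
    )
    matrix = make_matrix(values)
    out = coverage_filter(matrix, coverage_min=0.25)
    assert out.analytes == ["PC 16:0_18:1", "PC 16:0_20:4"]  # >= is inclusive
    strict = coverage_filter(matrix, coverage_min=0.26)
    assert strict.analytes == ["PC 16:0_20:4"]


def test_coverage_filter_idempotent_and_order_invariant():
    rng = np.random.default_rng(1)
    values = pd.DataFrame(
        rng.random((8, 3)), index=[f"s{i}" for i in range(8)],
        columns=["PC 16:0_18:1", "PC 16:0_18:2", "PC 16:0_20:4"],
    ).mask(rng.random((8, 3)) < 0.5)
    matrix = make_matrix(values)
    once = coverage_filter(matrix, 0.4)
    twice = coverage_filter(once, 0.4)
    assert once.analytes == twice.analytes
    shuffled = matrix.subset_samples(list(reversed(matrix.sample_ids)))
    assert set(coverage_filter(shuffled, 0.4).analytes) == set(once.analytes)


def test_round_trip_write_read(tmp_path, humet_cohort):
    _, species, _, _ = humet_cohort
    path = tmp_path / "species.tsv"
    species.write(path)
    back = read_concentration_table(path, "species_level_kit")
    assert back.analytes == species.analytes
    pd.testing.assert_frame_equal(
        back.values, species.values, check_exact=False, rtol=1e-12,
        check_names=False,
    )
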